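"""Cluster-level hybrid identification from dual lineage scores.

A candidate cluster is called hybrid when its tumor score is stochastically
greater than that of **every** non-tumor (immune/stromal) cluster AND its
macrophage score is stochastically greater than that of **every**
tumor-annotated cluster, each family of one-sided Mann-Whitney comparisons
Benjamini-Hochberg adjusted, all adjusted p at or below ``alpha``.  This
replaces manual inspection of per-cluster score violin plots with the
equivalent family of rank tests; because the tests are rank-based the
decision is invariant to monotone transformations of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import scipy.stats

from ._stats import bh_adjust

__all__ = ["HybridCall", "summarize_clusters", "call_hybrid_clusters"]

NON_TUMOR_LINEAGES = ("macrophage", "other_immune", "stromal")


@dataclass
class HybridCall:
    """Decision record for one cluster."""

    cluster: int
    is_hybrid: bool
    tum_comparisons: list[tuple[int, float, float]] = field(default_factory=list)
    mac_comparisons: list[tuple[int, float, float]] = field(default_factory=list)
    alpha: float = 0.05
    demotion_reason: str | None = None

    @property
    def max_adjusted_p_tum(self) -> float:
        """Worst (largest) adjusted p among the tumor-score comparisons."""
        return max((p for _, _, p in self.tum_comparisons), default=np.nan)

    @property
    def max_adjusted_p_mac(self) -> float:
        """Worst (largest) adjusted p among the macrophage-score comparisons."""
        return max((p for _, _, p in self.mac_comparisons), default=np.nan)


def summarize_clusters(
    scores: pd.DataFrame,
    clusters,
    annotations,
) -> pd.DataFrame:
    """Per-cluster score medians and majority-vote lineage annotation.

    ``scores`` must carry ``barcode``, ``tum_score`` and ``mac_score`` for
    every clustered cell; ``clusters`` and ``annotations`` are aligned with
    its rows.  The cluster annotation is the most frequent per-cell
    annotation among members (ties broken alphabetically).
    """
    clusters = np.asarray(clusters)
    annotations = np.asarray(annotations, dtype=object)
    if len(clusters) != len(scores) or len(annotations) != len(scores):
        raise ValueError("clusters and annotations must align with the score table")
    if scores[["tum_score", "mac_score"]].isna().any().any():
        raise ValueError("missing scores for some clustered cells")
    frame = scores.copy()
    frame["cluster"] = clusters
    frame["annotation"] = annotations
    rows = []
    for cl, grp in frame.groupby("cluster", sort=True):
        counts = grp["annotation"].value_counts()
        top = counts.max()
        majority = sorted(counts[counts == top].index)[0]
        rows.append(
            {
                "cluster": cl,
                "lineage_annotation": majority,
                "median_tum_score": float(grp["tum_score"].median()),
                "median_mac_score": float(grp["mac_score"].median()),
                "n_cells": int(len(grp)),
            }
        )
    return pd.DataFrame(rows)


def _greater(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-sided Mann-Whitney p and the AUC effect size P(a > b)."""
    res = scipy.stats.mannwhitneyu(a, b, alternative="greater")
    return float(res.pvalue), float(res.statistic) / (len(a) * len(b))


def call_hybrid_clusters(
    summaries: pd.DataFrame,
    scores: pd.DataFrame,
    clusters,
    alpha: float = 0.05,
    min_effect_auc: float = 0.9,
) -> list[HybridCall]:
    """Evaluate every cluster against the dual score criterion.

    Zero, one or several clusters may be called hybrid.  Requires at least
    one tumor-annotated and one immune-annotated cluster to compare
    against; raises otherwise.

    Because clusters are derived from the same expression matrix the
    scores are computed on, rank tests between clusters of hundreds of
    cells can reach significance on trivial shifts.  A call therefore
    additionally requires a material effect in every comparison: the
    probability that a random candidate cell outscores a random comparison
    cell (the Mann-Whitney AUC) must be at least ``min_effect_auc``.  Set
    ``min_effect_auc=0`` to recover the purely significance-based rule.
    """
    clusters = np.asarray(clusters)
    annot = dict(zip(summaries["cluster"], summaries["lineage_annotation"]))
    tumor_clusters = [c for c, a in annot.items() if a == "tumor"]
    immune_clusters = [c for c, a in annot.items() if a in ("macrophage", "other_immune")]
    non_tumor_clusters = [c for c, a in annot.items() if a in NON_TUMOR_LINEAGES]
    if not tumor_clusters or not immune_clusters:
        raise ValueError(
            "hybrid calling needs at least one tumor-annotated and one "
            "immune-annotated cluster; check the per-cell annotations"
        )
    tum = scores["tum_score"].to_numpy()
    mac = scores["mac_score"].to_numpy()

    calls = []
    for cand in summaries["cluster"]:
        in_cand = clusters == cand
        tum_cmp, mac_cmp = [], []
        aucs = []
        for other in non_tumor_clusters:
            if other == cand:
                continue
            p, auc = _greater(tum[in_cand], tum[clusters == other])
            tum_cmp.append((other, p))
            aucs.append(auc)
        for other in tumor_clusters:
            if other == cand:
                continue
            p, auc = _greater(mac[in_cand], mac[clusters == other])
            mac_cmp.append((other, p))
            aucs.append(auc)
        tum_adj = bh_adjust([p for _, p in tum_cmp])
        mac_adj = bh_adjust([p for _, p in mac_cmp])
        tum_full = [(c, p, q) for (c, p), q in zip(tum_cmp, tum_adj)]
        mac_full = [(c, p, q) for (c, p), q in zip(mac_cmp, mac_adj)]
        ok = (
            len(tum_full) > 0
            and len(mac_full) > 0
            and all(q <= alpha for _, _, q in tum_full)
            and all(q <= alpha for _, _, q in mac_full)
            and all(a >= min_effect_auc for a in aucs)
        )
        calls.append(
            HybridCall(
                cluster=cand,
                is_hybrid=bool(ok),
                tum_comparisons=tum_full,
                mac_comparisons=mac_full,
                alpha=alpha,
            )
        )
    return calls
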