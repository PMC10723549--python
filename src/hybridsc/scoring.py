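"""Lineage marker derivation and binned-control module scoring.

The two per-cell lineage scores (``tum_score`` against the tumor marker
program and ``mac_score`` against the macrophage/monocyte program) are the
quantities the hybrid caller operates on.  Marker genes are the top-n
differentially expressed genes between the two annotated lineages; the
module score is the classic expression-matched control-gene score: mean
expression of the gene set minus the mean over control genes drawn from
bins of similar data-wide mean expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._stats import bonferroni, log2_fold_change, rank_sum_pvalues

__all__ = ["ScoreConfig", "rank_lineage_markers", "module_score", "score_lineages"]


@dataclass
class ScoreConfig:
    """Module-score parameters: top-gene count, bin count, controls, seed."""

    n_top: int = 50
    nbin: int = 24
    n_ctrl: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.nbin < 2:
            raise ValueError("nbin must be >= 2")
        if self.n_ctrl < 1:
            raise ValueError("n_ctrl must be >= 1")
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")


def _dense(adata: ad.AnnData) -> np.ndarray:
    return adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, float)


def _de_table(Xa: np.ndarray, Xb: np.ndarray, genes) -> pd.DataFrame:
    p = rank_sum_pvalues(Xa, Xb)
    return pd.DataFrame(
        {
            "gene": list(genes),
            "log2fc": log2_fold_change(Xa, Xb),
            "p_value": p,
            "p_adjusted": bonferroni(p),
            "pct_a": (Xa > 0).mean(axis=0),
            "pct_b": (Xb > 0).mean(axis=0),
        }
    )


def rank_lineage_markers(
    adata: ad.AnnData,
    labels,
    group_a: str,
    group_b: str,
    n_top: int = 50,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Top ``n_top`` markers of each lineage by two-group Wilcoxon DE.

    ``labels`` is aligned with ``adata.obs_names``.  Genes are ranked by
    Bonferroni-adjusted p (ascending) then |log2fc| (descending), ties
    broken lexicographically by symbol; the first list is up in
    ``group_a``, the second up in ``group_b``.  The full per-gene DE table
    is returned alongside.
    """
    labels = np.asarray(labels)
    mask_a = labels == group_a
    mask_b = labels == group_b
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each lineage group needs at least 3 cells")
    X = _dense(adata)
    table = _de_table(X[mask_a], X[mask_b], adata.var_names)

    def top(direction: int) -> list[str]:
        sub = table[np.sign(table["log2fc"]) == direction].copy()
        sub["abs_lfc"] = sub["log2fc"].abs()
        sub = sub.sort_values(
            ["p_adjusted", "abs_lfc", "gene"], ascending=[True, False, True]
        )
        return sub["gene"].head(n_top).tolist()

    return top(+1), top(-1), table


def module_score(
    adata: ad.AnnData,
    gene_set,
    config: ScoreConfig | None = None,
) -> np.ndarray:
    """Expression-matched control score of ``gene_set`` per cell.

    Every gene's data-wide mean expression is computed; genes are cut into
    ``nbin`` equal-size bins by that mean (ties broken by symbol for
    determinism).  For each set gene, ``n_ctrl`` control genes are drawn
    uniformly without replacement from its bin (the whole bin if smaller);
    draws are independent across set genes, so a control gene can recur.
    The score is the mean expression over the set minus the mean over the
    pooled control draws (duplicates counted).
    """
    config = config or ScoreConfig()
    config.validate()
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set must not be empty")
    var_index = {g: i for i, g in enumerate(adata.var_names)}
    missing = [g for g in gene_set if g not in var_index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    n_genes = adata.n_vars
    if config.nbin > n_genes:
        raise ValueError(
            f"nbin={config.nbin} exceeds the {n_genes} genes available; "
            "lower nbin (small samples may need e.g. nbin=12)"
        )

    X = _dense(adata)
    gene_means = X.mean(axis=0)
    # stable order: by mean, then symbol, so equal means bin deterministically
    order = np.lexsort((np.asarray(adata.var_names), gene_means))
    bin_of = np.empty(n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, config.nbin)):
        bin_of[chunk] = b
    bin_members = [np.flatnonzero(bin_of == b) for b in range(config.nbin)]

    rng = np.random.default_rng(config.seed)
    set_idx = np.array([var_index[g] for g in gene_set])
    ctrl_draws = []
    for gi in set_idx:
        members = bin_members[bin_of[gi]]
        k = min(config.n_ctrl, members.size)
        ctrl_draws.append(rng.choice(members, size=k, replace=False))
    ctrl_idx = np.concatenate(ctrl_draws)
    return X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def score_lineages(
    adata: ad.AnnData,
    tumor_genes,
    macrophage_genes,
    config: ScoreConfig | None = None,
) -> pd.DataFrame:
    """Per-cell ``tum_score`` / ``mac_score`` table (one row per barcode)."""
    return pd.DataFrame(
        {
            "barcode": list(adata.obs_names),
            "tum_score": module_score(adata, tumor_genes, config),
            "mac_score": module_score(adata, macrophage_genes, config),
        }
    )
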