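"""Hybrid differential expression, cross-sample panel selection and ORA.

Differential expression between a hybrid cluster and each reference lineage
uses the two-sided Wilcoxon rank-sum test with Bonferroni adjustment and
the Seurat-convention log2 fold change.  The panel-selection step encodes
the cross-sample sharing rule (significant in at least ``min_samples_shared``
samples at |lfc| >= ``lfc_gene``) with the two narrowing rules for the
crowded comparisons: keep the top-k up-regulated genes versus tumor, and
only strongly down-regulated genes (lfc <= ``lfc_floor_down_vs_mac``)
versus macrophages.  Over-representation of a gene list in GMT gene sets
is the hypergeometric upper tail with Benjamini-Hochberg adjustment across
sets — a fully local equivalent of web-service enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from ._stats import bh_adjust, bonferroni, log2_fold_change, rank_sum_pvalues

__all__ = [
    "PanelSelectionConfig",
    "differential_expression",
    "select_shared_panel",
    "overrepresentation",
]


@dataclass
class PanelSelectionConfig:
    """Thresholds of the gene-panel and pathway-input filters."""

    alpha_adj: float = 0.05
    lfc_gene: float = 1.0
    lfc_pathway: float = 0.58
    min_samples_shared: int = 2
    top_k_up_vs_tumor: int = 10
    lfc_floor_down_vs_mac: float = -2.0
    include_genes: tuple[str, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        if self.min_samples_shared < 1:
            raise ValueError("min_samples_shared must be >= 1")
        for name in ("alpha_adj", "lfc_gene", "lfc_pathway", "lfc_floor_down_vs_mac"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def differential_expression(adata: ad.AnnData, cells_a, cells_b) -> pd.DataFrame:
    """Per-gene Wilcoxon DE between two disjoint barcode sets.

    Returns a table with ``gene``, ``log2fc`` (a over b), ``p_value``,
    Bonferroni ``p_adjusted`` and the expressing-cell fractions
    ``pct_a``/``pct_b``.
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if set(cells_a) & set(cells_b):
        raise ValueError("comparison groups overlap")
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("each comparison group needs at least 3 cells")
    pos = {b: i for i, b in enumerate(adata.obs_names)}
    missing = [b for b in cells_a + cells_b if b not in pos]
    if missing:
        raise ValueError(f"barcodes absent from matrix: {missing[:5]}")
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, float)
    Xa = X[[pos[b] for b in cells_a]]
    Xb = X[[pos[b] for b in cells_b]]
    p = rank_sum_pvalues(Xa, Xb)
    return pd.DataFrame(
        {
            "gene": list(adata.var_names),
            "log2fc": log2_fold_change(Xa, Xb),
            "p_value": p,
            "p_adjusted": bonferroni(p),
            "pct_a": (Xa > 0).mean(axis=0),
            "pct_b": (Xb > 0).mean(axis=0),
        }
    )


def _passing(table: pd.DataFrame, alpha: float, lfc: float, up: bool) -> pd.DataFrame:
    sig = table["p_adjusted"] <= alpha
    direction = table["log2fc"] >= lfc if up else table["log2fc"] <= -lfc
    return table[sig & direction]


def select_shared_panel(
    per_sample: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    config: PanelSelectionConfig | None = None,
) -> pd.DataFrame:
    """Cross-sample shared gene panel with provenance.

    ``per_sample`` maps sample id to its ``(hybrid vs tumor, hybrid vs
    macrophage)`` DE tables.  Output columns: ``gene``, ``comparison``
    (``vs_tumor``/``vs_macrophage``), ``direction`` (``up``/``down``),
    ``n_samples``, ``samples``.  Empty input yields an empty panel.
    """
    config = config or PanelSelectionConfig()
    config.validate()
    buckets: dict[tuple[str, str], dict[str, list]] = {}

    def collect(comparison, direction, sample, table, up):
        hits = _passing(table, config.alpha_adj, config.lfc_gene, up)
        for _, row in hits.iterrows():
            rec = buckets.setdefault((comparison, direction), {}).setdefault(
                row["gene"], []
            )
            rec.append((sample, row["p_adjusted"], row["log2fc"]))

    for sample, (vs_tumor, vs_mac) in per_sample.items():
        if vs_tumor is not None and len(vs_tumor):
            collect("vs_tumor", "up", sample, vs_tumor, up=True)
            collect("vs_tumor", "down", sample, vs_tumor, up=False)
        if vs_mac is not None and len(vs_mac):
            collect("vs_macrophage", "up", sample, vs_mac, up=True)
            collect("vs_macrophage", "down", sample, vs_mac, up=False)

    rows = []
    for (comparison, direction), genes in buckets.items():
        shared = {
            g: recs
            for g, recs in genes.items()
            if len(recs) >= config.min_samples_shared
        }
        if comparison == "vs_macrophage" and direction == "down":
            shared = {
                g: recs
                for g, recs in shared.items()
                if sum(lfc <= config.lfc_floor_down_vs_mac for _, _, lfc in recs)
                >= config.min_samples_shared
            }
        entries = [
            {
                "gene": g,
                "comparison": comparison,
                "direction": direction,
                "n_samples": len(recs),
                "samples": ",".join(sorted(s for s, _, _ in recs)),
                "best_p_adjusted": min(p for _, p, _ in recs),
            }
            for g, recs in shared.items()
        ]
        entries.sort(key=lambda e: (e["best_p_adjusted"], e["gene"]))
        if comparison == "vs_tumor" and direction == "up":
            entries = entries[: config.top_k_up_vs_tumor]
        rows.extend(entries)

    panel = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "comparison",
            "direction",
            "n_samples",
            "samples",
            "best_p_adjusted",
        ],
    )
    for g in config.include_genes:
        if g not in set(panel["gene"]):
            panel.loc[len(panel)] = [g, "curated", "included", 0, "", np.nan]
    return panel.reset_index(drop=True)


def overrepresentation(
    gene_list,
    universe,
    gene_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``gene_list`` in each set.

    ``p = sum_{i>=k} C(K,i) C(M-K, n-i) / C(M,n)`` with M = universe size,
    K = set size within the universe, n = list size, k = overlap; BH
    adjustment across sets.  Sets disjoint from the universe are recorded
    with K = 0 and p = 1.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("universe must not be empty")
    uni = set(universe)
    genes = set(gene_list)
    if not genes <= uni:
        raise ValueError("gene_list must be a subset of the universe")
    M, n = len(uni), len(genes)
    rows = []
    for name, members in gene_sets.items():
        in_uni = uni & set(members)
        K = len(in_uni)
        k = len(genes & in_uni)
        p = 1.0 if K == 0 else float(scipy.stats.hypergeom.sf(k - 1, M, K, n))
        rows.append(
            {
                "set_name": name,
                "overlap_k": k,
                "set_size_K": K,
                "list_size_n": n,
                "universe_M": M,
                "p_value": min(1.0, p),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = np.maximum(bh_adjust(table["p_value"]), table["p_value"])
        table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    return table
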