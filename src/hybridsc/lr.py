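"""Permutation-based ligand-receptor interaction specificity.

For every (ligand, receptor) pair and ordered (sender, receiver) cell-type
combination, the interaction score is the mean of the ligand's mean
normalized expression in the sender type and the receptor's mean in the
receiver type.  Significance comes from permuting the cell-type labels
(the same permutations for all pairs), with the empirical upper-tail
p-value ``(# permuted means >= observed) / n_permutations`` — no
smoothing, so p = 0 is attainable.  Cell types below the minimum size are
dropped before anything else, and a combination is evaluated only when the
ligand (receptor) is expressed in at least ``min_expr_fraction`` of the
sender (receiver) cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["LRConfig", "infer_interactions", "summarize_interactions"]


@dataclass
class LRConfig:
    n_permutations: int = 1000
    alpha: float = 0.05
    min_cells_per_type: int = 20
    min_expr_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0.0 <= self.min_expr_fraction <= 1.0):
            raise ValueError("min_expr_fraction must lie in [0, 1]")
        if self.min_cells_per_type < 1:
            raise ValueError("min_cells_per_type must be >= 1")


def infer_interactions(
    adata: ad.AnnData,
    labels,
    pair_table: pd.DataFrame,
    config: LRConfig | None = None,
) -> pd.DataFrame:
    """Evaluate every pair x (sender, receiver) combination.

    ``labels`` assigns a cell type to each cell of ``adata`` (normalized
    expression).  Returns one row per evaluated combination with the
    observed ``interaction_mean``, permutation ``p_value`` and the
    ``significant`` flag (p <= alpha).  Pairs whose genes are missing from
    the matrix are skipped.
    """
    config = config or LRConfig()
    config.validate()
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != adata.n_obs:
        raise ValueError("labels must align with cells")

    counts = pd.Series(labels).value_counts()
    kept_types = sorted(counts[counts >= config.min_cells_per_type].index)
    if len(kept_types) < 2:
        raise ValueError(
            f"need at least two cell types with >= {config.min_cells_per_type} cells"
        )
    keep_mask = np.isin(labels, kept_types)
    labels = labels[keep_mask]

    var_pos = {g: i for i, g in enumerate(adata.var_names)}
    genes_needed = sorted(
        {g for g in pair_table["ligand"]} | {g for g in pair_table["receptor"]}
    )
    present = [g for g in genes_needed if g in var_pos]
    gene_pos = {g: j for j, g in enumerate(present)}
    X = adata.X[keep_mask][:, [var_pos[g] for g in present]]
    X = X.toarray() if sp.issparse(X) else np.asarray(X, float)

    type_index = {t: np.flatnonzero(labels == t) for t in kept_types}
    type_sizes = np.array([type_index[t].size for t in kept_types], dtype=float)
    onehot = np.zeros((len(kept_types), len(labels)))
    for i, t in enumerate(kept_types):
        onehot[i, type_index[t]] = 1.0
    obs_mean = onehot @ X / type_sizes[:, None]          # type x gene means
    expr_frac = onehot @ (X > 0) / type_sizes[:, None]   # expressing fraction

    # enumerate evaluable combinations
    combos = []  # (ligand, receptor, sender_i, receiver_i)
    for _, row in pair_table.iterrows():
        lig, rec = row["ligand"], row["receptor"]
        if lig not in gene_pos or rec not in gene_pos:
            continue
        li, ri = gene_pos[lig], gene_pos[rec]
        for si, s in enumerate(kept_types):
            if expr_frac[si, li] < config.min_expr_fraction:
                continue
            for ti, t in enumerate(kept_types):
                if expr_frac[ti, ri] < config.min_expr_fraction:
                    continue
                combos.append((lig, rec, si, ti, li, ri))
    if not combos:
        return pd.DataFrame(
            columns=[
                "ligand", "receptor", "sender", "receiver",
                "interaction_mean", "p_value", "significant",
            ]
        )

    si_a = np.array([c[2] for c in combos])
    ti_a = np.array([c[3] for c in combos])
    li_a = np.array([c[4] for c in combos])
    ri_a = np.array([c[5] for c in combos])
    observed = (obs_mean[si_a, li_a] + obs_mean[ti_a, ri_a]) / 2.0
    exceed = np.zeros(len(combos), dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    perm = np.arange(len(labels))
    for _ in range(config.n_permutations):
        rng.shuffle(perm)
        perm_mean = onehot[:, perm] @ X / type_sizes[:, None]
        perm_stat = (perm_mean[si_a, li_a] + perm_mean[ti_a, ri_a]) / 2.0
        exceed += perm_stat >= observed
    pvals = exceed / config.n_permutations

    return pd.DataFrame(
        {
            "ligand": [c[0] for c in combos],
            "receptor": [c[1] for c in combos],
            "sender": [kept_types[c[2]] for c in combos],
            "receiver": [kept_types[c[3]] for c in combos],
            "interaction_mean": observed,
            "p_value": pvals,
            "significant": pvals <= config.alpha,
        }
    )


def summarize_interactions(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Sender x receiver matrix of significant interaction counts."""
    if results.empty:
        return pd.DataFrame()
    sig = results[results["p_value"] <= alpha]
    senders = sorted(results["sender"].unique())
    receivers = sorted(results["receiver"].unique())
    matrix = pd.DataFrame(0, index=senders, columns=receivers)
    for (s, r), grp in sig.groupby(["sender", "receiver"]):
        matrix.loc[s, r] = len(grp)
    return matrix
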