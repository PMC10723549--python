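"""Gene filtering, normalization, PCA embedding and Leiden clustering.

Normalization is log1p counts-per-10k (a documented, configurable stand-in
for variance-stabilizing transforms: the hybrid-detection logic downstream
depends on relative lineage expression, not on the exact variance model).
Principal components are selected by a cumulative-variance rule — the
smallest prefix of computed PCs whose cumulative share of the computed-PC
variance exceeds ``cum_threshold``, restricted to PCs whose individual
share is at least ``indiv_threshold`` — with fallbacks guaranteeing a
usable embedding (minimum two PCs; first ``min(10, max_pcs)`` PCs when the
individual filter empties the prefix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import igraph
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .io import CountMatrix

__all__ = ["Embedding", "qc_filter", "normalize", "embed", "select_pcs", "cluster"]


@dataclass
class Embedding:
    """PCA coordinates, selected-PC count, kNN graph and cluster labels."""

    pcs: np.ndarray
    variance_ratio: np.ndarray
    n_selected: int
    barcodes: list[str]
    neighbor_graph: sp.spmatrix | None = None
    cluster_labels: np.ndarray | None = None
    umap_coords: np.ndarray | None = None
    hvg: list[str] = field(default_factory=list)

    @property
    def coords(self) -> np.ndarray:
        """The selected-PC coordinates used for graphs and clustering."""
        return self.pcs[:, : self.n_selected]


def qc_filter(counts: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Keep genes detected (nonzero) in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be non-negative")
    if counts.n_genes == 0 or counts.n_cells == 0:
        raise ValueError("empty count matrix")
    detected = np.asarray((counts.values > 0).sum(axis=1)).ravel()
    keep = detected >= min_cells
    return CountMatrix(
        counts.values[keep, :],
        [g for g, k in zip(counts.gene_symbols, keep) if k],
        list(counts.barcodes),
        counts.sample_id,
    )


def normalize(counts: CountMatrix, scale: float = 1e4) -> ad.AnnData:
    """log1p counts-per-``scale`` normalization; returns cells x genes AnnData.

    Zero counts map exactly to zero and within-cell ordering of counts is
    preserved.  A cell with zero total counts is an error (its barcode is
    named) — such cells should be removed upstream.
    """
    adata = counts.to_anndata()
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = adata.obs_names[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts; remove it before normalizing")
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    X = X.multiply(scale / totals[:, None]).tocsr()
    X.data = np.log1p(X.data)
    adata.X = X
    adata.uns["normalization"] = {"method": "log1p_cp", "scale": scale}
    return adata


def _top_dispersion_genes(X: np.ndarray, n_hvg: int) -> np.ndarray:
    """Indices of the ``n_hvg`` genes with highest dispersion (var/mean).

    Computed on the de-logged normalized values, the standard
    dispersion-based highly-variable-gene heuristic.
    """
    expr = np.expm1(X)
    mean = expr.mean(axis=0)
    var = expr.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(-disp, kind="stable")
    return np.sort(order[:n_hvg])


def select_pcs(
    variance_ratio: np.ndarray,
    cum_threshold: float = 0.95,
    indiv_threshold: float = 0.05,
    max_pcs: int = 50,
) -> int:
    """Number of leading PCs to retain given per-PC variance shares.

    Shares are renormalized over the computed PCs.  The smallest prefix
    whose cumulative share exceeds ``cum_threshold`` is restricted to PCs
    with individual share >= ``indiv_threshold``; at least two PCs are
    always retained, and if no PC passes the individual filter the first
    ``min(10, max_pcs)`` PCs are used.
    """
    ratio = np.asarray(variance_ratio, dtype=float)
    ratio = ratio / ratio.sum()
    n_computed = ratio.size
    cum = np.cumsum(ratio)
    prefix = int(np.searchsorted(cum, cum_threshold, side="right")) + 1
    prefix = min(prefix, n_computed)
    n_pass = int(np.count_nonzero(ratio[:prefix] >= indiv_threshold))
    if n_pass == 0:
        return min(10, max_pcs, n_computed)
    return min(max(n_pass, 2), n_computed)


def embed(
    adata: ad.AnnData,
    n_hvg: int = 2000,
    max_pcs: int = 50,
    cum_threshold: float = 0.95,
    indiv_threshold: float = 0.05,
    clip: float = 10.0,
    random_state: int = 0,
) -> Embedding:
    """Scale highly variable genes and compute the PCA embedding."""
    if adata.n_obs < 3:
        raise ValueError("need at least 3 cells to embed")
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, float)
    if X.std() <= 1e-12 * max(1.0, float(np.abs(X).max())):
        raise ValueError("degenerate (constant) expression matrix")
    hvg_idx = (
        _top_dispersion_genes(X, n_hvg) if adata.n_vars > n_hvg else np.arange(adata.n_vars)
    )
    Xh = X[:, hvg_idx]
    mu = Xh.mean(axis=0)
    sd = Xh.std(axis=0)
    Xs = (Xh - mu) / np.where(sd > 0, sd, 1.0)
    np.clip(Xs, -clip, clip, out=Xs)
    n_comp = int(min(max_pcs, Xs.shape[0] - 1, Xs.shape[1]))
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=random_state)
    pcs = pca.fit_transform(Xs)
    ratio = pca.explained_variance_ratio_
    n_selected = select_pcs(ratio, cum_threshold, indiv_threshold, max_pcs)
    return Embedding(
        pcs=pcs,
        variance_ratio=ratio,
        n_selected=n_selected,
        barcodes=list(adata.obs_names),
        hvg=[adata.var_names[i] for i in hvg_idx],
    )


def cluster(
    embedding: Embedding,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> Embedding:
    """Leiden partition of the Euclidean kNN graph in selected-PC space."""
    coords = embedding.coords
    n_cells = coords.shape[0]
    if k_neighbors >= n_cells:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n_cells}")
    knn = kneighbors_graph(coords, n_neighbors=k_neighbors, mode="connectivity")
    adj = knn.maximum(knn.T).tocoo()
    graph = igraph.Graph(
        n=n_cells,
        edges=list(zip(adj.row[adj.row < adj.col], adj.col[adj.row < adj.col])),
        directed=False,
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    embedding.neighbor_graph = adj.tocsr()
    embedding.cluster_labels = np.asarray(part.membership, dtype=int)
    return embedding
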