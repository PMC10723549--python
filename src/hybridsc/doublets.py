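"""Simulation-based doublet scores and the cluster-level consensus rule.

Three kNN statistics on a joint embedding of observed cells and simulated
artificial doublets (pair sums of observed libraries) are computed at
contract level:

* ``pann`` — proportion of artificial neighbors among the K nearest
  neighbors in the merged embedding, K = round(pK x n_merged);
* ``knn_fraction`` — fraction of artificial cells among ``k_sim``
  neighbors, corrected for the simulation ratio r = n_art/n_obs as
  ``(f/r) / (f/r + (1 - f))``;
* ``density_ratio`` — artificial-cell density over observed-cell density
  within the radius of the ``k_sim``-th nearest neighbor, each normalized
  by its population size (the querying cell itself counts as observed, so
  the denominator is never zero).

A cluster is flagged as a doublet artifact when the percentile rank of its
median score among cluster medians exceeds ``rank_threshold`` in at least
two of the three methods — the consensus reading of "consistently elevated
doublet scores".  A hybrid call whose cluster is flagged is demoted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix
from .hybrid_calls import HybridCall

__all__ = [
    "DoubletConfig",
    "ClusterAdjudication",
    "simulate_artificial_doublets",
    "score_doublets",
    "score_from_embedding",
    "doublet_scores",
    "adjudicate_clusters",
]

METHODS = ("pann", "knn_fraction", "density_ratio")


@dataclass
class DoubletConfig:
    """Simulation and neighborhood parameters for the three scorers.

    ``pN`` is the artificial fraction of the merged set (so
    ``n_art = pN/(1-pN) x n_obs`` for the pANN variant), ``pK`` the merged
    neighborhood fraction.  ``n_sim`` (default: n_obs) is the artificial
    count for the other two scorers and ``k_sim`` their neighborhood size.
    ``n_expected`` mirrors the published tools' expected-doublet count used
    for hard thresholding; the consensus rule here is rank-based and does
    not consume it.
    """

    n_pcs: int = 10
    pN: float = 0.25
    pK: float = 0.09
    n_expected: int | None = None
    k_sim: int = 50
    n_sim: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.pN < 1.0):
            raise ValueError("pN must lie in (0, 1)")
        if not (0.0 < self.pK < 1.0):
            raise ValueError("pK must lie in (0, 1)")
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.k_sim < 1:
            raise ValueError("k_sim must be >= 1")


@dataclass
class ClusterAdjudication:
    cluster: int
    median_scores: dict[str, float]
    percentile_ranks: dict[str, float]
    flagged_doublet: bool
    n_methods_elevated: int


def simulate_artificial_doublets(
    counts: CountMatrix,
    config: DoubletConfig,
    n_art: int | None = None,
) -> CountMatrix:
    """Pair-sum artificial doublets from the observed libraries.

    ``n_art`` defaults to the pANN convention ``round(pN/(1-pN) x n_obs)``;
    pass ``config.n_sim`` (or any count) for the other scorers.
    """
    config.validate()
    n_obs = counts.n_cells
    if n_obs < 2:
        raise ValueError("need at least two observed cells")
    if n_art is None:
        n_art = int(round(config.pN / (1.0 - config.pN) * n_obs))
    rng = np.random.default_rng(config.seed)
    left = rng.integers(0, n_obs, size=n_art)
    delta = rng.integers(1, n_obs, size=n_art)
    right = (left + delta) % n_obs  # distinct partner, uniform over others
    values = counts.values[:, left] + counts.values[:, right]
    barcodes = [f"ART{i + 1:06d}" for i in range(n_art)]
    return CountMatrix(sp.csc_matrix(values), list(counts.gene_symbols), barcodes, counts.sample_id)


def _merged_embedding(
    counts: CountMatrix, artificial: CountMatrix, config: DoubletConfig
) -> np.ndarray:
    """log1p-CP10K normalize the merged matrix and project onto n_pcs PCs."""
    merged = sp.hstack([counts.values, artificial.values], format="csc")
    totals = np.asarray(merged.sum(axis=0)).ravel()
    if np.any(totals == 0):
        raise ValueError("merged matrix contains zero-total cells")
    X = merged.T.multiply(1e4 / totals[:, None]).tocsr()
    X.data = np.log1p(X.data)
    X = X.toarray()
    pca = PCA(n_components=min(config.n_pcs, X.shape[0] - 1, X.shape[1]),
              svd_solver="randomized", random_state=config.seed)
    return pca.fit_transform(X)


def score_doublets(
    counts: CountMatrix,
    artificial: CountMatrix,
    config: DoubletConfig,
    method: str,
) -> np.ndarray:
    """One doublet score per observed cell by the requested method."""
    coords = _merged_embedding(counts, artificial, config)
    return score_from_embedding(coords, counts.n_cells, artificial.n_cells, config, method)


def score_from_embedding(
    coords: np.ndarray,
    n_obs: int,
    n_art: int,
    config: DoubletConfig,
    method: str,
) -> np.ndarray:
    """kNN doublet statistics on a given merged embedding.

    Rows ``0..n_obs-1`` of ``coords`` are observed cells, the remaining
    ``n_art`` rows artificial doublets.
    """
    config.validate()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    obs_coords = coords[:n_obs]
    is_art = np.zeros(n_obs + n_art, dtype=bool)
    is_art[n_obs:] = True

    if method == "pann":
        K = int(round(config.pK * (n_obs + n_art)))
        if K < 1:
            raise ValueError("pK too small: merged neighborhood K < 1")
        k = K
    else:
        k = config.k_sim

    nn = NearestNeighbors(n_neighbors=min(k + 1, n_obs + n_art)).fit(coords)
    dist, idx = nn.kneighbors(obs_coords)
    # drop self (always the zero-distance first hit for observed queries)
    dist, idx = dist[:, 1:], idx[:, 1:]
    art_frac = is_art[idx].mean(axis=1)

    if method == "pann":
        return art_frac
    if method == "knn_fraction":
        f = art_frac
        r = n_art / n_obs
        with np.errstate(divide="ignore", invalid="ignore"):
            score = (f / r) / ((f / r) + (1.0 - f))
        return np.where(f == 0, 0.0, score)
    # density_ratio: counts within the k-th neighbor radius, self included
    n_art_in = is_art[idx].sum(axis=1)
    n_obs_in = (k - n_art_in) + 1  # + self
    return (n_art_in / n_art) / (n_obs_in / n_obs)


def doublet_scores(counts: CountMatrix, config: DoubletConfig) -> pd.DataFrame:
    """All three per-cell scores as a DoubletScoreTable data frame."""
    art_pann = simulate_artificial_doublets(counts, config)
    n_sim = config.n_sim if config.n_sim is not None else counts.n_cells
    art_sim = simulate_artificial_doublets(counts, config, n_art=n_sim)
    return pd.DataFrame(
        {
            "barcode": list(counts.barcodes),
            "pann": score_doublets(counts, art_pann, config, "pann"),
            "knn_fraction": score_doublets(counts, art_sim, config, "knn_fraction"),
            "density_ratio": score_doublets(counts, art_sim, config, "density_ratio"),
        }
    )


def _percentile_ranks(medians: np.ndarray) -> np.ndarray:
    """Fraction of other clusters with strictly smaller median (ties share
    the lower rank, so identical distributions are never flagged)."""
    n = medians.size
    if n <= 1:
        return np.zeros(n)
    return np.array([(medians < m).sum() / (n - 1) for m in medians])


def adjudicate_clusters(
    score_table: pd.DataFrame,
    clusters,
    hybrid_calls: list[HybridCall] | None = None,
    rank_threshold: float = 0.8,
) -> tuple[list[ClusterAdjudication], list[HybridCall]]:
    """Rank cluster median scores per method and apply the 2-of-3 rule.

    Returns the per-cluster adjudications and the (possibly demoted)
    hybrid calls.  With a single cluster no comparison is possible: the
    cluster is returned unflagged.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != len(score_table):
        raise ValueError("clusters must align with the score table")
    frame = score_table.copy()
    frame["cluster"] = clusters
    med = frame.groupby("cluster", sort=True)[list(METHODS)].median()

    ranks = {m: _percentile_ranks(med[m].to_numpy()) for m in METHODS}
    adjudications = []
    flagged = set()
    for i, cl in enumerate(med.index):
        pr = {m: float(ranks[m][i]) for m in METHODS}
        n_elev = sum(pr[m] > rank_threshold for m in METHODS)
        is_flagged = len(med) > 1 and n_elev >= 2
        if is_flagged:
            flagged.add(cl)
        adjudications.append(
            ClusterAdjudication(
                cluster=cl,
                median_scores={m: float(med[m].iloc[i]) for m in METHODS},
                percentile_ranks=pr,
                flagged_doublet=is_flagged,
                n_methods_elevated=n_elev,
            )
        )

    updated = []
    for call in hybrid_calls or []:
        if call.is_hybrid and call.cluster in flagged:
            call.is_hybrid = False
            call.demotion_reason = (
                "cluster doublet-score percentile rank exceeded "
                f"{rank_threshold} in >= 2 of 3 methods"
            )
        updated.append(call)
    return adjudications, updated
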