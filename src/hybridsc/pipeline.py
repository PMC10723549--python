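"""End-to-end per-sample hybrid detection: preprocess -> score -> call -> guard.

Chains the module stages in the order a per-sample analysis runs them:
gene filtering, normalization, PCA + Leiden clustering, lineage marker
derivation and module scoring, cluster-level hybrid calling, and the
doublet-score consensus adjudication that can demote a call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .doublets import ClusterAdjudication, DoubletConfig, adjudicate_clusters, doublet_scores
from .hybrid_calls import HybridCall, call_hybrid_clusters, summarize_clusters
from .io import CountMatrix
from .preprocess import Embedding, cluster, embed, normalize, qc_filter
from .scoring import ScoreConfig, rank_lineage_markers, score_lineages

__all__ = ["SampleResult", "analyze_sample"]


@dataclass
class SampleResult:
    """Everything one sample's run produces."""

    adata: ad.AnnData
    embedding: Embedding
    scores: pd.DataFrame
    summaries: pd.DataFrame
    calls: list[HybridCall]
    adjudications: list[ClusterAdjudication]
    tumor_markers: list[str] = field(default_factory=list)
    macrophage_markers: list[str] = field(default_factory=list)
    marker_de: pd.DataFrame | None = None
    doublet_table: pd.DataFrame | None = None

    @property
    def hybrid_clusters(self) -> list[int]:
        return [c.cluster for c in self.calls if c.is_hybrid]

    @property
    def cluster_labels(self) -> np.ndarray:
        return self.embedding.cluster_labels


def analyze_sample(
    counts: CountMatrix,
    annotations,
    min_cells: int = 3,
    n_top_markers: int = 50,
    score_config: ScoreConfig | None = None,
    doublet_config: DoubletConfig | None = None,
    resolution: float = 1.0,
    k_neighbors: int = 20,
    alpha: float = 0.05,
    rank_threshold: float = 0.8,
    seed: int = 0,
    run_doublet_guard: bool = True,
) -> SampleResult:
    """Run the full hybrid-detection chain on one sample.

    ``annotations`` holds the per-cell lineage annotation (tumor,
    macrophage, other_immune, stromal, unassigned) aligned with the
    columns of ``counts``.  The doublet guard is scored on the filtered
    counts and adjudicated against the Leiden clusters.
    """
    annotations = np.asarray(annotations, dtype=object)
    if annotations.shape[0] != counts.n_cells:
        raise ValueError("annotations must align with count matrix columns")
    score_config = score_config or ScoreConfig(seed=seed)
    doublet_config = doublet_config or DoubletConfig(seed=seed)

    filtered = qc_filter(counts, min_cells=min_cells)
    adata = normalize(filtered)
    adata.obs["annotation"] = annotations

    embedding = embed(adata, random_state=seed)
    embedding = cluster(embedding, k_neighbors=k_neighbors, resolution=resolution, seed=seed)
    labels = embedding.cluster_labels
    adata.obs["cluster"] = labels

    tumor_markers, macrophage_markers, marker_de = rank_lineage_markers(
        adata, annotations, "tumor", "macrophage", n_top=n_top_markers
    )
    scores = score_lineages(adata, tumor_markers, macrophage_markers, score_config)
    summaries = summarize_clusters(scores, labels, annotations)
    calls = call_hybrid_clusters(summaries, scores, labels, alpha=alpha)

    adjudications: list[ClusterAdjudication] = []
    dbl_table = None
    if run_doublet_guard:
        dbl_table = doublet_scores(filtered, doublet_config)
        adjudications, calls = adjudicate_clusters(
            dbl_table, labels, calls, rank_threshold=rank_threshold
        )

    return SampleResult(
        adata=adata,
        embedding=embedding,
        scores=scores,
        summaries=summaries,
        calls=calls,
        adjudications=adjudications,
        tumor_markers=tumor_markers,
        macrophage_markers=macrophage_markers,
        marker_de=marker_de,
        doublet_table=dbl_table,
    )
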