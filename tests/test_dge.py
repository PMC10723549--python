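"""Differential expression, the shared-panel rules and hypergeometric ORA."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from hybridsc import syndata
from hybridsc.dge import (
    PanelSelectionConfig,
    differential_expression,
    overrepresentation,
    select_shared_panel,
)

from conftest import make_adata


class TestDifferentialExpression:
    def test_exact_p_matches_enumeration(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        adata = make_adata(X)
        table = differential_expression(adata, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        assert table["p_value"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_null_genes_flat_under_label_permutation(self):
        rng = np.random.default_rng(0)
        X = np.log1p(rng.lognormal(size=(200, 30)))  # log-normalized scale
        adata = make_adata(X)
        names = list(adata.obs_names)
        table = differential_expression(adata, names[:100], names[100:])
        assert np.abs(table["log2fc"]).max() < 0.5
        assert (table["p_adjusted"] > 0.5).mean() > 0.9

    def test_overlapping_groups_rejected(self):
        adata = make_adata(np.ones((6, 2)))
        with pytest.raises(ValueError):
            differential_expression(adata, ["c0", "c1", "c2"], ["c2", "c3", "c4"])

    def test_threshold_tiers_select_different_lists(self):
        """A gene with lfc 0.9 at adjusted p 0.01 misses the gene-panel
        cut (|lfc| >= 1) but enters the pathway list (|lfc| >= 0.58)."""
        row = pd.DataFrame(
            {"gene": ["x"], "log2fc": [0.9], "p_value": [0.001], "p_adjusted": [0.01],
             "pct_a": [0.9], "pct_b": [0.1]}
        )
        cfg = PanelSelectionConfig(min_samples_shared=1)
        panel = select_shared_panel({"s1": (row, None)}, cfg)
        assert "x" not in set(panel["gene"])
        pathway_pass = (row["p_adjusted"] <= cfg.alpha_adj) & (
            row["log2fc"].abs() >= cfg.lfc_pathway
        )
        assert pathway_pass.all()

    def test_planted_hybrid_genes_recovered(self, default_normalized):
        adata, truth = default_normalized
        pop = truth["population"].to_numpy()
        bars = truth["barcode"].to_numpy()
        table = differential_expression(
            adata, list(bars[pop == "hybrid"]), list(bars[pop == "tumor"])
        )
        up = set(table[(table.p_adjusted <= 0.05) & (table.log2fc >= 1.0)]["gene"])
        planted = set(syndata.HYBRID_BOOST_SEED) | {f"HYB{j + 1:03d}" for j in range(10, 40)}
        assert len(up & planted) / len(planted) >= 0.8


def de_row(gene, lfc, padj):
    return {"gene": gene, "log2fc": lfc, "p_value": padj / 10, "p_adjusted": padj,
            "pct_a": 0.5, "pct_b": 0.5}


class TestSharedPanel:
    def test_gene_shared_in_two_of_five_samples_retained(self):
        tables = {}
        for i in range(5):
            rows = [de_row("shared", 2.0, 0.01)] if i < 2 else [de_row("shared", 2.0, 0.5)]
            tables[f"s{i}"] = (pd.DataFrame(rows), pd.DataFrame([de_row("m", 0.0, 1.0)]))
        panel = select_shared_panel(tables)
        assert set(panel["gene"]) == {"shared"}
        assert panel["n_samples"].iloc[0] == 2

    def test_top_k_rule_caps_up_vs_tumor(self):
        genes = [f"g{i:02d}" for i in range(30)]
        rows = [de_row(g, 2.0, 0.001 * (i + 1)) for i, g in enumerate(genes)]
        tables = {s: (pd.DataFrame(rows), None) for s in ("a", "b")}
        panel = select_shared_panel(tables)
        up = panel[(panel.comparison == "vs_tumor") & (panel.direction == "up")]
        assert len(up) == 10
        assert set(up["gene"]) == set(genes[:10])  # best adjusted p first

    def test_down_vs_mac_needs_strong_fold(self):
        weak = de_row("weak", -1.2, 0.01)
        strong = de_row("strong", -2.5, 0.01)
        tables = {s: (None, pd.DataFrame([weak, strong])) for s in ("a", "b")}
        panel = select_shared_panel(tables)
        down = panel[(panel.comparison == "vs_macrophage") & (panel.direction == "down")]
        assert set(down["gene"]) == {"strong"}

    def test_empty_inputs_give_empty_panel(self):
        assert select_shared_panel({}).empty

    def test_relaxing_alpha_never_shrinks_panel(self):
        rng = np.random.default_rng(0)
        rows = [de_row(f"g{i}", rng.uniform(-3, 3), rng.uniform(0, 0.2)) for i in range(40)]
        tables = {s: (pd.DataFrame(rows), pd.DataFrame(rows)) for s in ("a", "b")}
        strict = select_shared_panel(tables, PanelSelectionConfig(alpha_adj=0.01, top_k_up_vs_tumor=1000))
        loose = select_shared_panel(tables, PanelSelectionConfig(alpha_adj=0.1, top_k_up_vs_tumor=1000))
        assert set(strict["gene"]) <= set(loose["gene"])

    def test_curated_include_list_appended(self):
        cfg = PanelSelectionConfig(include_genes=("GPX1",))
        panel = select_shared_panel({}, cfg)
        assert list(panel["gene"]) == ["GPX1"]


def brute_force_ora_p(M, K, n, k):
    """P(overlap >= k) by enumerating all C(M, n) draws."""
    universe = range(M)
    in_set = set(range(K))
    hits = sum(
        1 for draw in combinations(universe, n) if len(in_set & set(draw)) >= k
    )
    return hits / comb(M, n)


class TestOverrepresentation:
    def test_perfect_overlap_exact_probability(self):
        """M=10, K=5, n=5, k=5: a single draw of C(10,5)=252 achieves full
        overlap, so p = 1/252."""
        universe = [f"g{i}" for i in range(10)]
        sets = {"s": universe[:5]}
        out = overrepresentation(universe[:5], universe, sets)
        assert out["p_value"].iloc[0] == pytest.approx(1 / 252, rel=1e-12)
        assert brute_force_ora_p(10, 5, 5, 5) == pytest.approx(1 / 252)

    @pytest.mark.parametrize("M,K,n", [(8, 3, 4), (10, 4, 5), (12, 6, 3)])
    def test_matches_enumeration_oracle(self, M, K, n):
        universe = [f"g{i}" for i in range(M)]
        gene_list = universe[:n]
        sets = {"s": universe[: K]}
        out = overrepresentation(gene_list, universe, sets)
        k = len(set(gene_list) & set(universe[:K]))
        assert out["p_value"].iloc[0] == pytest.approx(brute_force_ora_p(M, K, n, k), rel=1e-10)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        out = overrepresentation(universe[:3], universe, {"s": universe[5:]})
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_set_recorded_with_zero_size(self):
        universe = ["a", "b", "c"]
        out = overrepresentation(["a"], universe, {"outside": ["x", "y"]})
        assert out["set_size_K"].iloc[0] == 0
        assert out["p_value"].iloc[0] == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation([], [], {"s": ["a"]})

    def test_adjusted_at_least_raw(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {f"s{j}": universe[j : j + 5] for j in range(10)}
        out = overrepresentation(universe[:5], universe, sets)
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()
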