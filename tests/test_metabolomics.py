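"""Univariate stats, the joint screen, clustering order, and ORA."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from herbnet.datasets import load_reference_metabolite_table
from herbnet.exceptions import InputError
from herbnet.metabolomics import (
    MetaboliteScreen,
    hclust_heatmap_order,
    ora_enrichment,
    screen_metabolites,
    univariate_stats,
)
from herbnet.simulate import MetaboSimSpec, gen_metabolites


class TestUnivariate:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        half = rng.lognormal(10, 0.2, size=(20, 4))
        X = pd.DataFrame(np.hstack([half, half]),
                         columns=[f"F{i}" for i in range(4)] + [f"C{i}" for i in range(4)])
        groups = pd.Series(["treated"] * 4 + ["control"] * 4, index=X.columns)
        stats = univariate_stats(X, groups)
        assert np.allclose(stats["fc"], 1.0)
        assert (stats["p_value"] > 0.99).all()

    def test_trend_follows_fold_change(self):
        table = load_reference_metabolite_table()
        assert table.loc["Citrulline", "fc"] == pytest.approx(127.97)
        assert table.loc["Citrulline", "trend"] == "up"
        assert table.loc["L-Arginine", "fc"] == pytest.approx(0.06)
        assert table.loc["L-Arginine", "trend"] == "down"
        # recompute trend from fc across all 47 rows
        assert (np.where(table["fc"] > 1, "up", "down") == table["trend"]).all()

    def test_zero_control_mean_rejected(self):
        X = pd.DataFrame([[1.0, 1.0, 0.0, 0.0]], columns=["F1", "F2", "C1", "C2"])
        groups = pd.Series(["treated"] * 2 + ["control"] * 2, index=X.columns)
        with pytest.raises(InputError):
            univariate_stats(X, groups)


class TestScreen:
    def test_reference_table_counts(self):
        table = load_reference_metabolite_table()
        out = screen_metabolites(table[["p_value", "fc", "trend"]], table["vip"])
        assert int(out["passes"].sum()) == 47
        assert int((out["passes"] & (out["fc"] > 1)).sum()) == 31
        assert int((out["passes"] & (out["fc"] < 1)).sum()) == 16

    def test_one_sided_rule_drops_downregulated(self):
        table = load_reference_metabolite_table()
        out = screen_metabolites(
            table[["p_value", "fc", "trend"]], table["vip"], fc_mode="greater"
        )
        assert int(out["passes"].sum()) == 31

    def test_misaligned_ids_rejected(self):
        table = load_reference_metabolite_table()
        vip = table["vip"].iloc[:-1]
        with pytest.raises(InputError):
            screen_metabolites(table[["p_value", "fc", "trend"]], vip)

    def test_estimator_recovers_planted_metabolites(self, planted_metabolites):
        X, groups, truth = planted_metabolites
        screen = MetaboliteScreen().fit(X, groups)
        assert screen.results_.loc[truth, "passes"].all()
        assert screen.n_up_ >= 10  # all planted shifts are upward

    def test_thresholds_are_strict(self):
        stats = pd.DataFrame(
            {"p_value": [0.05, 0.01], "fc": [2.0, 1.0], "trend": ["up", "up"]},
            index=["a", "b"],
        )
        vip = pd.Series([1.0, 3.0], index=["a", "b"])
        out = screen_metabolites(stats, vip)
        # a: p not < 0.05 and vip not > 1; b: fc neither > 1 nor < 1
        assert not out["passes"].any()


class TestHclust:
    def test_identical_samples_adjacent(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.lognormal(10, 0.5, size=(10, 5)),
                         columns=list("abcde"))
        X["f"] = X["c"]  # duplicate sample -> zero distance
        order = hclust_heatmap_order(X)["col_order"]
        assert abs(order.index("c") - order.index("f")) == 1

    def test_planted_groups_cluster_contiguously(self):
        # ~20% differential metabolites, the regime where a treated-vs-
        # control heatmap shows distinct sample clustering
        X, groups, _ = gen_metabolites(MetaboSimSpec(n_diff=40, seed=9))
        order = hclust_heatmap_order(X)["col_order"]
        labels = [groups[s] for s in order]
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)

    def test_z_rows_standardised(self):
        X, _, _ = gen_metabolites(MetaboSimSpec(n_metabolites=30, seed=2))
        z = hclust_heatmap_order(X)["z"]
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_zero_variance_row_excluded(self):
        X, _, _ = gen_metabolites(MetaboSimSpec(n_metabolites=20, seed=3))
        X.iloc[0] = 5.0
        out = hclust_heatmap_order(X)
        assert X.index[0] not in out["z"].index

    def test_single_row_rejected(self):
        with pytest.raises(InputError):
            hclust_heatmap_order(pd.DataFrame([[1.0, 2.0]]))


class TestORA:
    def test_closed_form_example(self):
        # universe 10, pathway 5, 3 hits all inside: C(5,3)/C(10,3) = 10/120
        universe = {f"m{i}" for i in range(10)}
        pathway = {f"m{i}" for i in range(5)}
        hits = {"m0", "m1", "m2"}
        out = ora_enrichment(hits, universe, {"pw": pathway})
        assert out["p_value"].iloc[0] == pytest.approx(10 / 120)

    def test_pathway_equals_universe(self):
        u = {"a", "b", "c"}
        out = ora_enrichment({"a"}, u, {"all": u})
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_empty_hits(self):
        u = {"a", "b", "c", "d"}
        out = ora_enrichment(set(), u, {"pw1": {"a"}, "pw2": {"b", "c"}})
        assert (out["p_value"] == 1.0).all()

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(InputError):
            ora_enrichment({"zzz"}, {"a", "b"}, {})

    def test_matches_exhaustive_enumeration(self):
        # brute force: enumerate every hit set of the observed size and
        # count those with at least as many pathway members
        rng = np.random.default_rng(31)
        for _ in range(5):
            N = int(rng.integers(6, 13))
            universe = [f"m{i}" for i in range(N)]
            pathway = set(rng.choice(universe, size=int(rng.integers(2, N)), replace=False))
            n = int(rng.integers(1, N))
            hits = set(rng.choice(universe, size=n, replace=False))
            k = len(hits & pathway)
            total = math.comb(N, n)
            count = sum(
                1 for s in combinations(universe, n) if len(set(s) & pathway) >= k
            )
            out = ora_enrichment(hits, set(universe), {"pw": pathway})
            assert out["p_value"].iloc[0] == pytest.approx(count / total, abs=1e-12)

    def test_bh_column_present_when_requested(self):
        u = {f"m{i}" for i in range(8)}
        out = ora_enrichment({"m0", "m1"}, u, {"a": {"m0"}, "b": {"m3", "m4"}},
                             correct=True)
        assert "p_adj" in out.columns
        assert (out["p_adj"] >= out["p_value"] - 1e-12).all()
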