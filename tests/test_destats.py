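"""NB differential test, threshold presets, length association, clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from elongrec import (
    PRESETS,
    SimConfig,
    apply_preset,
    cluster_patterns,
    length_association,
    log2ratio_matrix,
    nb_de_test,
    simulate,
)
from elongrec.errors import ParameterError, ValidationError


from _oracles import brute_force_bh, naive_average_linkage_heights


class TestNbDeTest:
    def test_log2fc_uses_declared_pseudocount(self):
        assert math.log2((20 + 0.5) / (5 + 0.5)) == pytest.approx(1.898, abs=5e-4)

    def test_detects_planted_fold_change(self):
        rng = np.random.default_rng(0)
        n = 500
        mu = rng.uniform(20, 200, n)
        fold = np.ones(n)
        fold[:50] = 4.0
        size = 1 / 0.05
        a = rng.negative_binomial(size, size / (size + mu[:, None]), size=(n, 3))
        b = rng.negative_binomial(
            size, size / (size + (mu * fold)[:, None]), size=(n, 3)
        )
        df = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"f{i}" for i in range(n)],
            columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
        )
        res = nb_de_test(df, [f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)])
        up, down = apply_preset(res, "transcript_preset")
        planted = {f"f{i}" for i in range(50)}
        called_planted = len(up & planted) / 50
        assert called_planted >= 0.9
        assert len(up - planted) <= 10  # few false calls among 450 nulls

    def test_fewer_than_two_replicates_rejected(self):
        df = pd.DataFrame({"a1": [5], "b1": [5], "b2": [6]}, index=["f"])
        with pytest.raises(ParameterError):
            nb_de_test(df, ["a1"], ["b1", "b2"])

    def test_null_comparison_well_calibrated(self):
        from elongrec.studies import de_null_study

        out = de_null_study(seed=17, n_features=1000)
        assert abs(out["type1_at_0.05"] - 0.05) <= 0.025
        assert out["calls_transcript_preset"] == 0
        assert out["calls_kcl_preset"] == 0


class TestBenjaminiHochberg:
    def test_known_example_flattens_to_max(self):
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)
        assert np.allclose(brute_force_bh([0.01, 0.02, 0.03, 0.04]), adj)

    @settings(max_examples=60, deadline=None)
    @given(
        pvals=st.lists(
            st.floats(min_value=1e-8, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_matches_brute_force_and_permutation_invariant(self, pvals):
        adj = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(adj, brute_force_bh(pvals))
        perm = list(reversed(pvals))
        adj_perm = multipletests(perm, method="fdr_bh")[1]
        assert np.allclose(adj_perm, list(reversed(adj)))
        assert np.all(adj >= np.asarray(pvals) - 1e-12)


class TestApplyPreset:
    def _frame(self, log2fc, padj):
        return pd.DataFrame(
            {"log2fc": [log2fc], "padj": [padj], "stat": [0.0]}, index=["f"]
        )

    @pytest.mark.parametrize(
        "log2fc,padj,preset,expect_up,expect_down",
        [
            (1.0, 0.10, "transcript_preset", True, False),  # inclusive boundaries
            (0.99, 0.10, "transcript_preset", False, False),
            (-2.0, 0.5, "transcript_preset", False, False),
            (math.log2(1.49), 0.01, "kcl_preset", False, False),
            (math.log2(1.5), 0.05, "kcl_preset", True, False),
            (-math.log2(1.5), 0.05, "kcl_preset", False, True),
        ],
    )
    def test_printed_rules_inclusive(self, log2fc, padj, preset, expect_up, expect_down):
        up, down = apply_preset(self._frame(log2fc, padj), preset)
        assert ("f" in up) is expect_up
        assert ("f" in down) is expect_down

    def test_up_down_disjoint(self):
        rng = np.random.default_rng(5)
        res = pd.DataFrame(
            {
                "log2fc": rng.normal(0, 2, 100),
                "padj": rng.uniform(0, 1, 100),
                "stat": rng.normal(0, 3, 100),
            },
            index=[f"f{i}" for i in range(100)],
        )
        up, down = apply_preset(res, "transcript_preset")
        assert up & down == set()

    def test_unknown_preset_rejected(self):
        with pytest.raises(ParameterError):
            apply_preset(self._frame(2.0, 0.01), "bogus_preset")


class TestLengthAssociation:
    def test_exact_anticorrelation(self):
        lengths = {f"f{i}": 10 ** (3 + i) for i in range(5)}
        res = pd.DataFrame(
            {
                "log2fc": [-2.0] * 5,
                "padj": [0.01] * 5,
                "stat": [-math.log10(lengths[f"f{i}"]) for i in range(5)],
            },
            index=[f"f{i}" for i in range(5)],
        )
        res["called"] = True
        res["direction"] = "down"
        out = length_association(res, lengths, "down")
        assert out["R"] == pytest.approx(-1.0)

    def test_null_statistic_uncorrelated_with_length(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 1000
            lengths = {f"f{i}": int(10 ** rng.uniform(3, 5.5)) for i in range(n)}
            res = pd.DataFrame(
                {
                    "log2fc": rng.normal(-2, 0.1, n),
                    "padj": rng.uniform(0, 0.05, n),
                    "stat": rng.normal(0, 1, n),
                },
                index=[f"f{i}" for i in range(n)],
            )
            res["called"] = True
            res["direction"] = "down"
            out = length_association(res, lengths, "down")
            hits += abs(out["R"]) < 0.1
        assert hits >= 19

    def test_simulated_block_makes_down_set_longer(self):
        from elongrec.studies import length_association_study

        out = length_association_study(seed=31)
        assert out["R"] < 0
        assert out["mean_length_down"] > out["mean_length_up"]

    def test_too_few_called_rejected(self):
        res = pd.DataFrame(
            {"log2fc": [1.0], "padj": [0.01], "stat": [1.0]}, index=["f"]
        )
        res["called"] = True
        res["direction"] = "up"
        with pytest.raises(ValidationError):
            length_association(res, {"f": 1000}, "up")




class TestClusterPatterns:
    def _pattern_matrix(self, n_per=20, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        conds = ["R0", "R15", "R30"]
        cols = pd.MultiIndex.from_tuples(
            [(g, c) for g in ("WT", "AT") for c in conds], names=["group", "condition"]
        )
        # planted archetypes as (WT profile, AT profile) in log2 ratio units
        templates = {
            "similar_both": ([1, 1, 1], [1, 1, 1]),
            "up_in_AT": ([0, 0, 0], [2, 2, 2]),
            "up_in_AT_after_washout": ([0, 0, 0], [0, 2, 2]),
            "down_in_AT": ([1, 1, 1], [-1, -1, -1]),
        }
        rows, index, labels = [], [], []
        for name, (wt, at) in templates.items():
            for k in range(n_per):
                rows.append(np.concatenate([wt, at]) + rng.normal(0, noise, 6))
                index.append(f"{name}_{k}")
                labels.append(name)
        return pd.DataFrame(rows, index=index, columns=cols), labels

    def test_recovers_planted_archetypes(self):
        mat, labels = self._pattern_matrix()
        clusters = cluster_patterns(mat, k=4)
        assert len(clusters) == 4
        found = {c.archetype for c in clusters}
        assert found == {
            "similar_both",
            "up_in_AT",
            "up_in_AT_after_washout",
            "down_in_AT",
        }
        for c in clusters:
            planted = {m.rsplit("_", 1)[0] for m in c.members}
            assert planted == {c.archetype}

    def test_clusters_partition_features(self):
        mat, _ = self._pattern_matrix(n_per=5)
        clusters = cluster_patterns(mat, k=4)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(mat.index)

    def test_identical_rows_stay_together(self):
        mat, _ = self._pattern_matrix(n_per=3, noise=0.2, seed=1)
        mat.loc["dup_a"] = mat.iloc[0]
        mat.loc["dup_b"] = mat.iloc[0]
        for k in (2, 3, 4):
            clusters = cluster_patterns(mat, k=k)
            where = {
                c.cluster_id for c in clusters if {"dup_a", "dup_b"} & set(c.members)
            }
            assert len(where) == 1

    def test_merge_heights_match_naive_agglomeration(self):
        rng = np.random.default_rng(7)
        points = rng.normal(0, 1, size=(6, 4))
        from scipy.cluster.hierarchy import linkage

        z = linkage(points, method="average", metric="euclidean")
        assert np.allclose(sorted(z[:, 2]), naive_average_linkage_heights(points))

    def test_non_finite_rejected(self):
        mat, _ = self._pattern_matrix(n_per=3)
        mat.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError):
            cluster_patterns(mat, k=2)

    def test_log2ratio_matrix_shape_and_baseline(self, small_sim):
        mat = log2ratio_matrix(small_sim.counts)
        assert list(mat.columns.names) == ["group", "condition"]
        assert set(mat.columns.get_level_values("condition")) == {"R0", "R15", "R30"}
        assert set(mat.columns.get_level_values("group")) == {"WT", "AT"}
        assert np.all(np.isfinite(mat.to_numpy()))
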