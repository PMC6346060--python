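"""Pearson screening, ICC comparison, and wavefront estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from elongrec import (
    BEYOND_TRANSCRIPT_END,
    CoverageProfile,
    SimConfig,
    build_profiles,
    changed_set,
    detect_changed,
    dissimilarities,
    estimate_wavefront,
    icc_compare,
    profile_pearson,
    simulate,
)
from elongrec.errors import ParameterError, ValidationError
from elongrec.profiles import ProfileSet


from _oracles import naive_pearson


def prof(values, tid="t", sid="s", exon_len=100.0):
    values = np.asarray(values, dtype=float)
    return CoverageProfile(tid, sid, values, np.full(values.size, exon_len))


class TestProfilePearson:
    def test_identity_gives_one(self):
        p = prof([1, 2, 3, 4])
        assert profile_pearson(p, prof([1, 2, 3, 4])) == pytest.approx(1.0)

    def test_exact_anti_order_gives_minus_one(self):
        assert profile_pearson(prof([1, 2, 3, 4]), prof([4, 3, 2, 1])) == pytest.approx(-1.0)

    def test_zero_variance_is_undefined(self):
        assert profile_pearson(prof([2, 2, 2, 2]), prof([1, 2, 3, 4])) is None

    def test_matches_independent_oracle_on_block_toy(self):
        # flat untreated profile vs exp(-lam x) at midpoints of a 6-exon toy
        lam = 1e-3
        mids = np.arange(6) * 500.0 + 250.0
        flat = [1.0, 1.1, 0.9, 1.05, 0.95, 1.0]
        blocked = np.exp(-lam * mids)
        got = profile_pearson(prof(flat, exon_len=500), prof(blocked, exon_len=500))
        assert got == pytest.approx(naive_pearson(flat, blocked), rel=1e-12)

    def test_mismatched_transcripts_rejected(self):
        with pytest.raises(ValidationError):
            profile_pearson(prof([1, 2, 3], tid="a"), prof([1, 2, 3], tid="b"))


def _pset_from_matrices(matrices, meta):
    """Build a ProfileSet directly from specimen-by-exon matrices."""
    n_exons = next(iter(matrices.values())).shape[1]
    return ProfileSet(
        densities=matrices,
        exon_lengths={k: np.full(m.shape[1], 100.0) for k, m in matrices.items()},
        specimens=list(meta.index),
        meta=meta,
    )


def _meta(rows):
    return pd.DataFrame(
        rows, columns=["specimen_id", "group", "condition", "replicate"]
    ).set_index("specimen_id")


class TestDetectChanged:
    meta = None

    def setup_method(self):
        self.meta = _meta(
            [
                ("u1", "WT", "Untr", 1),
                ("u2", "WT", "Untr", 2),
                ("t1", "WT", "R0", 1),
                ("t2", "WT", "R0", 2),
            ]
        )

    def test_changed_requires_all_pairs_below_threshold(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        # treated replicate 1 anti-correlates, replicate 2 correlates
        mats = {"t": np.vstack([base, base * 1.1, base[::-1], base])}
        calls = detect_changed(_pset_from_matrices(mats, self.meta), "WT")
        assert calls[0].changed is False  # one pair at r=1 vetoes

        mats2 = {"t": np.vstack([base, base * 1.1, base[::-1], base[::-1] * 0.9])}
        calls2 = detect_changed(_pset_from_matrices(mats2, self.meta), "WT")
        assert calls2[0].changed is True

    def test_undefined_pair_vetoes_changed(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        flat = np.full(4, 2.0)
        mats = {"t": np.vstack([base, base, flat, base[::-1]])}
        calls = detect_changed(_pset_from_matrices(mats, self.meta), "WT")
        assert calls[0].changed is False
        assert np.isnan(calls[0].r_values).sum() == 2

    def test_treated_equal_untreated_not_changed(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        mats = {"t": np.vstack([base, base, base, base])}
        calls = detect_changed(_pset_from_matrices(mats, self.meta), "WT")
        assert calls[0].changed is False
        assert np.allclose(calls[0].r_values, 1.0)

    def test_missing_condition_rejected(self):
        meta = _meta([("u1", "WT", "Untr", 1), ("u2", "WT", "Untr", 2)])
        mats = {"t": np.ones((2, 4))}
        with pytest.raises(ParameterError):
            detect_changed(_pset_from_matrices(mats, meta), "WT")

    def test_monotone_in_threshold(self, small_profiles):
        pset, _ = small_profiles
        tight = changed_set(detect_changed(pset, "WT", threshold=0.1))
        loose = changed_set(detect_changed(pset, "WT", threshold=0.2))
        assert tight <= loose


class TestIccCompare:
    def test_identical_groups_perfect_agreement_no_difference(self):
        d = pd.Series([0.1, 0.5, 0.9, 0.3, 0.7], index=list("abcde"))
        res = icc_compare(d, d.copy(), n_perm=500, seed=0)
        assert res.icc == pytest.approx(1.0)
        assert np.allclose(res.per_transcript_delta, 0.0)
        assert res.consistent_difference is False

    def test_independent_vectors_have_small_icc(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            idx = [f"t{i}" for i in range(200)]
            d_a = pd.Series(rng.uniform(0, 1, 200), index=idx)
            d_b = pd.Series(rng.uniform(0, 1, 200), index=idx)
            res = icc_compare(d_a, d_b, n_perm=200, seed=seed)
            hits += abs(res.icc) < 0.2
        assert hits >= 38  # >= 95% of runs

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(1)
        idx = [f"t{i}" for i in range(50)]
        d_b = pd.Series(rng.uniform(0.1, 0.5, 50), index=idx)
        d_a = d_b + 0.4
        res = icc_compare(d_a, d_b, n_perm=1000, seed=2)
        assert res.consistent_difference is True
        assert res.mean_delta == pytest.approx(0.4)

    def test_swapping_groups_negates_delta_keeps_abs_icc(self):
        rng = np.random.default_rng(3)
        idx = [f"t{i}" for i in range(30)]
        d_a = pd.Series(rng.uniform(0, 1, 30), index=idx)
        d_b = pd.Series(rng.uniform(0, 1, 30), index=idx)
        r1 = icc_compare(d_a, d_b, n_perm=200, seed=4)
        r2 = icc_compare(d_b, d_a, n_perm=200, seed=4)
        assert r1.icc == pytest.approx(r2.icc)
        assert np.allclose(r1.per_transcript_delta, -r2.per_transcript_delta)

    def test_too_few_shared_transcripts_rejected(self):
        d_a = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ParameterError):
            icc_compare(d_a, d_a.copy(), n_perm=10, seed=0)


class TestDissimilarities:
    def test_range_and_perfect_agreement(self):
        meta = _meta(
            [
                ("u1", "WT", "Untr", 1),
                ("u2", "WT", "Untr", 2),
                ("r1", "WT", "R15", 1),
                ("r2", "WT", "R15", 2),
            ]
        )
        base = np.array([1.0, 3.0, 2.0, 5.0])
        mats = {"t": np.vstack([base, base, base, base])}
        d = dissimilarities(_pset_from_matrices(mats, meta), "WT")
        assert d["t"] == pytest.approx(0.0)

    def test_simulated_dissimilarities_in_range(self, small_profiles):
        pset, _ = small_profiles
        d = dissimilarities(pset, "WT")
        vals = d.dropna().to_numpy()
        assert np.all((vals >= 0.0) & (vals <= 2.0))


class TestEstimateWavefront:
    def test_full_recovery_returns_beyond_end(self):
        untr = prof([1.0, 1.2, 0.9, 1.1, 1.0])
        assert estimate_wavefront(untr, prof(untr.values.copy())) == BEYOND_TRANSCRIPT_END

    def test_matches_brute_force_scan_on_toy(self):
        # 8 exons of 100 nt; step from ~1 to ~0.2 after the 5th exon
        untr = prof([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        ratio = np.array([1.02, 0.97, 1.01, 0.99, 1.03, 0.21, 0.18, 0.2])
        rec = prof(ratio * untr.values)
        got = estimate_wavefront(untr, rec)

        # independent brute-force changepoint scan
        mids = untr.midpoints
        best, best_sse = None, np.inf
        for j in range(1, 8):
            hi, lo = ratio[:j].mean(), ratio[j:].mean()
            sse = ((ratio[:j] - hi) ** 2).sum() + ((ratio[j:] - lo) ** 2).sum()
            if sse < best_sse:
                best, best_sse = j, sse
        expected = (mids[best - 1] + mids[best]) / 2.0
        assert got == pytest.approx(expected)
        assert got == pytest.approx(500.0)

    def test_noiseless_simulation_recovers_wavefront(self):
        from elongrec.studies import wavefront_study

        out = wavefront_study(seed=21, noiseless=True, n_transcripts=20)
        assert out["n"] >= 5
        assert out["max_abs_err_exon_spans"] <= 1.0

    def test_unstable_ratio_rejected(self):
        untr = prof([0.0, 0.0, 0.0, 1.0, 1.0])
        rec = prof([0.0, 0.0, 0.0, 0.5, 0.5])
        with pytest.raises(ValidationError):
            estimate_wavefront(untr, rec)

    def test_too_few_exons_rejected(self):
        with pytest.raises(ValidationError):
            estimate_wavefront(prof([1, 1, 1]), prof([1, 1, 0.1]))
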