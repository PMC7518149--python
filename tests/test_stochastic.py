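"""Conditional entropies, variance and within-day permutation nulls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import milkorder as mo
from milkorder.stochastic import Segmentation, _entropy_bits


def label_frame(rows):
    """Label DataFrame from a list of per-cow segment sequences (None=missing)."""
    return pd.DataFrame(rows).astype("Float64").astype("Int64")


class TestSegmentation:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.03, 1), (0.05, 1), (0.051, 2), (1.0, 20), (0.951, 20), (0.95, 19)],
    )
    def test_boundaries_half_open(self, value, expected):
        assert Segmentation(20).labels_of(np.array([value]))[0] == expected

    def test_simulated_quantiles_never_escape_range(self, small_qm):
        lab = mo.segment_labels(small_qm)
        ok = lab.stack().dropna()
        assert ok.min() >= 1 and ok.max() <= 20

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            Segmentation(20).labels_of(np.array([0.0]))
        with pytest.raises(ValueError, match="outside"):
            Segmentation(20).labels_of(np.array([1.2]))


class TestSegmentEntropy:
    def test_uniform_114_cows_is_log2_114(self):
        # 114 cows each seen once in segment 1: maximal stochasticity
        lab = label_frame([[1]] * 114)
        h = mo.segment_entropy(lab, n_segments=1)
        assert h.loc[1] == pytest.approx(np.log2(114))
        assert round(float(h.loc[1]), 2) == 6.83

    def test_single_cow_degenerate(self):
        lab = label_frame([[1] * 50])
        assert mo.segment_entropy(lab, n_segments=1).loc[1] == 0.0

    def test_two_cows_twice_each_is_one_bit(self):
        lab = label_frame([[1, 1], [1, 1]])
        assert mo.segment_entropy(lab, n_segments=1).loc[1] == pytest.approx(1.0)

    def test_empty_segment_reported_missing(self):
        lab = label_frame([[1], [1]])
        with pytest.warns(UserWarning, match="empty segment"):
            h = mo.segment_entropy(lab, n_segments=3)
        assert np.isnan(h.loc[2]) and np.isnan(h.loc[3])


class TestCowEntropy:
    def test_uniform_20_segments_is_log2_20(self):
        lab = label_frame([list(range(1, 21))])
        h = mo.cow_entropy(lab, n_segments=20)
        assert h.iloc[0] == pytest.approx(np.log2(20))
        assert round(float(h.iloc[0]), 2) == 4.32

    def test_constant_cow_zero(self):
        lab = label_frame([[7] * 30])
        assert mo.cow_entropy(lab, n_segments=20).iloc[0] == 0.0

    def test_bimodal_first_or_last_is_one_bit(self):
        # always first or always last: variance maximal, entropy only 1 bit
        lab = label_frame([[1, 20] * 10])
        assert mo.cow_entropy(lab, n_segments=20).iloc[0] == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        seq = rng.integers(1, 21, 40)
        perm = rng.permutation(20) + 1
        h1 = mo.cow_entropy(label_frame([seq]), n_segments=20).iloc[0]
        h2 = mo.cow_entropy(label_frame([perm[seq - 1]]), n_segments=20).iloc[0]
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_bounds_on_simulated_herd(self, small_qm):
        h = mo.cow_entropy(mo.segment_labels(small_qm), n_segments=20)
        assert (h.dropna() >= 0).all()
        assert (h.dropna() <= np.log2(20) + 1e-12).all()


class TestCowVariance:
    def test_constant_is_zero(self, make_qm):
        qm = make_qm(np.full((1, 10), 0.4))
        assert mo.cow_variance(qm).iloc[0] == 0.0

    def test_two_point_closed_form(self, make_qm):
        n = 10
        qm = make_qm([np.tile([1e-9, 1.0], n // 2)])
        assert mo.cow_variance(qm).iloc[0] == pytest.approx(0.25 * n / (n - 1), abs=1e-6)

    def test_matches_two_pass_oracle(self, make_qm):
        rng = np.random.default_rng(0)
        vals = rng.random((30, 25))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        got = mo.cow_variance(make_qm(vals))
        for i in range(30):
            row = vals[i][~np.isnan(vals[i])]
            if len(row) < 2:
                assert np.isnan(got.iloc[i])
                continue
            mean = row.sum() / len(row)
            oracle = ((row - mean) ** 2).sum() / (len(row) - 1)
            assert got.iloc[i] == pytest.approx(oracle, abs=1e-12)

    def test_single_observation_missing(self, make_qm):
        vals = np.full((1, 5), np.nan)
        vals[0, 0] = 0.3
        assert np.isnan(mo.cow_variance(make_qm(vals)).iloc[0])


class TestPermuteWithinDays:
    def test_day_multisets_preserved(self, small_qm):
        perm = mo.permute_within_days(small_qm, seed=4)
        for col in small_qm.days:
            a = np.sort(small_qm.values[col].dropna().to_numpy())
            b = np.sort(perm.values[col].dropna().to_numpy())
            assert np.array_equal(a, b)

    def test_missingness_pattern_preserved(self, small_qm):
        perm = mo.permute_within_days(small_qm, seed=4)
        assert (perm.values.isna() == small_qm.values.isna()).all().all()

    def test_same_seed_identical(self, small_qm):
        a = mo.permute_within_days(small_qm, seed=9)
        b = mo.permute_within_days(small_qm, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestPermutationPvalues:
    def test_highly_consistent_cow_gets_minimal_p(self, make_qm):
        # one perfectly consistent cow among exchangeable ones
        rng = np.random.default_rng(2)
        n, d = 20, 40
        vals = np.empty((n, d))
        for j in range(d):
            vals[:, j] = rng.permutation(np.arange(1, n + 1) / n)
        # pin cow 0 to the front every day, re-rank columns
        vals[0] = 0.001
        vals = np.argsort(np.argsort(vals, axis=0), axis=0) / n + 1.0 / n
        qm = make_qm(vals)
        B = 99
        p = mo.permutation_pvalues(qm, "entropy", B=B, seed=0)
        assert p.iloc[0] == pytest.approx(1.0 / (B + 1))

    def test_observed_equal_to_null_gives_p_one(self, make_qm):
        # constant matrix: every permutation leaves per-cow stats unchanged
        qm = make_qm(np.full((2, 6), 1.0))
        p = mo.permutation_pvalues(qm, "variance", B=19, seed=0)
        assert (p == 1.0).all()

    def test_same_seed_identical(self, small_qm):
        a = mo.permutation_pvalues(small_qm, "entropy", B=50, seed=7)
        b = mo.permutation_pvalues(small_qm, "entropy", B=50, seed=7)
        pd.testing.assert_series_equal(a, b)

    def test_entropy_detects_bimodality_variance_does_not(self, make_qm):
        # planted bimodal cow: front/rear alternation in an exchangeable herd
        rng = np.random.default_rng(8)
        n, d = 30, 60
        vals = np.empty((n, d))
        for j in range(d):
            vals[:, j] = rng.permutation(np.arange(1, n + 1) / n)
        ranks = np.argsort(np.argsort(vals, axis=0), axis=0)
        vals = (ranks + 1.0) / n
        # swap the bimodal cow into first/last position alternately
        for j in range(d):
            target = 0.0 if j % 2 == 0 else 1.0
            k = np.argmin(np.abs(vals[:, j] - target))
            vals[[0, k], j] = vals[[k, 0], j]
        qm = make_qm(vals)
        res = mo.QueueStochasticity(qm).fit(B=200, seed=1)
        row = res.per_cow.iloc[0]
        assert row["p_entropy"] <= 0.05  # entropy: clearly non-random
        assert row["p_variance"] > 0.5  # variance: looks maximally random
        assert row["variance"] > res.per_cow["variance"].iloc[1:].median()


class TestUShapeRecovery:
    def test_entropy_tracks_distance_from_center(self, small_qm):
        res = mo.QueueStochasticity(small_qm).fit(B=150, seed=2)
        pc = res.per_cow.dropna()
        rho = spearmanr(pc["H_c"], (pc["median_quantile"] - 0.5).abs()).statistic
        # consistency is highest at the queue extremes -> entropy rises
        # toward the center, so the correlation is strongly negative
        assert rho < -0.5

    def test_summary_mentions_reference_entropies(self, small_qm):
        res = mo.QueueStochasticity(small_qm).fit(B=20, seed=0)
        text = res.summary()
        assert "4.32" in text and "log2(20)" in text


def test_entropy_bits_helper_matches_scipy():
    from scipy.stats import entropy as scipy_entropy

    rng = np.random.default_rng(1)
    counts = rng.integers(0, 20, (10, 6)).astype(float)
    ours = _entropy_bits(counts, axis=-1)
    for i in range(10):
        c = counts[i][counts[i] > 0]
        assert ours[i] == pytest.approx(scipy_entropy(c, base=2), abs=1e-12)
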