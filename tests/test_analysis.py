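"""ROC/AUROC, Youden cut-off, Agreement Index and Spearman analyses against
independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import perimqc as pq
from perimqc.series import MaskSeries, RTVSeries


def make_series(values, subject="s"):
    values = np.asarray(values, float)
    return RTVSeries(subject, np.arange(float(len(values))), values)


def make_mask(bools, subject="s"):
    bools = np.asarray(bools, bool)
    return MaskSeries(subject, np.arange(float(len(bools))), bools, "error_rate", 2.0)


def brute_force_roc_point(x, y, c):
    pos, neg = x[y], x[~y]
    return np.mean(pos > c), np.mean(neg <= c)


def pair_ranking_auroc(x, y):
    """Mann-Whitney probability with ties half-counted, by full enumeration."""
    pos, neg = x[y], x[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPooledROC:
    def test_perfect_predictor_reaches_corner(self):
        y = np.array([0, 0, 1, 1, 0, 1], bool)
        curve = pq.pooled_roc([make_series(y.astype(float))], [make_mask(y)])
        j = curve.sensitivity + curve.specificity
        assert np.max(j) == pytest.approx(2.0)

    def test_degenerate_labels_rejected(self):
        y = np.zeros(5, bool)
        with pytest.raises(ValueError):
            pq.pooled_roc([make_series(np.arange(5.0))], [make_mask(y)])

    def test_curve_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 20))
            x = np.round(rng.uniform(0, 1, n), 2)  # force ties
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            curve = pq.pooled_roc([make_series(x)], [make_mask(y)])
            for c, sens, spec in zip(
                curve.thresholds, curve.sensitivity, curve.specificity
            ):
                bf_sens, bf_spec = brute_force_roc_point(x, y, c)
                assert sens == pytest.approx(bf_sens)
                assert spec == pytest.approx(bf_spec)

    def test_pooling_across_subjects_equals_concatenation(self):
        rng = np.random.default_rng(4)
        xs = [rng.uniform(0, 1, 30) for _ in range(3)]
        ys = [rng.random(30) < 0.3 for _ in range(3)]
        split = pq.pooled_roc(
            [make_series(x) for x in xs], [make_mask(y) for y in ys]
        )
        merged = pq.pooled_roc(
            [make_series(np.concatenate(xs))], [make_mask(np.concatenate(ys))]
        )
        assert np.array_equal(split.thresholds, merged.thresholds)
        assert np.allclose(split.sensitivity, merged.sensitivity)


class TestAUROC:
    def test_perfect_predictor_scores_one(self):
        y = np.array([0, 1, 0, 1], bool)
        curve = pq.pooled_roc([make_series(y.astype(float))], [make_mask(y)])
        assert pq.auroc(curve) == pytest.approx(1.0)

    def test_constant_predictor_scores_half(self):
        y = np.array([0, 1, 0, 1], bool)
        curve = pq.pooled_roc([make_series(np.ones(4))], [make_mask(y)])
        assert pq.auroc(curve) == pytest.approx(0.5)

    def test_equals_pair_ranking_probability(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            x = np.round(rng.uniform(0, 1, n), 1)
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            curve = pq.pooled_roc([make_series(x)], [make_mask(y)])
            assert pq.auroc(curve) == pytest.approx(pair_ranking_auroc(x, y))

    def test_label_independent_predictor_averages_half(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 60)
        aurocs = []
        for _ in range(200):
            y = np.zeros(60, bool)
            y[rng.choice(60, 20, replace=False)] = True
            curve = pq.pooled_roc([make_series(x)], [make_mask(y)])
            aurocs.append(pq.auroc(curve))
        se = np.std(aurocs) / np.sqrt(len(aurocs))
        assert abs(np.mean(aurocs) - 0.5) < 3 * se


class TestYouden:
    def test_perfect_separation_gives_j_of_one(self):
        x = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1], bool)
        curve = pq.pooled_roc([make_series(x)], [make_mask(y)])
        result = pq.youden_cutoff(curve, x)
        assert result.youden_j == pytest.approx(1.0)
        assert 0.2 <= result.cutoff < 0.8
        assert result.sensitivity == 1.0 and result.specificity == 1.0

    def test_matches_brute_force_threshold_search(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x = np.round(rng.uniform(0, 1, n), 2)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            curve = pq.pooled_roc([make_series(x)], [make_mask(y)])
            result = pq.youden_cutoff(curve, x)
            best_j = max(
                sum(brute_force_roc_point(x, y, c)) - 1.0 for c in np.unique(x)
            )
            assert result.youden_j == pytest.approx(best_j)

    def test_percentile_is_inclusive_cdf(self):
        x = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        y = np.array([0, 0, 0, 1, 1], bool)
        curve = pq.pooled_roc([make_series(x)], [make_mask(y)])
        result = pq.youden_cutoff(curve, x)
        assert result.percentile == pytest.approx(
            100.0 * np.mean(x <= result.cutoff)
        )


class TestDeviantMask:
    def test_cutoff_one_flags_nothing(self):
        series = make_series([0.0, 0.5, 1.0])
        assert not np.any(pq.deviant_value_mask(series, 1.0).mask)

    def test_cutoff_zero_flags_positive_values(self):
        series = make_series([0.1, 0.0, 0.9])
        assert list(pq.deviant_value_mask(series, 0.0).mask) == [True, False, True]

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        st.floats(min_value=0, max_value=1),
    )
    @settings(derandomize=True)
    def test_elementwise_strict_comparison(self, values, cutoff):
        mask = pq.deviant_value_mask(make_series(values), cutoff).mask
        assert list(mask) == [v > cutoff for v in values]


class TestAgreementIndex:
    def test_identical_masks_score_one(self):
        m = make_mask([1, 1, 0, 0, 1])
        assert pq.agreement_index(m, m).ai == pytest.approx(1.0)

    def test_disjoint_masks_score_zero(self):
        a = make_mask([1, 1, 0, 0])
        b = make_mask([0, 0, 1, 1])
        assert pq.agreement_index(a, b).ai == 0.0

    def test_interval_overlap_example(self):
        # A = [0,10) s, B = [5,15) s on a 1-s grid: 5 shared of 15 total
        t = np.arange(20.0)
        a = MaskSeries("s", t, (t >= 0) & (t < 10), "error_rate", 2.0)
        b = MaskSeries("s", t, (t >= 5) & (t < 15), "rtv", 0.15)
        result = pq.agreement_index(a, b)
        assert result.ai == pytest.approx(5.0 / 15.0)
        assert result.seconds_in_intersection == 5.0
        assert result.seconds_in_union == 15.0

    def test_empty_union_is_undefined(self):
        a = make_mask([0, 0, 0])
        assert math.isnan(pq.agreement_index(a, a).ai)
        assert not pq.agreement_index(a, a).defined

    def test_mismatched_grids_rejected(self):
        a = make_mask([1, 0])
        b = make_mask([1, 0, 1])
        with pytest.raises(ValueError):
            pq.agreement_index(a, b)

    @given(
        st.lists(st.booleans(), min_size=1, max_size=40),
        st.lists(st.booleans(), min_size=1, max_size=40),
    )
    @settings(derandomize=True)
    def test_symmetric_bounded_jaccard(self, a_bits, b_bits):
        n = min(len(a_bits), len(b_bits))
        a, b = make_mask(a_bits[:n]), make_mask(b_bits[:n])
        ab, ba = pq.agreement_index(a, b), pq.agreement_index(b, a)
        if ab.defined:
            assert ab.ai == pytest.approx(ba.ai)
            assert 0.0 <= ab.ai <= 1.0
            sa = set(np.flatnonzero(a.mask))
            sb = set(np.flatnonzero(b.mask))
            assert ab.ai == pytest.approx(len(sa & sb) / len(sa | sb))
            if ab.ai == 1.0:
                assert sa == sb
            if sa and sb and not (sa & sb):
                assert ab.ai == 0.0


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert pq.spearman(x, x**3)[0] == pytest.approx(1.0)
        assert pq.spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_pearson(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        rho, _ = pq.spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle)

    def test_constant_input_flagged_undefined(self):
        rho, p = pq.spearman(np.ones(10), np.arange(10.0))
        assert math.isnan(rho) and math.isnan(p)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(5, 50))
            x = np.round(rng.uniform(0, 5, n), 0)
            y = np.round(rng.uniform(0, 5, n), 0)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rho, p = pq.spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestIndividualAndMeta:
    def test_zero_error_subject_flagged_undefined(self, quiet_session):
        grid = pq.make_grid(quiet_session.duration_s)
        err = pq.ErrorRateSeries("S001", grid, np.zeros(len(grid)))
        onsets, rts = pq.extract_rt_observations(quiet_session)
        rt = pq.interpolate_rt(onsets, rts, grid, "S001")
        rtv = pq.sliding_rtv(rt)
        results = pq.individual_analysis([err], [rt], [rtv], [0])
        assert math.isnan(results[0].rho_rt) and math.isnan(results[0].rho_rtv)

    def test_cohort_medians_match_brute_force(self, small_cohort):
        results = pq.ResponseQualityModel(small_cohort).fit()
        rhos = [c.rho_rtv for c in results.correlations if not math.isnan(c.rho_rtv)]
        med, mx = results.rho_median_max("rtv")
        assert med == pytest.approx(float(np.median(rhos)))
        assert mx == pytest.approx(float(np.max(rhos)))

    def test_identity_statistic_gives_perfect_meta_correlation(self):
        errors = [3, 1, 4, 1, 5, 9, 2, 6]
        rho, p = pq.meta_correlation([float(e) for e in errors], errors)
        assert rho == pytest.approx(1.0)

    def test_permuted_statistic_averages_zero(self):
        rng = np.random.default_rng(9)
        errors = list(range(30))
        rhos = []
        for _ in range(200):
            stat = rng.permutation(30).astype(float)
            rhos.append(pq.meta_correlation(stat, errors)[0])
        se = np.std(rhos) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 3 * se

    def test_nan_statistics_dropped_pairwise(self):
        stat = [math.nan, 1.0, 2.0, 3.0, math.nan, 5.0]
        errors = [9, 1, 2, 3, 9, 5]
        rho, _ = pq.meta_correlation(stat, errors)
        assert rho == pytest.approx(1.0)
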