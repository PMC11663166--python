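"""ROC toolkit: empirical curves, AUC identities, Youden search, DeLong
inference, analytic AUCs and Bayes predictive values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amypredict.roc import (
    auc_from_operating_points,
    binary_marker_auc,
    binormal_auc,
    delong_auc_ci,
    delong_paired_test,
    empirical_roc,
    mann_whitney_auc,
    ppv_npv,
    trapezoid_auc,
    youden_cutoff,
)


def _random_instance(seed, n_max=40, levels=6):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, n_max))
    values = rng.integers(0, levels, n).astype(float)  # heavy ties
    labels = rng.random(n) < 0.4
    if labels.all() or not labels.any():
        labels[0] = not labels[0]
    return values, labels


def _pairwise_auc(values, labels, direction="above"):
    """O(n^2) Mann-Whitney oracle."""
    v = np.asarray(values, float)
    v = -v if direction == "below" else v
    pos, neg = v[np.asarray(labels, bool)], v[~np.asarray(labels, bool)]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestEmpiricalROC:
    def test_perfect_separation(self):
        curve = empirical_roc([1, 2, 3, 4], [True, True, False, False], "below")
        assert trapezoid_auc(curve) == 1.0
        assert any((f == 0 and t == 1) for f, t in zip(curve.fpr, curve.tpr))

    def test_all_ties_give_diagonal(self):
        curve = empirical_roc([2, 2, 2, 2], [True, False, True, False])
        np.testing.assert_array_equal(curve.fpr, [0, 1])
        np.testing.assert_array_equal(curve.tpr, [0, 1])
        assert trapezoid_auc(curve) == 0.5

    def test_vertices_monotone_and_anchored(self):
        for seed in range(20):
            v, y = _random_instance(seed)
            c = empirical_roc(v, y)
            assert c.fpr[0] == 0 and c.tpr[0] == 0
            assert c.fpr[-1] == 1 and c.tpr[-1] == 1
            assert (np.diff(c.fpr) >= 0).all() and (np.diff(c.tpr) >= 0).all()

    def test_vertices_match_exhaustive_threshold_enumeration(self):
        for seed in range(20):
            v, y = _random_instance(seed)
            c = empirical_roc(v, y, "above")
            pts = {(0.0, 0.0), (1.0, 1.0)}
            for t in np.unique(v):
                pred = v >= t
                pts.add(((pred & ~y).sum() / (~y).sum(),
                         (pred & y).sum() / y.sum()))
            assert set(zip(c.fpr, c.tpr)) == pts

    def test_single_class_refused(self):
        with pytest.raises(ValueError, match="class"):
            empirical_roc([1, 2, 3], [True, True, True])

    def test_matches_sklearn_curve_auc(self):
        sk = pytest.importorskip("sklearn.metrics")
        for seed in range(10):
            v, y = _random_instance(seed, n_max=80)
            ours = trapezoid_auc(empirical_roc(v, y, "above"))
            assert ours == pytest.approx(sk.roc_auc_score(y, v), abs=1e-12)


class TestAUCIdentities:
    def test_trapezoid_equals_mann_whitney_everywhere(self):
        for seed in range(50):
            v, y = _random_instance(seed)
            for d in ("above", "below"):
                a = trapezoid_auc(empirical_roc(v, y, d))
                assert a == pytest.approx(_pairwise_auc(v, y, d), abs=1e-12)
                assert mann_whitney_auc(v, y, d) == pytest.approx(a, abs=1e-12)

    def test_operating_point_reconstruction_identities(self):
        assert auc_from_operating_points([(100, 100)]) == 1.0
        assert auc_from_operating_points([(50, 50)]) == 0.5

    def test_published_threshold_tables_reproduce_reported_aucs(self):
        # volumetric score: >=1 (86.9, 50.5), >=2 (38.0, 86.3) -> 0.72
        assert auc_from_operating_points(
            [(86.9, 50.5), (38.0, 86.3)]) == pytest.approx(0.72, abs=0.005)
        # four-item score rows -> 0.82
        assert auc_from_operating_points(
            [(96, 27.0), (86.6, 67.6), (52.0, 91.7), (14.6, 96.4)]
        ) == pytest.approx(0.82, abs=0.005)

    def test_out_of_range_point_refused(self):
        with pytest.raises(ValueError):
            auc_from_operating_points([(120, 50)])


class TestYouden:
    def test_perfect_separation_rule(self):
        rule = youden_cutoff([1, 2, 3, 4, 5, 6],
                             [True, True, True, False, False, False], "below")
        assert rule.youden_j == pytest.approx(1.0)
        assert rule.cutoff == pytest.approx(3.5)
        assert rule.sensitivity == 100 and rule.specificity == 100

    def test_matches_exhaustive_enumeration(self):
        for seed in range(40):
            v, y = _random_instance(seed)
            for d in ("below", "above"):
                rule = youden_cutoff(v, y, d)
                best = -np.inf
                u = np.unique(v)
                for c in np.r_[-np.inf, (u[:-1] + u[1:]) / 2, np.inf]:
                    pred = v < c if d == "below" else v > c
                    j = (pred & y).sum() / y.sum() + (~pred & ~y).sum() / (~y).sum() - 1
                    best = max(best, j)
                assert rule.youden_j == pytest.approx(best, abs=1e-12)
                assert rule.youden_j == pytest.approx(
                    rule.sensitivity / 100 + rule.specificity / 100 - 1, abs=1e-9)

    def test_tie_breaks_toward_most_specific_rule(self):
        # any cutoff splitting {1,2} vs {3,4} has J = 1; several cutoffs tie
        # at lower J on this instance with duplicated values
        v = np.array([1.0, 1.0, 2.0, 2.0])
        y = np.array([True, False, True, False])
        rule = youden_cutoff(v, y, "below")
        # J = 0 everywhere; the most specific rule classifies nobody positive
        assert rule.youden_j == pytest.approx(0.0)
        assert rule.cutoff == -np.inf
        assert rule.specificity == 100.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        v, y = _random_instance(seed, levels=10)
        base = youden_cutoff(v, y, "below")
        trans = youden_cutoff(np.exp(0.3 * v), y, "below")
        assert trans.youden_j == pytest.approx(base.youden_j, abs=1e-12)
        assert trans.sensitivity == pytest.approx(base.sensitivity)
        assert trans.specificity == pytest.approx(base.specificity)


class TestDeLong:
    def test_perfect_separation_zero_variance(self):
        y = np.r_[np.zeros(5, bool), np.ones(5, bool)]
        res = delong_auc_ci(np.r_[np.zeros(5), np.ones(5)], y)
        assert res.auc == 1.0 and res.standard_error == 0.0
        assert res.ci_low == res.ci_high == 1.0

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.zeros(198, bool), np.ones(92, bool)]
        v = np.where(y, rng.normal(1, 1, 290), rng.normal(0, 1, 290))
        res = delong_auc_ci(v, y)
        boot = []
        pos_idx, neg_idx = np.nonzero(y)[0], np.nonzero(~y)[0]
        for _ in range(2000):
            idx = np.r_[rng.choice(pos_idx, 92), rng.choice(neg_idx, 198)]
            boot.append(mann_whitney_auc(v[idx], y[idx]))
        bv = np.var(boot, ddof=1)
        assert abs(res.standard_error**2 - bv) / bv < 0.15

    def test_ci_coverage_under_binormal_truth(self):
        true_auc = binormal_auc(0.5, 1, 0, 1)
        cover = 0
        n_rep = 1000
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            y = np.r_[np.zeros(500, bool), np.ones(500, bool)]
            v = np.where(y, rng.normal(0.5, 1, 1000), rng.normal(0, 1, 1000))
            res = delong_auc_ci(v, y)
            cover += res.ci_low <= true_auc <= res.ci_high
        assert cover / n_rep == pytest.approx(0.95, abs=0.02)

    def test_logit_ci_within_bounds(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.zeros(30, bool), np.ones(30, bool)]
        v = np.where(y, rng.normal(2, 1, 60), rng.normal(0, 1, 60))
        res = delong_auc_ci(v, y, scale="logit")
        assert 0 < res.ci_low <= res.auc <= res.ci_high < 1

    def test_paired_identical_markers(self):
        rng = np.random.default_rng(1)
        y = rng.random(60) < 0.4
        v = rng.normal(size=60)
        auc_a, auc_b, z, p = delong_paired_test(v, v, y)
        assert auc_a == auc_b and z == 0.0 and p == 1.0

    def test_paired_type_one_error_near_nominal(self):
        rej = 0
        n_rep = 2000
        for s in range(n_rep):
            rng = np.random.default_rng(100_000 + s)
            y = np.r_[np.zeros(100, bool), np.ones(100, bool)]
            latent = np.where(y, rng.normal(0.8, 1, 200), rng.normal(0, 1, 200))
            a = latent + rng.normal(0, 1, 200)
            b = latent + rng.normal(0, 1, 200)
            *_, p = delong_paired_test(a, b, y)
            rej += p < 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=0.015)

    def test_paired_p_close_to_permutation_oracle(self):
        rng = np.random.default_rng(5)
        n = 30
        y = np.r_[np.zeros(n, bool), np.ones(n, bool)]
        latent = np.where(y, rng.normal(0.9, 1, 2 * n), rng.normal(0, 1, 2 * n))
        a = latent + rng.normal(0, 1, 2 * n)
        b = latent + rng.normal(0, 0.7, 2 * n)
        *_, p = delong_paired_test(a, b, y)
        obs = abs(_pairwise_auc(a, y) - _pairwise_auc(b, y))
        exceed = 0
        n_perm = 5000
        for _ in range(n_perm):
            swap = rng.random(2 * n) < 0.5
            aa, bb = np.where(swap, b, a), np.where(swap, a, b)
            d = abs(_pairwise_auc(aa, y) - _pairwise_auc(bb, y))
            exceed += d >= obs - 1e-12
        assert p == pytest.approx(exceed / n_perm, abs=0.02)

    def test_mismatched_records_refused(self):
        with pytest.raises(ValueError):
            delong_paired_test([1, 2, 3], [1, 2], [True, False, True])


class TestAnalyticAUCs:
    def test_equal_means_give_half(self):
        assert binormal_auc(1, 2, 1, 3) == 0.5
        assert binary_marker_auc(0.4, 0.4) == 0.5

    def test_binormal_matches_printed_angular_gyrus_auc(self):
        auc = binormal_auc(7.96, 1.26, 8.82, 1.11, "below")
        assert auc == pytest.approx(0.69, abs=0.01)

    def test_binormal_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        n = 10**6
        y = np.r_[np.zeros(n // 2, bool), np.ones(n // 2, bool)]
        v = np.where(y, rng.normal(6.33, 0.92, n), rng.normal(6.88, 0.95, n))
        mc = mann_whitney_auc(v, y, "below")
        assert binormal_auc(6.33, 0.92, 6.88, 0.95, "below") == pytest.approx(mc, abs=0.002)

    def test_binary_marker_matches_printed_apoe4_auc(self):
        assert binary_marker_auc(0.696, 0.298) == pytest.approx(0.699, abs=1e-9)
        assert binary_marker_auc(0.696, 0.298) == pytest.approx(0.69, abs=0.01)

    def test_binary_marker_matches_simulation(self):
        rng = np.random.default_rng(7)
        n = 10**5
        y = np.r_[np.zeros(n // 2, bool), np.ones(n // 2, bool)]
        v = np.where(y, rng.random(n) < 0.696, rng.random(n) < 0.298).astype(float)
        assert binary_marker_auc(0.696, 0.298) == pytest.approx(
            mann_whitney_auc(v, y), abs=0.005)

    def test_invalid_inputs_refused(self):
        with pytest.raises(ValueError):
            binormal_auc(1, 0, 0, 1)
        with pytest.raises(ValueError):
            binary_marker_auc(1.2, 0.3)


class TestPredictiveValues:
    def test_printed_volumetric_row_arithmetic(self):
        ppv, npv = ppv_npv(86.9, 50.5, 92 / 290)
        assert round(ppv, 1) == 44.9 and round(npv, 1) == 89.2
        ppv, npv = ppv_npv(90.9, 43.7, 45 / 290)
        assert round(ppv, 1) == 22.9 and round(npv, 1) == 96.3

    def test_perfect_test(self):
        assert ppv_npv(100, 100, 0.3) == (100.0, 100.0)

    def test_degenerate_corner_flagged(self):
        with pytest.warns(UserWarning, match="PPV"):
            ppv, npv = ppv_npv(0, 100, 0.5)
        assert np.isnan(ppv) and npv == pytest.approx(50.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1, 99), st.floats(1, 99),
           st.floats(0.05, 0.9), st.floats(0.001, 0.09))
    def test_monotone_in_prevalence(self, sens, spec, p, dp):
        ppv1, npv1 = ppv_npv(sens, spec, p)
        ppv2, npv2 = ppv_npv(sens, spec, p + dp)
        assert ppv2 >= ppv1 - 1e-9
        assert npv2 <= npv1 + 1e-9

    def test_prevalence_must_be_interior(self):
        with pytest.raises(ValueError):
            ppv_npv(80, 80, 0.0)
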