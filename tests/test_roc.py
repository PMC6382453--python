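"""ROC/AUC inference: oracles for AUC, F-index, DeLong, and q-values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from ogttbench import (
    auc_mann_whitney,
    confusion_metrics,
    delong_ci,
    delong_covariance,
    delong_paired_test,
    delong_variance,
    f_index_cutoff,
    qvalues,
    roc_curve,
    significance_call,
    storey_pi0,
)
from ogttbench.roc import delong_components


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def auc_pair_counting(scores, labels):
    """Brute-force probability a positive outranks a negative, ties 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def delong_naive(scores_a, scores_b, labels):
    """Quadratic-time structural components for two paired score vectors.

    Returns (auc_a, auc_b, var_a, var_b, cov_ab) exactly as defined: V10_i is
    positive i's mean psi against all negatives, V01_j the mirror.
    """

    def components(scores):
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        return psi.mean(), psi.mean(axis=1), psi.mean(axis=0)

    auc_a, a10, a01 = components(scores_a)
    auc_b, b10, b01 = components(scores_b)
    m, n = len(a10), len(a01)
    var = lambda v: v.var(ddof=1)
    cov = lambda u, v: np.cov(u, v, ddof=1)[0, 1]
    var_a = var(a10) / m + var(a01) / n
    var_b = var(b10) / m + var(b01) / n
    cov_ab = cov(a10, b10) / m + cov(a01, b01) / n
    return auc_a, auc_b, var_a, var_b, cov_ab


def _random_instance(rng, n_max=30, ties=True):
    m = rng.integers(2, n_max // 2)
    n = rng.integers(2, n_max // 2)
    labels = np.concatenate([np.ones(m, dtype=int), np.zeros(n, dtype=int)])
    if ties and rng.random() < 0.5:
        scores = rng.integers(0, 5, size=m + n).astype(float)
    else:
        scores = rng.normal(size=m + n)
    return scores, labels


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


class TestAUC:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        assert auc_mann_whitney([1.0, 2.0, 3.0, 4.0], labels) == 1.0

    def test_all_ties(self):
        labels = np.array([0, 1, 0, 1])
        assert auc_mann_whitney(np.ones(4), labels) == 0.5

    def test_hand_listed_pair_counting(self, rng):
        labels = np.array([1] * 5 + [0] * 5)
        scores = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 2.0, 0.0, 4.0, 1.0, 3.0])
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels)
        )

    def test_matches_trapezoid_and_sklearn(self, rng):
        """Rank AUC equals the trapezoidal ROC area on random instances."""
        for _ in range(200):
            scores, labels = _random_instance(rng)
            mine = auc_mann_whitney(scores, labels)
            assert mine == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
            roc = roc_curve(scores, labels)
            area = np.trapezoid(roc.sens, 1.0 - roc.spec)
            assert mine == pytest.approx(area, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1.0, 2.0], [1, 1])


class TestROCCurveShape:
    def test_endpoints_and_monotonicity(self, rng):
        scores, labels = _random_instance(rng)
        roc = roc_curve(scores, labels)
        assert roc.sens[0] == 0.0 and roc.spec[0] == 1.0
        assert roc.sens[-1] == 1.0 and roc.spec[-1] == 0.0
        assert (np.diff(roc.sens) >= 0).all()
        assert (np.diff(roc.spec) <= 0).all()


# ---------------------------------------------------------------------------
# F-index cutoff and confusion metrics
# ---------------------------------------------------------------------------


class TestFIndexCutoff:
    def test_dominant_point_chosen(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        thr, sens, spec = f_index_cutoff(roc_curve(scores, labels))
        assert sens == 1.0 and spec == 1.0
        assert 0.3 < thr <= 0.7

    def test_equals_exhaustive_scan(self, rng):
        for _ in range(100):
            scores, labels = _random_instance(rng)
            roc = roc_curve(scores, labels)
            thr, sens, spec = f_index_cutoff(roc)
            f_opt = 2 * sens * spec / (sens + spec)
            f_scan = max(
                (2 * s * p / (s + p)) if s + p > 0 else 0.0
                for s, p in zip(roc.sens, roc.spec)
            )
            assert f_opt == pytest.approx(f_scan, abs=1e-12)

    def test_harmonic_mean_of_equal_values_is_the_value(self):
        from ogttbench.roc import _harmonic

        for s in (0.3, 0.5, 0.7, 1.0):
            assert _harmonic(np.array([s]), np.array([s]))[0] == pytest.approx(s)
        # degenerate points score zero, never a spurious optimum
        assert _harmonic(np.array([0.0]), np.array([1.0]))[0] == 0.0

    def test_degenerate_curve_rejected(self):
        from ogttbench.roc import ROCCurve

        with pytest.raises(ValueError):
            f_index_cutoff(
                ROCCurve(np.array([np.inf]), np.array([0.0]), np.array([1.0]))
            )


class TestConfusionMetrics:
    def test_hand_built_table(self):
        # TP 3, FP 1, FN 1, TN 5 at threshold 0.5
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.3, 0.1, 0.2, 0.1, 0.4, 0.2])
        labels = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        m = confusion_metrics(scores, labels, 0.5)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["ppv"] == pytest.approx(0.75)
        assert m["npv"] == pytest.approx(5 / 6)

    def test_perfect_classifier(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        m = confusion_metrics(scores, labels, 0.5)
        assert all(v == 1.0 for v in m.values())

    def test_all_positive_rule(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        m = confusion_metrics(scores, labels, 0.0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0
        assert np.isnan(m["npv"])  # empty denominator reported missing


# ---------------------------------------------------------------------------
# DeLong variance / covariance / CI / paired test
# ---------------------------------------------------------------------------


class TestDeLong:
    def test_fast_equals_naive_sweep(self, rng):
        """Midrank implementation equals the O(n^2) structural components."""
        for _ in range(300):
            scores_a, labels = _random_instance(rng)
            scores_b = rng.normal(size=len(labels))
            auc_a, auc_b, var_a, var_b, cov_ab = delong_naive(
                scores_a, scores_b, labels
            )
            assert auc_mann_whitney(scores_a, labels) == pytest.approx(auc_a, abs=1e-12)
            assert delong_variance(scores_a, labels) == pytest.approx(var_a, rel=1e-9)
            assert delong_variance(scores_b, labels) == pytest.approx(var_b, rel=1e-9)
            assert delong_covariance(scores_a, scores_b, labels) == pytest.approx(
                cov_ab, rel=1e-9, abs=1e-12
            )

    def test_all_ties_closed_form(self):
        """With all-identical scores every component is exactly 1/2, so the
        variance of the components — and of the AUC — is zero."""
        labels = np.array([1] * 20 + [0] * 20)
        scores = np.ones(40)
        _, v10, v01 = delong_components(scores, labels)
        np.testing.assert_array_equal(v10, 0.5)
        np.testing.assert_array_equal(v01, 0.5)
        assert delong_variance(scores, labels) == 0.0

    def test_variance_scaling_with_duplication(self, rng):
        scores, labels = _random_instance(rng, n_max=28, ties=False)
        v1 = delong_variance(scores, labels)
        v2 = delong_variance(np.tile(scores, 2), np.tile(labels, 2))
        assert v2 == pytest.approx(v1 / 2, rel=0.25)

    def test_ci_analytic_vs_bootstrap(self):
        rng = np.random.default_rng(99)
        n = 500
        labels = (np.arange(n) < 150).astype(int)
        scores = rng.normal(size=n) + labels * 0.95
        lo_a, hi_a = delong_ci(scores, labels, method="analytic")
        lo_b, hi_b = delong_ci(
            scores, labels, method="stratified_bootstrap", replicates=2000, seed=7
        )
        assert lo_a == pytest.approx(lo_b, abs=0.02)
        assert hi_a == pytest.approx(hi_b, abs=0.02)

    def test_ci_width_halves_with_4x_sample(self):
        rng = np.random.default_rng(5)
        labels = (np.arange(400) < 120).astype(int)
        scores = rng.normal(size=400) + labels
        w1 = np.diff(delong_ci(scores, labels))[0]
        labels4 = np.tile(labels, 4)
        scores4 = rng.normal(size=1600) + labels4
        w4 = np.diff(delong_ci(scores4, labels4))[0]
        assert w4 == pytest.approx(w1 / 2, rel=0.3)

    def test_perfect_separation_clips_to_one(self):
        labels = np.array([0, 0, 1, 1])
        lo, hi = delong_ci(np.array([0.0, 0.1, 1.0, 1.1]), labels)
        assert hi == 1.0

    def test_identical_models_degenerate(self):
        labels = np.array([0, 1, 0, 1, 0, 1])
        scores = np.array([0.1, 0.9, 0.3, 0.7, 0.2, 0.8])
        res = delong_paired_test(scores, scores, labels)
        assert res.delta_auc == 0.0
        assert res.p == 1.0
        assert res.degenerate

    def test_antisymmetry(self, rng):
        scores_a, labels = _random_instance(rng, ties=False)
        scores_b = rng.normal(size=len(labels))
        ab = delong_paired_test(scores_a, scores_b, labels)
        ba = delong_paired_test(scores_b, scores_a, labels)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)
        assert ab.delta_auc == pytest.approx(-ba.delta_auc)

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(ValueError):
            delong_paired_test([0.1, 0.2], [0.1, 0.2, 0.3], [0, 1, 1])

    def test_type_one_error_calibration(self):
        """Under a shared-label null the paired test rejects at ~5%."""
        rng = np.random.default_rng(2024)
        n, n_pos = 200, 60
        labels = (np.arange(n) < n_pos).astype(int)
        n_sims = 2000
        rejections = 0
        for _ in range(n_sims):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            if delong_paired_test(a, b, labels).p < 0.05:
                rejections += 1
        assert rejections / n_sims == pytest.approx(0.05, abs=0.015)


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------


class TestQValues:
    def test_single_p_identity(self):
        assert qvalues([0.03], pi0=1.0)[0] == pytest.approx(0.03)

    def test_hand_case(self):
        q = qvalues(np.array([0.01, 0.02, 0.03, 0.8]), pi0=1.0)
        # stepwise minimization: m*p/i = .04, .04, .04, .8; already monotone
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.8], atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.random(50)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_bh_equivalence(self, rng):
        """With pi0 = 1 q-values equal Benjamini-Hochberg adjusted p-values."""
        for _ in range(20):
            p = rng.random(rng.integers(1, 60))
            q = qvalues(p, pi0=1.0)
            bh = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_dominance_bounds(self, rng):
        """q is squeezed between pi0*p (the min over t is at most taken at
        t = max p, denominator m) and pi0*m*p/rank (the t = p term)."""
        p = rng.random(40)
        pi0 = storey_pi0(p)
        q = qvalues(p, pi0=pi0)
        ranks = np.argsort(np.argsort(p)) + 1
        assert (q <= pi0 * len(p) * p / ranks + 1e-12).all()
        assert (q >= pi0 * p - 1e-12).all()

    def test_pi0_estimator(self):
        # half the batch above 0.5 -> pi0 = 1 (clipped)
        assert storey_pi0(np.linspace(0.01, 0.99, 100)) == pytest.approx(1.0, abs=0.05)
        # all p tiny -> floored, not zero
        assert storey_pi0(np.full(20, 1e-4)) == pytest.approx(1 / 20)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.2])
        with pytest.raises(ValueError):
            qvalues([])


class TestSignificanceCall:
    @pytest.mark.parametrize(
        "q, expected",
        [
            (0.044, True),    # rounds to 0.04
            (0.049, False),   # rounds to 0.05: differs from unrounded q < 0.05
            (0.05, False),    # strict inequality at the boundary
            (0.045, True),    # half-even on the decimal digits: -> 0.04
            (0.055, False),   # half-even: -> 0.06
            (0.0, True),
            (1.0, False),
        ],
    )
    def test_rounding_rule(self, q, expected):
        assert significance_call(q) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_call(1.5)
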