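"""ROC construction, AUC inference, correlated-ROC comparison, and pFDR.

The components here implement the inference layer of the benchmark:

* Empirical ROC and the Mann-Whitney AUC (ties counted 1/2), equal to the
  trapezoidal area under the empirical curve.
* The F-index cutoff: the score threshold maximizing the harmonic mean of
  sensitivity and specificity, with accuracy/sens/spec/PPV/NPV reported at
  that cutoff.
* DeLong's nonparametric variance and covariance of correlated AUCs via
  structural components, computed with midranks in O(n log n); a 95% CI
  either analytic (normal) or by stratified bootstrap (resampling within
  outcome class, percentile interval); and the paired z test comparing two
  models' ROC curves on the same participants.
* Storey's positive false discovery rate q-values over a batch of p-values,
  with the published decision rule: round q to two decimals, call q < 0.05
  significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
from scipy import stats
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCCurve",
    "ModelPerformance",
    "ComparisonResult",
    "roc_curve",
    "auc_mann_whitney",
    "f_index_cutoff",
    "confusion_metrics",
    "delong_components",
    "delong_variance",
    "delong_covariance",
    "delong_ci",
    "delong_paired_test",
    "qvalues",
    "storey_pi0",
    "significance_call",
    "evaluate_scores",
]


# ---------------------------------------------------------------------------
# ROC curve and threshold metrics
# ---------------------------------------------------------------------------


@dataclass
class ROCCurve:
    """Empirical ROC: descending thresholds with sensitivity/specificity.

    Includes the degenerate endpoints (sens 0, spec 1) at threshold +inf and
    (sens 1, spec 0) at the minimum score.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return labels


def roc_curve(scores, labels) -> ROCCurve:
    """Empirical ROC of scores against binary labels (higher = positive)."""
    labels = _check_labels(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    return ROCCurve(thresholds=thr, sens=tpr, spec=1.0 - fpr)


def auc_mann_whitney(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2).

    Identical to the trapezoidal area under the empirical ROC.
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    m = int(pos.sum())
    n = len(labels) - m
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - m * (m + 1) / 2) / (m * n))


def _harmonic(sens: np.ndarray, spec: np.ndarray) -> np.ndarray:
    s = sens + spec
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(s > 0, 2.0 * sens * spec / np.where(s > 0, s, 1.0), 0.0)
    return f


def f_index_cutoff(roc: ROCCurve) -> tuple[float, float, float]:
    """Threshold maximizing the harmonic mean of sensitivity and specificity.

    Returns (threshold, sens, spec) at the optimum. The harmonic mean at a
    degenerate point (either coordinate 0) is defined as 0. Ties are broken
    toward higher sensitivity.
    """
    if len(roc.thresholds) < 2:
        raise ValueError("degenerate ROC curve")
    f = _harmonic(roc.sens, roc.spec)
    best_f = f.max()
    candidates = np.flatnonzero(f == best_f)
    # among ties, the highest sensitivity
    i = candidates[np.argmax(roc.sens[candidates])]
    return float(roc.thresholds[i]), float(roc.sens[i]), float(roc.spec[i])


def confusion_metrics(scores, labels, threshold: float) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV and NPV at a score threshold.

    A score >= threshold predicts positive. A PPV or NPV with an empty
    denominator is reported as NaN, not zero.
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    n = tp + fp + fn + tn
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if tp + fp > 0 else float("nan"),
        "npv": tn / (tn + fn) if tn + fn > 0 else float("nan"),
    }


# ---------------------------------------------------------------------------
# DeLong structural components
# ---------------------------------------------------------------------------


def delong_components(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC with its structural components over positives and negatives.

    ``V10[i]`` is the fraction of negatives outranked by positive i (ties
    1/2); ``V01[j]`` the fraction of positives outranking negative j. Both
    average to the AUC. Computed with midranks in O(n log n).
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m < 1 or n < 1:
        raise ValueError("need at least one observation per class")
    all_ranks = rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong variance of the AUC from the structural-component estimator."""
    _, v10, v01 = delong_components(scores, labels)
    if len(v10) < 2 or len(v01) < 2:
        raise ValueError("need at least two observations per class")
    return float(v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01))


def delong_covariance(scores_a, scores_b, labels) -> float:
    """Covariance of two correlated AUCs (same participants, same labels)."""
    _, a10, a01 = delong_components(scores_a, labels)
    _, b10, b01 = delong_components(scores_b, labels)
    m, n = len(a10), len(a01)
    if m < 2 or n < 2:
        raise ValueError("need at least two observations per class")
    cov10 = np.cov(a10, b10, ddof=1)[0, 1]
    cov01 = np.cov(a01, b01, ddof=1)[0, 1]
    return float(cov10 / m + cov01 / n)


def delong_ci(
    scores,
    labels,
    level: float = 0.95,
    method: str = "analytic",
    replicates: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the AUC.

    ``analytic``: normal interval AUC +/- z * sqrt(DeLong variance), clipped
    to [0, 1]. ``stratified_bootstrap``: percentile interval of the AUC over
    replicates resampled within each outcome class (2000 by default).
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    alpha = 1.0 - level
    if method == "analytic":
        auc = auc_mann_whitney(scores, labels)
        se = np.sqrt(delong_variance(scores, labels))
        z = stats.norm.ppf(1 - alpha / 2)
        return float(np.clip(auc - z * se, 0, 1)), float(np.clip(auc + z * se, 0, 1))
    if method == "stratified_bootstrap":
        rng = np.random.default_rng(seed)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        if len(pos) < 2 or len(neg) < 2:
            raise ValueError("need at least two observations per class")
        m, n = len(pos), len(neg)
        aucs = np.empty(replicates)
        y = np.concatenate([np.ones(m, dtype=int), np.zeros(n, dtype=int)])
        for b in range(replicates):
            sample = np.concatenate(
                [rng.choice(pos, m, replace=True), rng.choice(neg, n, replace=True)]
            )
            aucs[b] = auc_mann_whitney(sample, y)
        lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


@dataclass
class ComparisonResult:
    """Paired comparison of one model's ROC against the reference model's."""

    delta_auc: float
    z: float
    p: float
    q: float | None = None
    significant: bool | None = None
    degenerate: bool = False

    def with_q(self, q: float) -> "ComparisonResult":
        return ComparisonResult(
            delta_auc=self.delta_auc,
            z=self.z,
            p=self.p,
            q=q,
            significant=significance_call(q),
            degenerate=self.degenerate,
        )


def delong_paired_test(scores_a, scores_b, labels) -> ComparisonResult:
    """DeLong z test for two correlated ROC curves on shared participants.

    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov_ab), two-sided normal p.
    Antisymmetric in (a, b). When the variance of the difference is zero
    (identical rankings) the result is flagged degenerate with p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(labels)
    if scores_a.shape != scores_b.shape or len(scores_a) != len(labels):
        raise ValueError("score vectors must align with the shared labels")
    auc_a, a10, a01 = delong_components(scores_a, labels)
    auc_b, b10, b01 = delong_components(scores_b, labels)
    m, n = len(a10), len(a01)
    var_a = a10.var(ddof=1) / m + a01.var(ddof=1) / n
    var_b = b10.var(ddof=1) / m + b01.var(ddof=1) / n
    cov = np.cov(a10, b10, ddof=1)[0, 1] / m + np.cov(a01, b01, ddof=1)[0, 1] / n
    delta = auc_a - auc_b
    var_delta = var_a + var_b - 2 * cov
    if var_delta <= 1e-16:
        return ComparisonResult(delta_auc=float(delta), z=0.0, p=1.0, degenerate=True)
    z = delta / np.sqrt(var_delta)
    p = 2 * stats.norm.sf(abs(z))
    return ComparisonResult(delta_auc=float(delta), z=float(z), p=float(max(p, np.finfo(float).tiny)))


# ---------------------------------------------------------------------------
# Positive FDR q-values
# ---------------------------------------------------------------------------


def storey_pi0(pvals: np.ndarray, lam: float = 0.5) -> float:
    """Fixed-lambda estimate of the null proportion pi0 = #{p > lam}/((1-lam) m).

    Clipped to at most 1; floored at 1/m so an all-small batch does not
    collapse every q-value to zero.
    """
    pvals = np.asarray(pvals, dtype=float)
    m = len(pvals)
    pi0 = (pvals > lam).sum() / ((1.0 - lam) * m)
    return float(min(1.0, max(pi0, 1.0 / m)))


def qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """Positive-FDR q-values for a batch of p-values.

    q_(i) = min over t >= p_(i) of pi0 * m * t / #{p <= t}, i.e. the
    step-up minimization over the observed p-values, enforced monotone
    nondecreasing in p. With ``pi0 = 1`` this is exactly the
    Benjamini-Hochberg adjusted p-value.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1 or len(pvals) == 0:
        raise ValueError("need a 1-D, non-empty batch of p-values")
    if ((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pvals)
    if pi0 is None:
        pi0 = storey_pi0(pvals)
    order = np.argsort(pvals, kind="stable")
    q_sorted = pi0 * m * pvals[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def significance_call(q: float) -> bool:
    """The published decision rule: round q to two decimals (half-even),
    then call significant iff the rounded value is strictly below 0.05."""
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    rounded = float(
        Decimal(repr(float(q))).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN)
    )
    return rounded < 0.05


# ---------------------------------------------------------------------------
# Model-level evaluation bundle
# ---------------------------------------------------------------------------


@dataclass
class ModelPerformance:
    """AUC with CI plus threshold metrics at the F-index cutoff."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n: int


def evaluate_scores(
    scores,
    labels,
    ci_method: str = "analytic",
    ci_replicates: int = 2000,
    seed: int = 0,
) -> ModelPerformance:
    """Full per-model performance bundle from averaged CV scores."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    auc = auc_mann_whitney(scores, labels)
    lo, hi = delong_ci(
        scores, labels, method=ci_method, replicates=ci_replicates, seed=seed
    )
    roc = roc_curve(scores, labels)
    cutoff, _, _ = f_index_cutoff(roc)
    metrics = confusion_metrics(scores, labels, cutoff)
    return ModelPerformance(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        cutoff=cutoff,
        n=len(labels),
        **metrics,
    )
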