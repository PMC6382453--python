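"""Synthetic OGTT cohort generator.

Emulates the structure of a prospective nondiabetic cohort followed for
progression to type 2 diabetes: 543 participants of whom 146 progress, with
baseline clinical risk factors (age, sex, BMI, family history), OGTT plasma
glucose and serum insulin at 0/30/60/120 min, HbA1c, and six standardized
serum metabolites whose correlations with the glucose time points match the
reported values (e.g. mannose vs 30-min PG, r = 0.32).

Construction is a latent-Gaussian copula with class-conditional mean shifts:

* Each marker has a latent standard-normal value with within-class covariance
  ``C`` and a standardized mean separation ``delta`` between progressors and
  nonprogressors, so its theoretical single-marker discrimination is the
  binormal AUC ``Phi(delta / sqrt(2))``.
* The pooled (cohort-level) correlation of a two-class Gaussian mixture is
  inflated by the mean shifts. We therefore solve for ``C`` such that the
  *pooled* correlation equals the requested target matrix: with progressor
  fraction ``p`` and ``c_i = p(1-p) delta_i^2``,
  ``C_ij = R_ij * sqrt((1+c_i)(1+c_j)) - p(1-p) delta_i delta_j``.
  ``C`` keeps a unit diagonal; if the subtraction leaves it indefinite it is
  repaired by eigenvalue clipping (and the repair is logged on the cohort).
* Glucose/insulin/clinical columns are mapped affinely to their measurement
  scales and truncated at zero; sex and family history are thresholded to
  0/1 at their prevalence quantiles; metabolites stay on the standardized
  (zero-mean, unit-variance) scale.
* Rows that would be diabetic at baseline under the WHO criteria
  (FPG >= 7.0 or 2-h PG >= 11.1 mmol/L) are redrawn, because the emulated
  cohort is nondiabetic at entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    Cohort,
    GlycemicStatus,
    METABOLITE_COLUMNS,
    PG_COLUMNS,
    classify_glycemic_status_frame,
)

__all__ = [
    "SimConfig",
    "default_sim_config",
    "generate_cohort",
    "binormal_auc",
    "calibrate_effect",
]

#: Canonical marker order of the generated table.
MARKER_ORDER = (
    "age", "sex", "bmi", "fh",
    "pg0", "pg30", "pg60", "pg120",
    "ins0", "ins30", "ins60", "ins120",
    "hba1c",
) + METABOLITE_COLUMNS

INS_COLUMNS = ("ins0", "ins30", "ins60", "ins120")


def binormal_auc(delta: float) -> float:
    """Theoretical AUC of a marker with standardized class separation ``delta``.

    Under the equal-variance binormal model, AUC = Phi(delta / sqrt(2));
    strictly increasing in ``delta``, 0.5 at the null.
    """
    delta = float(delta)
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    return float(stats.norm.cdf(delta / np.sqrt(2.0)))


def calibrate_effect(target_auc: float) -> float:
    """Inverse of :func:`binormal_auc` on (0.5, 1): the delta reaching an AUC."""
    target_auc = float(target_auc)
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target AUC must lie strictly between 0.5 and 1")
    return float(np.sqrt(2.0) * stats.norm.ppf(target_auc))


def _default_correlation() -> pd.DataFrame:
    """Latent correlation targets.

    Metabolite-glucose and metabolite-HbA1c entries are the reported cohort
    correlations; the OGTT blocks use the stylized fact that adjacent time
    points correlate more strongly than distant ones. Insulin-glucose and
    metabolite-metabolite entries are plausibility assumptions (no cohort
    values are reported for them). Sex and family history are uncorrelated
    with everything by default.
    """
    m = len(MARKER_ORDER)
    R = pd.DataFrame(np.eye(m), index=MARKER_ORDER, columns=MARKER_ORDER)

    def put(a, b, r):
        R.loc[a, b] = r
        R.loc[b, a] = r

    # OGTT glucose block: adjacent time points inter-correlate most strongly
    put("pg0", "pg30", 0.50)
    put("pg0", "pg60", 0.45)
    put("pg0", "pg120", 0.40)
    put("pg30", "pg60", 0.70)
    put("pg30", "pg120", 0.45)
    put("pg60", "pg120", 0.60)
    # insulin block, same shape
    put("ins0", "ins30", 0.50)
    put("ins0", "ins60", 0.45)
    put("ins0", "ins120", 0.40)
    put("ins30", "ins60", 0.65)
    put("ins30", "ins120", 0.45)
    put("ins60", "ins120", 0.60)
    # insulin-glucose: same time point moderately, cross-times weakly
    for i, (g, s) in enumerate(zip(PG_COLUMNS, INS_COLUMNS)):
        put(g, s, 0.30)
    for g in PG_COLUMNS:
        for s in INS_COLUMNS:
            if R.loc[g, s] == 0:
                R.loc[g, s] = R.loc[s, g] = 0.15
    # HbA1c reflects average glycemia
    put("hba1c", "pg0", 0.30)
    put("hba1c", "pg30", 0.25)
    put("hba1c", "pg60", 0.25)
    put("hba1c", "pg120", 0.20)
    put("hba1c", "mannose", 0.16)
    put("hba1c", "x12063", 0.16)
    put("hba1c", "ahb", 0.05)
    put("hba1c", "hyp3_bk", -0.05)
    # reported metabolite-glucose correlations
    put("mannose", "pg0", 0.30)
    put("mannose", "pg30", 0.32)
    put("mannose", "pg60", 0.26)
    put("mannose", "pg120", 0.14)
    put("ahb", "pg0", 0.08)
    put("ahb", "pg30", 0.28)
    put("ahb", "pg60", 0.37)
    put("ahb", "pg120", 0.28)
    put("hyp3_bk", "pg0", -0.05)
    put("hyp3_bk", "pg30", -0.18)
    put("hyp3_bk", "pg60", -0.25)
    put("hyp3_bk", "pg120", -0.18)
    put("x12063", "pg0", 0.10)
    put("x12063", "pg30", 0.20)
    put("x12063", "pg60", 0.25)
    put("x12063", "pg120", 0.35)
    # modest co-variation among the glucose-linked metabolites
    put("mannose", "ahb", 0.15)
    put("mannose", "x12063", 0.15)
    put("ahb", "x12063", 0.15)
    put("hyp3_bk", "ahb", -0.10)
    put("hyp3_bk", "mannose", -0.10)
    # adiposity drives insulinemia and, weakly, glycemia
    put("bmi", "ins0", 0.35)
    for s in ("ins30", "ins60", "ins120"):
        put("bmi", s, 0.25)
    for g in PG_COLUMNS:
        put("bmi", g, 0.15)
        put("age", g, 0.10)
    return R


def _default_effects() -> dict[str, float]:
    """Standardized class separations, calibrated to reported single-marker
    AUCs where those exist (glucose time points, HbA1c, mannose, clinical
    factors) and to plausible sub-reference values elsewhere."""
    eff = {name: 0.0 for name in MARKER_ORDER}
    eff.update(
        {
            "age": calibrate_effect(0.60),
            "sex": 0.25,   # latent shift; male excess risk
            "bmi": calibrate_effect(0.62),
            "fh": 0.30,    # latent shift; familial enrichment
            "pg0": calibrate_effect(0.63),
            "pg30": calibrate_effect(0.71),
            "pg60": calibrate_effect(0.75),
            "pg120": calibrate_effect(0.68),
            "ins0": calibrate_effect(0.60),
            "ins30": calibrate_effect(0.62),
            "ins60": calibrate_effect(0.62),
            "ins120": calibrate_effect(0.61),
            "hba1c": calibrate_effect(0.67),
            "mannose": calibrate_effect(0.70),
            "ahb": calibrate_effect(0.66),
            "hyp3_bk": -calibrate_effect(0.60),
            "a_tocopherol": calibrate_effect(0.57),
            "carnitine_10_1": calibrate_effect(0.57),
            "x12063": calibrate_effect(0.66),
        }
    )
    return eff


#: (mean, SD) on the measurement scale; glucose in mmol/L, insulin in mU/L,
#: HbA1c in %, age in years, BMI in kg/m^2. Chosen so the WHO strata of the
#: generated cohort land near 16% IFG / 21% IGT. Metabolites stay latent.
DEFAULT_LOCATION_SCALE: dict[str, tuple[float, float]] = {
    "age": (45.0, 10.0),
    "bmi": (26.5, 4.2),
    "pg0": (5.7, 0.60),
    "pg30": (8.5, 1.7),
    "pg60": (8.0, 2.0),
    "pg120": (6.5, 1.65),
    "ins0": (8.0, 3.5),
    "ins30": (60.0, 28.0),
    "ins60": (55.0, 26.0),
    "ins120": (40.0, 20.0),
    "hba1c": (5.6, 0.4),
}

#: Prevalence of the positive level for thresholded binary markers.
DEFAULT_BINARY_PREVALENCE = {"sex": 0.5, "fh": 0.3}

#: Missing-completely-at-random rates per marker (metabolite panels and
#: insulin assays drop occasional measurements; glucose is essentially
#: complete in OGTT cohorts).
DEFAULT_MISSING_RATE = dict.fromkeys(METABOLITE_COLUMNS, 0.02) | dict.fromkeys(
    INS_COLUMNS, 0.02
) | {"hba1c": 0.01}


@dataclass
class SimConfig:
    """Full description of one synthetic cohort draw.

    ``corr`` is the *pooled* (cohort-level) Pearson correlation target;
    ``effects`` are within-class standardized mean separations (the binormal
    delta); ``missing_rate`` are per-marker MCAR probabilities.
    """

    n: int = 543
    n_progressors: int = 146
    marker_names: tuple[str, ...] = MARKER_ORDER
    corr: pd.DataFrame | None = None
    effects: dict[str, float] = field(default_factory=_default_effects)
    location_scale: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LOCATION_SCALE)
    )
    binary_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BINARY_PREVALENCE)
    )
    missing_rate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_progressors < self.n:
            raise ValueError("need 0 < n_progressors < n")
        if self.corr is None:
            self.corr = _default_correlation().loc[
                list(self.marker_names), list(self.marker_names)
            ]
        self.corr = pd.DataFrame(
            np.asarray(self.corr, dtype=float),
            index=list(self.marker_names),
            columns=list(self.marker_names),
        )
        if not np.allclose(self.corr, self.corr.T, atol=1e-12):
            raise ValueError("correlation target must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("correlation target must have unit diagonal")
        missing = [m for m in self.effects if m not in self.marker_names]
        if missing:
            raise ValueError(f"effects reference unknown markers: {missing}")
        for name, rate in self.missing_rate.items():
            if not 0 <= rate < 1:
                raise ValueError(f"missing rate for {name} outside [0, 1)")


def default_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """The shipped study conditions with an explicit seed."""
    return replace(SimConfig(seed=seed), **overrides)


def _nearest_corr(mat: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clip to positive semi-definite and renormalize the diagonal.

    Returns (repaired matrix, whether a repair was needed).
    """
    w, v = np.linalg.eigh(mat)
    if w.min() >= 0:
        return mat, False
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def _within_class_cov(
    R: np.ndarray, delta: np.ndarray, p: float
) -> tuple[np.ndarray, bool]:
    """Within-class covariance whose two-class pooled correlation equals R."""
    c = p * (1 - p) * delta**2
    scale = np.sqrt(1.0 + c)
    C = R * np.outer(scale, scale) - p * (1 - p) * np.outer(delta, delta)
    # unit diagonal by construction: (1+c) - c = 1
    w = np.linalg.eigvalsh(C)
    repaired = False
    if w.min() < 0:
        C, repaired = _nearest_corr(C)
    return C, repaired


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw one cohort under ``config``; bit-reproducible for a given seed."""
    rng = np.random.default_rng(config.seed)
    names = list(config.marker_names)
    m = len(names)
    n, k = config.n, config.n_progressors
    p = k / n

    delta = np.array([config.effects.get(name, 0.0) for name in names])
    notes: list[str] = []

    R = config.corr.to_numpy()
    R, corr_repaired = _nearest_corr(R)
    if corr_repaired:
        notes.append("target correlation matrix repaired to PSD by eigenvalue clipping")
    C, cov_repaired = _within_class_cov(R, delta, p)
    if cov_repaired:
        notes.append("within-class covariance repaired to PSD by eigenvalue clipping")
    L = np.linalg.cholesky(C + 1e-12 * np.eye(m))

    outcome = np.zeros(n, dtype=int)
    outcome[:k] = 1
    rng.shuffle(outcome)
    # class-conditional latent means keep the pooled mean at zero
    shift = np.where(outcome[:, None] == 1, (1 - p), -p) * delta[None, :]

    c = p * (1 - p) * delta**2
    pooled_sd = np.sqrt(1.0 + c)

    def draw(rows: np.ndarray) -> np.ndarray:
        z = rng.standard_normal((len(rows), m)) @ L.T + shift[rows]
        return z

    def to_measurement(z: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(z, columns=names)
        for name in names:
            if name in config.binary_prevalence:
                prev = config.binary_prevalence[name]
                i = names.index(name)
                t = pooled_sd[i] * stats.norm.ppf(1 - prev)
                df[name] = (df[name].to_numpy() > t).astype(float)
            elif name in config.location_scale:
                loc, scale = config.location_scale[name]
                i = names.index(name)
                df[name] = loc + scale * df[name].to_numpy() / pooled_sd[i]
        for name in PG_COLUMNS + INS_COLUMNS:
            if name in df.columns:
                df[name] = np.maximum(df[name].to_numpy(), 0.0)
        return df

    rows = np.arange(n)
    markers = to_measurement(draw(rows))

    # the emulated cohort is nondiabetic at entry: redraw rows that would be
    # diabetic at baseline (or carry a degenerate nonpositive glucose value)
    has_glucose = "pg0" in names and "pg120" in names
    if has_glucose:
        n_redrawn = 0
        for _ in range(200):
            pg0 = markers["pg0"].to_numpy()
            pg2 = markers["pg120"].to_numpy()
            invalid = (pg0 <= 0) | (pg2 <= 0) | (pg0 >= 7.0) | (pg2 >= 11.1)
            if not invalid.any():
                break
            idx = np.flatnonzero(invalid)
            n_redrawn += len(idx)
            markers.iloc[idx] = to_measurement(draw(idx)).to_numpy()
        else:
            raise RuntimeError("baseline-diabetes rejection did not converge")
        if n_redrawn:
            notes.append(f"redrew {n_redrawn} baseline-diabetic draws (rejection)")
        status = classify_glycemic_status_frame(
            markers["pg0"].to_numpy(), markers["pg120"].to_numpy()
        )
        assert not (status == GlycemicStatus.T2D).any()
    else:
        status = None

    for name, rate in config.missing_rate.items():
        if name in markers.columns and rate > 0:
            drop = rng.random(n) < rate
            markers.loc[drop, name] = np.nan

    ids = np.array([f"P{i + 1:04d}" for i in range(n)])
    return Cohort(
        markers=markers,
        outcome=outcome,
        participant_id=ids,
        status=status,
        notes=notes,
    )
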