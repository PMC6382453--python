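"""Cohort data model, I/O, preprocessing and baseline association statistics.

A cohort is a per-participant table of clinical and metabolic markers from a
prospective oral glucose tolerance test (OGTT) study, together with a binary
progression outcome (1 = progressed to type 2 diabetes during follow-up) and a
baseline glycemic stratum derived from the WHO criteria on fasting and 2-hour
plasma glucose.

Missingness has two policies, applied by the pipeline per variable class:
metabolite columns are imputed with the minimum nonmissing measurement, while
clinical/glucose/insulin variables are handled by per-model complete-case
exclusion (:func:`complete_cases`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GlycemicStatus",
    "Cohort",
    "PG_COLUMNS",
    "METABOLITE_COLUMNS",
    "classify_glycemic_status",
    "classify_glycemic_status_frame",
    "load_cohort",
    "standardize",
    "impute_min",
    "complete_cases",
    "fisher_exact",
    "welch_t",
    "pearson_r",
    "cohort_summary",
]

#: OGTT plasma-glucose columns, mmol/L, at 0/30/60/120 minutes.
PG_COLUMNS = ("pg0", "pg30", "pg60", "pg120")

#: The six serum metabolic markers carried through the benchmark.
METABOLITE_COLUMNS = (
    "mannose",
    "ahb",
    "hyp3_bk",
    "a_tocopherol",
    "carnitine_10_1",
    "x12063",
)

#: Strings treated as missing when reading delimited tables.
NA_SENTINELS = ("", "NA")


class GlycemicStatus(enum.Enum):
    """WHO glycemic category from a (fasting, 2-hour) plasma glucose pair.

    T2D is diagnostic (overt diabetes) rather than a baseline stratum; cohorts
    analysed here are nondiabetic at baseline, so participant status is one of
    NORMAL / IFG / IGT.
    """

    NORMAL = "NORMAL"
    IFG = "IFG"
    IGT = "IGT"
    T2D = "T2D"


def classify_glycemic_status(fpg: float, pg2h: float) -> GlycemicStatus:
    """Classify a (FPG, 2-hour PG) pair in mmol/L by the WHO criteria.

    * T2D: FPG >= 7.0 or 2-h PG >= 11.1 (takes precedence);
    * IFG: 6.1 <= FPG < 7.0 and 2-h PG < 7.8;
    * IGT: FPG < 7.0 and 7.8 <= 2-h PG < 11.1;
    * NORMAL otherwise.

    The IFG and IGT windows are disjoint by construction (IFG requires
    2-h PG < 7.8, IGT requires >= 7.8), so the map is a partition.
    """
    fpg = float(fpg)
    pg2h = float(pg2h)
    if not (np.isfinite(fpg) and np.isfinite(pg2h)) or fpg <= 0 or pg2h <= 0:
        raise ValueError(
            f"glucose values must be finite and positive, got ({fpg}, {pg2h})"
        )
    if fpg >= 7.0 or pg2h >= 11.1:
        return GlycemicStatus.T2D
    if 6.1 <= fpg and pg2h < 7.8:
        return GlycemicStatus.IFG
    if 7.8 <= pg2h:
        return GlycemicStatus.IGT
    return GlycemicStatus.NORMAL


def classify_glycemic_status_frame(
    fpg: np.ndarray, pg2h: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`classify_glycemic_status`; returns an object array."""
    fpg = np.asarray(fpg, dtype=float)
    pg2h = np.asarray(pg2h, dtype=float)
    bad = ~np.isfinite(fpg) | ~np.isfinite(pg2h) | (fpg <= 0) | (pg2h <= 0)
    if bad.any():
        raise ValueError("glucose values must be finite and positive")
    out = np.full(fpg.shape, GlycemicStatus.NORMAL, dtype=object)
    out[(7.8 <= pg2h)] = GlycemicStatus.IGT
    out[(6.1 <= fpg) & (pg2h < 7.8)] = GlycemicStatus.IFG
    out[(fpg >= 7.0) | (pg2h >= 11.1)] = GlycemicStatus.T2D
    return out


@dataclass
class Cohort:
    """Participant-by-marker table with outcome and baseline glycemic status.

    Attributes
    ----------
    markers:
        Numeric DataFrame, one row per participant; missing values are NaN.
        Glucose columns are in mmol/L; metabolites in standardized units.
    outcome:
        Integer array, 1 for progressors, 0 otherwise.
    participant_id:
        Opaque labels, unique, aligned with ``markers`` rows.
    status:
        Baseline :class:`GlycemicStatus` per participant, or None when the
        glucose columns needed to derive it are absent.
    """

    markers: pd.DataFrame
    outcome: np.ndarray
    participant_id: np.ndarray
    status: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=int)
        if len(self.markers) != len(self.outcome):
            raise ValueError("markers and outcome lengths differ")
        levels = np.unique(self.outcome)
        if not np.isin(levels, [0, 1]).all() or len(levels) != 2:
            raise ValueError("outcome must contain exactly the levels {0, 1}")
        ids = np.asarray(self.participant_id)
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate participant ids")
        if len(set(self.markers.columns)) != len(self.markers.columns):
            raise ValueError("marker names must be unique")
        for col in PG_COLUMNS:
            if col in self.markers.columns:
                vals = self.markers[col].to_numpy(dtype=float)
                finite = vals[np.isfinite(vals)]
                if finite.size and finite.min() < 0:
                    raise ValueError(f"negative glucose values in {col}")

    @property
    def n(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list[str]:
        return list(self.markers.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True wherever a marker value is absent."""
        return self.markers.isna()

    def subset(self, rows: np.ndarray) -> "Cohort":
        """Row-subset preserving alignment; ``rows`` is an index or bool mask."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return Cohort(
            markers=self.markers.iloc[rows].reset_index(drop=True),
            outcome=self.outcome[rows],
            participant_id=np.asarray(self.participant_id)[rows],
            status=None if self.status is None else np.asarray(self.status)[rows],
            notes=list(self.notes),
        )


def load_cohort(
    path,
    schema: dict | None = None,
) -> Cohort:
    """Read a delimited (comma or tab) per-participant marker table.

    Parameters
    ----------
    path:
        CSV/TSV file with a header row. Empty strings and ``NA`` are missing.
    schema:
        Optional column-role mapping with keys ``participant_id``, ``outcome``
        and optionally ``markers`` (list restricting/ordering marker columns)
        and ``rename`` (file column -> canonical marker name). Defaults:
        ``participant_id`` / ``outcome`` columns by those names, all remaining
        columns as markers.
    """
    schema = dict(schema or {})
    id_col = schema.get("participant_id", "participant_id")
    outcome_col = schema.get("outcome", "outcome")
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(
        path, sep=sep, na_values=list(NA_SENTINELS), keep_default_na=False
    )
    if rename := schema.get("rename"):
        df = df.rename(columns=rename)
    if outcome_col not in df.columns:
        raise ValueError(f"missing outcome column {outcome_col!r}")
    outcome_raw = df[outcome_col]
    levels = pd.unique(outcome_raw.dropna())
    if len(levels) != 2 or not set(levels) <= {0, 1, 0.0, 1.0}:
        raise ValueError(
            f"outcome column must be binary 0/1, found levels {sorted(levels)}"
        )
    if id_col in df.columns:
        ids = df[id_col].to_numpy()
    else:
        ids = np.arange(len(df))
    marker_cols = schema.get("markers") or [
        c for c in df.columns if c not in (id_col, outcome_col)
    ]
    markers = df[marker_cols].apply(pd.to_numeric, errors="coerce")
    status = None
    if "pg0" in markers.columns and "pg120" in markers.columns:
        pg0 = markers["pg0"].to_numpy(dtype=float)
        pg2 = markers["pg120"].to_numpy(dtype=float)
        ok = np.isfinite(pg0) & np.isfinite(pg2) & (pg0 > 0) & (pg2 > 0)
        status = np.full(len(markers), None, dtype=object)
        if ok.any():
            status[ok] = classify_glycemic_status_frame(pg0[ok], pg2[ok])
    return Cohort(
        markers=markers,
        outcome=outcome_raw.to_numpy(dtype=int),
        participant_id=ids,
        status=status,
    )


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort in the same delimited layout :func:`load_cohort` reads."""
    df = cohort.markers.copy()
    df.insert(0, "participant_id", cohort.participant_id)
    df["outcome"] = cohort.outcome
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.6g")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def standardize(values: np.ndarray) -> np.ndarray:
    """Scale the nonmissing entries to zero mean and unit variance.

    Missing (NaN) entries are left untouched. Raises on fewer than two
    nonmissing values or zero variance (a constant marker carries no signal
    and silently zeroing it would hide that).
    """
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    if obs.sum() < 2:
        raise ValueError("need at least two nonmissing values to standardize")
    mu = values[obs].mean()
    sd = values[obs].std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant (zero-variance) vector")
    out = values.copy()
    out[obs] = (values[obs] - mu) / sd
    return out


def impute_min(values: np.ndarray) -> np.ndarray:
    """Replace missing entries with the minimum nonmissing measurement.

    This is the convention for metabolite abundances where a missing value
    typically reflects a measurement below the detection limit.
    """
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    if not obs.any():
        raise ValueError("all values missing; nothing to impute from")
    out = values.copy()
    out[~obs] = values[obs].min()
    return out


def impute_metabolites(cohort: Cohort, columns=METABOLITE_COLUMNS) -> Cohort:
    """Minimum-impute the metabolite columns present in the cohort."""
    markers = cohort.markers.copy()
    for col in columns:
        if col in markers.columns and markers[col].isna().any():
            markers[col] = impute_min(markers[col].to_numpy(dtype=float))
    return Cohort(
        markers=markers,
        outcome=cohort.outcome,
        participant_id=cohort.participant_id,
        status=cohort.status,
        notes=list(cohort.notes),
    )


def complete_cases(cohort: Cohort, variables) -> Cohort:
    """Rows with no missing entry among ``variables`` (per-model exclusion).

    Raises if the subset loses an outcome level entirely, since no two-class
    analysis is then possible.
    """
    variables = list(variables)
    unknown = [v for v in variables if v not in cohort.markers.columns]
    if unknown:
        raise KeyError(f"unknown marker(s): {unknown}")
    keep = ~cohort.markers[variables].isna().any(axis=1).to_numpy()
    if len(np.unique(cohort.outcome[keep])) < 2:
        raise ValueError(
            "complete-case subset lost an outcome level for variables "
            f"{variables}"
        )
    return cohort.subset(keep) if keep.sum() < cohort.n else cohort


# ---------------------------------------------------------------------------
# Baseline association statistics (cohort description)
# ---------------------------------------------------------------------------


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sidedness by the usual convention: sum hypergeometric probabilities of
    all tables (at fixed margins) no more probable than the observed one.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        raise ValueError("both margins must be positive")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch unequal-variance t test; returns (t, Welch-Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-transform p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cohort_summary(cohort: Cohort, binary_markers=("sex", "fh")) -> pd.DataFrame:
    """Per-variable baseline association with the progression outcome.

    Binary markers get a Fisher exact p from the induced 2x2 table; continuous
    markers a Welch t p comparing progressors vs nonprogressors. Rows with a
    missing value for a variable are excluded for that variable only.
    """
    rows = []
    y = cohort.outcome
    for name in cohort.marker_names:
        v = cohort.markers[name].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        v_ok, y_ok = v[ok], y[ok]
        entry = {
            "variable": name,
            "n": int(ok.sum()),
            "mean_progressor": float(np.mean(v_ok[y_ok == 1])),
            "mean_nonprogressor": float(np.mean(v_ok[y_ok == 0])),
        }
        if name in binary_markers:
            tab = [
                [int(((v_ok == 1) & (y_ok == 1)).sum()), int(((v_ok == 1) & (y_ok == 0)).sum())],
                [int(((v_ok == 0) & (y_ok == 1)).sum()), int(((v_ok == 0) & (y_ok == 0)).sum())],
            ]
            try:
                entry["test"] = "fisher"
                entry["p"] = fisher_exact(tab)
            except ValueError:
                entry["p"] = np.nan
        else:
            try:
                entry["test"] = "welch"
                entry["p"] = welch_t(v_ok[y_ok == 1], v_ok[y_ok == 0])[2]
            except ValueError:
                entry["p"] = np.nan
        rows.append(entry)
    return pd.DataFrame(rows)
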