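"""End-to-end benchmark orchestration.

``run_benchmark`` takes a cohort (loaded or simulated), enumerates the
candidate variable sets, scores each with repeated nested cross-validated
regularized least squares, summarizes each model's ROC (AUC with CI, F-index
cutoff and its confusion metrics), compares every non-reference model to the
reference model (the 1-h plasma glucose singleton by default) with DeLong's
paired test, and calibrates the batch of comparison p-values into positive-FDR
q-values with the two-decimal-rounding significance rule.

Because complete-case participant sets differ between models, each DeLong
comparison is run on the intersection of the two models' complete-case rows;
the reference model's scores are recomputed on that common subset (cached per
subset) so the pairing is valid. Each such recomputation is noted in the run
manifest.

``run_stratified`` reruns the whole benchmark inside the baseline IFG/IGT and
IFG/IGT-free strata; stratified comparisons report raw DeLong p-values
without the q-value batch, matching how subgroup analyses are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, GlycemicStatus, complete_cases, impute_metabolites
from .enumeration import ModelFamily, VariableSet, default_grid, enumerate_grid
from .rls import CVConfig, nested_cv_scores
from .roc import (
    delong_paired_test,
    evaluate_scores,
    qvalues,
    significance_call,
    storey_pi0,
)
from .simulate import SimConfig, generate_cohort

__all__ = ["RunConfig", "BenchmarkResult", "run_benchmark", "run_stratified"]

#: Default reference model: the 1-hour plasma glucose singleton.
DEFAULT_REFERENCE = ("pg60",)


@dataclass
class RunConfig:
    """One full benchmark run.

    pi0_mode : ``storey`` (fixed-lambda positive-FDR estimate) or ``bh``
        (pi0 = 1, plain Benjamini-Hochberg) for the q-value batch.
    ci_method : ``analytic`` or ``stratified_bootstrap`` AUC interval.
    """

    families: list[ModelFamily] = field(default_factory=default_grid)
    cv: CVConfig = field(default_factory=CVConfig)
    reference: tuple[str, ...] = DEFAULT_REFERENCE
    ci_method: str = "analytic"
    ci_replicates: int = 2000
    pi0_mode: str = "storey"
    impute_metabolite_columns: bool = True
    seed: int = 0


@dataclass
class BenchmarkResult:
    """Results table plus provenance: one performance row per model, one
    comparison row per non-reference model, and the run manifest."""

    table: pd.DataFrame
    provenance: pd.DataFrame
    manifest: dict

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")

    def summary(self) -> str:
        """Plain-text report: each model's AUC, cutoff metrics and q."""
        lines = [
            f"{len(self.table)} models benchmarked against reference "
            f"{self.manifest['reference']} "
            f"(n = {self.manifest['cohort_n']}, "
            f"{self.manifest['cohort_progressors']} progressors)",
            "",
        ]
        for _, r in self.table.sort_values("auc", ascending=False).iterrows():
            q = "ref" if r["is_reference"] else f"q={r['q']:.2f}"
            lines.append(
                f"  {r['variables']}: AUC {r['auc']:.2f} "
                f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f}), "
                f"sens {r['sensitivity']:.2f}, spec {r['specificity']:.2f}, {q}"
            )
        sig = self.table[self.table["significant"] == True]  # noqa: E712
        lines += [
            "",
            f"{len(sig)} models significantly outperform or underperform the "
            "reference (rounded q < 0.05)",
        ]
        return "\n".join(lines)


def _model_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % 2**31)


def run_benchmark(
    cohort: Cohort, config: RunConfig | None = None
) -> BenchmarkResult:
    """Score every enumerated model and compare each to the reference."""
    config = config or RunConfig()
    manifest: dict = {
        "seed": config.seed,
        "cv": {
            "repetitions": config.cv.repetitions,
            "outer_folds": config.cv.outer_folds,
            "inner_folds": config.cv.inner_folds,
            "lambda_grid": [float(x) for x in config.cv.lambda_grid],
        },
        "ci_method": config.ci_method,
        "pi0_mode": config.pi0_mode,
        "notes": list(cohort.notes),
    }
    if config.impute_metabolite_columns:
        cohort = impute_metabolites(cohort)
        manifest["metabolite_imputation"] = "minimum nonmissing per metabolite"

    models, provenance = enumerate_grid(config.families)
    reference = VariableSet(config.reference)
    if reference not in models:
        models = [reference] + models
        provenance = pd.concat(
            [
                pd.DataFrame(
                    [{"model_id": -1, "variables": reference.label,
                      "n_variables": len(reference), "families": "reference"}]
                ),
                provenance,
            ],
            ignore_index=True,
        )
        manifest["reference_added"] = True
    manifest["reference"] = reference.label
    manifest["n_models"] = len(models)
    manifest["cohort_n"] = cohort.n
    manifest["cohort_progressors"] = int(cohort.outcome.sum())

    # scores for each model on its own complete-case rows
    score_cache: dict[tuple, np.ndarray] = {}

    def scores_for(vs: VariableSet, rows: np.ndarray, seed: int) -> np.ndarray:
        key = (vs.members, rows.tobytes())
        if key not in score_cache:
            sub = cohort.subset(rows)
            X = sub.markers[list(vs.members)].to_numpy(dtype=float)
            cv = CVConfig(
                repetitions=config.cv.repetitions,
                outer_folds=config.cv.outer_folds,
                inner_folds=config.cv.inner_folds,
                lambda_grid=config.cv.lambda_grid,
                seed=seed,
            )
            score_cache[key] = nested_cv_scores(X, sub.outcome, cv)
        return score_cache[key]

    def case_rows(vs: VariableSet) -> np.ndarray:
        keep = ~cohort.markers[list(vs.members)].isna().any(axis=1).to_numpy()
        rows = np.flatnonzero(keep)
        if len(np.unique(cohort.outcome[rows])) < 2:
            raise ValueError(
                f"complete-case subset for {vs.label} lost an outcome level"
            )
        return rows

    ref_rows = case_rows(reference)
    ref_seed = _model_seed(config.seed, 0)

    rows_out = []
    comparisons = []
    recompute_notes = []
    for idx, vs in enumerate(models):
        rows = case_rows(vs)
        seed = ref_seed if vs == reference else _model_seed(config.seed, idx + 1)
        scores = scores_for(vs, rows, seed)
        labels = cohort.outcome[rows]
        perf = evaluate_scores(
            scores,
            labels,
            ci_method=config.ci_method,
            ci_replicates=config.ci_replicates,
            seed=seed,
        )
        record = {
            "model_id": idx,
            "variables": vs.label,
            "n_variables": len(vs),
            "n_complete": perf.n,
            "is_reference": vs == reference,
            "auc": perf.auc,
            "ci_low": perf.ci_low,
            "ci_high": perf.ci_high,
            "cutoff": perf.cutoff,
            "accuracy": perf.accuracy,
            "sensitivity": perf.sensitivity,
            "specificity": perf.specificity,
            "ppv": perf.ppv,
            "npv": perf.npv,
        }
        if vs == reference:
            # self-comparison is degenerate by construction (identical
            # rankings): delta 0, p 1; excluded from the q batch below
            record.update(delta_auc=0.0, z=0.0, p=1.0)
        else:
            common = np.intersect1d(rows, ref_rows)
            in_common = np.isin(rows, common)
            model_scores_c = scores[in_common]
            if len(common) == len(ref_rows):
                ref_scores_c = scores_for(reference, ref_rows, ref_seed)
            else:
                ref_scores_c = scores_for(reference, common, ref_seed)
                recompute_notes.append(
                    f"{vs.label}: reference rescored on common n={len(common)}"
                )
            cmp_res = delong_paired_test(
                model_scores_c, ref_scores_c, cohort.outcome[common]
            )
            record.update(delta_auc=cmp_res.delta_auc, z=cmp_res.z, p=cmp_res.p)
            comparisons.append((idx, cmp_res))
        rows_out.append(record)

    table = pd.DataFrame(rows_out)
    # q-values over the single batch of all non-reference comparisons
    pvals = np.array([c.p for _, c in comparisons])
    if len(pvals):
        pi0 = 1.0 if config.pi0_mode == "bh" else storey_pi0(pvals)
        manifest["pi0"] = pi0
        qs = qvalues(pvals, pi0=pi0)
        qmap = {idx: q for (idx, _), q in zip(comparisons, qs)}
        table["q"] = table["model_id"].map(qmap)
        table["significant"] = [
            significance_call(q) if np.isfinite(q) else None
            for q in table["q"].fillna(np.nan)
        ]
    else:
        table["q"] = np.nan
        table["significant"] = None
    manifest["reference_rescored"] = recompute_notes
    return BenchmarkResult(table=table, provenance=provenance, manifest=manifest)


def run_stratified(
    cohort: Cohort, config: RunConfig | None = None
) -> dict[str, BenchmarkResult]:
    """Rerun the benchmark inside the IFG/IGT and IFG/IGT-free strata.

    Raises if the cohort has no baseline status, a stratum is empty, or a
    stratum retains only one outcome class. Stratified tables keep raw DeLong
    p-values; no q-value batch is formed within strata.
    """
    config = config or RunConfig()
    if cohort.status is None:
        raise ValueError("cohort has no baseline glycemic status")
    status = np.asarray(cohort.status)
    in_ifg_igt = np.isin(status, [GlycemicStatus.IFG, GlycemicStatus.IGT])
    strata = {"ifg_igt": in_ifg_igt, "ifg_igt_free": ~in_ifg_igt}
    out: dict[str, BenchmarkResult] = {}
    for name, mask in strata.items():
        if mask.sum() == 0:
            raise ValueError(f"stratum {name!r} is empty")
        if len(np.unique(cohort.outcome[mask])) < 2:
            raise ValueError(f"stratum {name!r} has a single outcome class")
        sub = cohort.subset(mask)
        res = run_benchmark(sub, config)
        res.table["q"] = np.nan
        res.table["significant"] = None
        res.manifest["stratum"] = name
        out[name] = res
    return out


def write_run(
    result: BenchmarkResult, outdir, name: str = "benchmark"
) -> None:
    """Write results table, provenance and manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.to_tsv(outdir / f"{name}_results.tsv")
    result.provenance.to_csv(
        outdir / f"{name}_models.tsv", sep="\t", index=False
    )
    (outdir / f"{name}_manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str)
    )
    (outdir / f"{name}_summary.txt").write_text(result.summary() + "\n")
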