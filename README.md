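# ogttbench

Systematic benchmarking of predictive models for progression to type 2
diabetes from oral glucose tolerance test (OGTT) data.

## The problem

In prospective diabetes cohorts, the question is rarely whether a single
marker predicts progression but which *combination* does best: plasma glucose
(PG) at 0/30/60/120 min of an OGTT, serum insulin at the same time points,
HbA1c, clinical risk factors (age, sex, BMI, family history), and serum
metabolites such as mannose, α-hydroxybutyrate (AHB) or
bradykinin-hydroxyproline. Answering it honestly requires evaluating every
combination under identical, leakage-free cross-validation, and then
comparing each candidate to a strong reference — 1-hour PG — with a test
that respects the correlation between ROC curves computed on the same
participants, corrected for the hundreds of comparisons made.

`ogttbench` implements that pipeline end to end for biostatisticians and
epidemiologists, together with a synthetic cohort generator so the entire
workflow is testable without access to any private study data.

## Method

For each candidate variable set *V*:

1. **Scoring.** A regularized least-squares (ridge) classifier on the ±1-coded
   outcome, `min ‖y − Xw‖² + λ‖w‖²` (intercept unpenalized, closed form via a
   single SVD reused across the λ grid). Performance is estimated by repeated
   nested cross-validation: stratified outer folds hold participants out,
   inner folds pick λ ∈ 2^(−10…10) by out-of-fold AUC, standardization is fit
   on training folds only, and out-of-fold scores are averaged over 100
   fold re-randomizations.
2. **ROC summary.** AUC by the Mann–Whitney statistic (ties ½) with a 95% CI
   from DeLong's structural-component variance (analytic, or a 2000-replicate
   class-stratified bootstrap). The operating cutoff maximizes the F-index —
   the harmonic mean of sensitivity and specificity — and accuracy,
   sensitivity, specificity, PPV and NPV are reported there.
3. **Comparison.** Each model is compared to the reference (1-h PG) with
   DeLong's paired z test for correlated ROC curves,
   z = ΔAUC / √(var_A + var_B − 2·cov_AB), on the participants shared by the
   two models' complete-case subsets.
4. **Multiplicity.** The batch of comparison p-values is converted to
   positive-FDR q-values (Storey's fixed-λ π₀ estimate, or π₀ = 1 for plain
   Benjamini–Hochberg); a model is called significant when its q-value,
   rounded to two decimals, is strictly below 0.05.

Candidate sets are enumerated exhaustively from declarative families (base
markers + pools of optional units, the clinical factors forming one atomic
unit), e.g. the family "1-h PG, ≥1 of 6 metabolites, ±HbA1c, ±clinical
block" spans (2⁶−1)·2·2 = 252 models.

The generator draws a latent Gaussian cohort with class-conditional mean
shifts calibrated so single-marker binormal AUCs and cohort-level marker
correlations match published values (e.g. mannose–30-min PG r = 0.32),
assigns WHO baseline strata (IFG/IGT) from fasting and 2-h glucose, and
rejects baseline-diabetic draws.

## Worked example

```python
import ogttbench as ob

cohort = ob.generate_cohort(ob.default_sim_config(seed=1))   # 543, 146 progressors
families = [
    ob.ModelFamily("pg_singles",
        pools=(ob.Pool((("pg0",), ("pg30",), ("pg60",), ("pg120",)),
                       min_take=1, max_take=1),)),
    ob.ModelFamily("metabolites",
        pools=(ob.Pool((("mannose",), ("ahb",), ("hyp3_bk",), ("a_tocopherol",),
                        ("carnitine_10_1",), ("x12063",)), min_take=6),)),
    ob.ModelFamily("pg60+hba1c+metabolites",
        base=("pg60", "hba1c", "mannose", "ahb", "hyp3_bk",
              "a_tocopherol", "carnitine_10_1", "x12063")),
    ob.ModelFamily("hba1c", base=("hba1c",)),
]
config = ob.RunConfig(families=families, cv=ob.CVConfig(repetitions=20, seed=1), seed=1)
print(ob.run_benchmark(cohort, config).summary())
```

prints

```
7 models benchmarked against reference pg60 (n = 543, 146 progressors)

  a_tocopherol+ahb+carnitine_10_1+hba1c+hyp3_bk+mannose+pg60+x12063: AUC 0.80 (95% CI 0.75-0.84), sens 0.65, spec 0.82, q=0.02
  pg60: AUC 0.76 (95% CI 0.72-0.80), sens 0.74, spec 0.66, ref
  a_tocopherol+ahb+carnitine_10_1+hyp3_bk+mannose+x12063: AUC 0.74 (95% CI 0.69-0.79), sens 0.73, spec 0.68, q=0.18
  pg30: AUC 0.73 (95% CI 0.68-0.78), sens 0.68, spec 0.68, q=0.08
  pg120: AUC 0.67 (95% CI 0.62-0.73), sens 0.62, spec 0.68, q=0.00
  hba1c: AUC 0.66 (95% CI 0.60-0.71), sens 0.69, spec 0.56, q=0.00
  pg0: AUC 0.62 (95% CI 0.56-0.67), sens 0.60, spec 0.59, q=0.00

4 models significantly outperform or underperform the reference (rounded q < 0.05)
```

Read it as the field does: 1-h PG is the strongest single glucose time point
(AUC 0.76); fasting glucose and HbA1c alone are clearly weaker (q = 0.00);
the six-metabolite panel is comparable to 1-h PG (q = 0.18); and adding
HbA1c and the metabolites to 1-h PG lifts the AUC to 0.80 with a
significant improvement (q = 0.02).

The same run from the shell:

```bash
ogttbench simulate --out cohort.tsv --seed 1
ogttbench run-all --out results/ --seed 1 --reps 100 --stratify
```

`run-all` writes the results table (TSV: variables, n, AUC, CI, cutoff,
accuracy/sens/spec/PPV/NPV, ΔAUC, DeLong p, q, significance call), the model
provenance table, a JSON manifest echoing every default used, and a text
summary; `--stratify` reruns the benchmark inside the baseline IFG/IGT and
IFG/IGT-free strata. Staged commands `enumerate`, `score`, `compare`,
`report` expose the intermediate steps.

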