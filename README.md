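# psamine

Discovery of prognostic patterns in longitudinal PSA trajectories of
prostate-cancer patients under androgen deprivation therapy (ADT).

## The problem

After ADT starts, PSA (prostate specific antigen, ng/ml) typically falls to
a minimum — the *nadir* — and then either stays controlled (hormone-sensitive
disease, HSPC) or rises again as the tumour becomes castration-resistant
(CRPC). Classical prognostic markers (pretreatment PSA, nadir level, time to
nadir) use only one or two values of the series. `psamine` instead mines the
*whole* trajectory for prognostic subsequences:

1. **Velocity transformation.** Each consecutive pair of measurements gives a
   PSA velocity `PSAV = (PSA_t2 − PSA_t1) / (t2 − t1)` in ng/(ml·mo); the
   series is split at the nadir into before- and after-nadir segments.
2. **Discretization.** Pooled velocities are binned into ordinal states by
   equal-frequency binning (five states, `L_q … H_q`) and by Fayyad–Irani
   entropy/MDL supervised discretization on the outcome class
   (`L_e, M_e, H_e, …`).
3. **Sequential pattern mining.** PrefixSpan finds, per outcome class, every
   state subsequence with support ≥ 0.3 and length ≤ 3 (patterns are
   time-ordered but not necessarily consecutive).
4. **Predictive selection.** Each candidate pattern becomes a binary patient
   feature added to the 14-covariate baseline B; stratified 10-fold
   cross-validation measures `ΔAUC = AUC(B ∪ p) − AUC(B)` (logistic
   regression) and `ΔC-index` (Cox proportional hazards), with one-sided
   paired t-tests across folds. Patterns improving both metrics
   significantly (α = 0.05) are kept.
5. **Informative selection.** Among the predictive patterns, a partial order
   prefers the more specific/rarer pattern: a pattern dominates its
   sub-patterns, dominates equal-length patterns with wider state intervals,
   and — when neither structural rule applies — the rarer pattern wins.
6. **Survival comparison.** The final pattern is compared against the
   dichotomized classical factors (pretreatment PSA ≥ 100 ng/ml,
   nadir ≥ 0.2 ng/ml, time to nadir ≥ 12 months) by Kaplan–Meier curves and
   log-rank tests on progression-free survival.

Because no public cohort accompanies this method, the package ships a
seedable synthetic cohort generator (`psamine.simulate`) that plants the
structure the method is designed to detect: non-progressors always show the
configured number of substantial post-nadir declines (≥ 0.048 ng/(ml·mo)),
progressors never show a repeated one.

## Worked example

```python
from psamine import SimConfig, run_pipeline

report = run_pipeline({"seed": 1, "sim": {"n_patients": 300}}, outdir="out")
after = report["segments"]["after_nadir"]
print("final pattern:", after["final_pattern"])
for c in report["survival"]:
    print(f"{c.grouping_name:18s} log-rank={c.logrank_statistic:7.2f}  p={c.p_value:.2g}")
```

prints (seed 1):

```
final pattern: ML_q→L_q→L_q
pattern            log-rank=  33.24  p=8.1e-09
pretreatment_psa   log-rank=   0.34  p=0.56
nadir_psa          log-rank=   0.15  p=0.7
time_to_nadir      log-rank=   5.37  p=0.02
```

The selected pattern `ML_q→L_q→L_q` reads: a small velocity followed by two
bottom-state declines after the nadir — i.e. the PSA *dropped substantially
twice* after reaching its minimum. Patients carrying it progress far more
slowly (the pattern's log-rank statistic dwarfs the classical markers'); by
the contrapositive, patients without repeated post-nadir declines are the
high-risk group. On this cohort the pattern raised the cross-validated AUC
from 0.67 (baseline) by 0.102 (paired p = 7e-4).

The same pipeline is scriptable from the shell:

```bash
psamine simulate -c config.yaml -o cohort/     # writes measurements.csv, covariates.csv
psamine discover -c config.yaml -o artifacts/  # candidates.csv, evaluation.csv,
                                               # selection.json, survival.csv, run.log
```

`config.yaml` carries the nested keys of
`psamine.pipeline.DEFAULT_CONFIG` (`io.*`, `sim.*`, `transform.*`,
`mining.*`, `selection.*`, `survival.*`, `seed`); flags override the file.

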