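# renal-angina

Severe acute kidney injury (AKI) complicates half or more of pediatric
septic-shock admissions, and creatinine-based recognition comes too late
for early renal protection. The **renal angina index (RAI)** addresses
this by crossing a *risk* tier (1 — PICU admission, 3 — solid-organ or
stem-cell transplant, 5 — mechanical ventilation or vasoactive support)
with an *injury* tier (1/2/4/8 from the worse of the first-12-hour
creatinine fold-change over baseline and the percent fluid overload):

```
RAI = risk × injury ∈ {1, …, 40},    RAI+  ⇔  RAI ≥ 8
```

This package implements, as a tested and reusable library with a CLI, the
complete analysis pipeline used to evaluate early RAI as a predictor of
severe AKI (KDIGO stage ≥ 2 within 3 days) in children with septic shock:

- **records_io** — a patient data model over two delimited text tables
  (`cohort.csv` + long-format `timeseries.csv`) and the cohort eligibility
  filter (stay < 48 h, known kidney disease, AKI onset after day 3, severe
  AKI within 12 h of admission);
- **kdigo** — baseline creatinine (lowest value in the prior 3 months, or
  bedside-Schwartz back-calculation at an assumed eGFR of
  120 mL/min/1.73 m²) and 2012 KDIGO staging from creatinine and
  urine-output criteria;
- **fluid** — fluid overload, FO% = (Σin − Σout)[L] / weight[kg] × 100,
  FO+ at > 10 %;
- **rai** — the index itself;
- **stats** — 2×2 odds ratios with Wald CIs, chi-square with Fisher
  fallback, Wilcoxon/t group comparisons, logistic regression by
  Newton–Raphson IRLS, ROC/AUC (Mann–Whitney with ties counted ½,
  Hanley–McNeil CIs), the Youden optimal cutoff and the combined
  RAI+&lactate logistic score;
- **summary** — the group-comparison tables (survivors vs non-survivors,
  severe-AKI vs not, RAI− vs RAI+, and the three early-warning strata);
- **synthetic** — a two-layer synthetic cohort generator (indicator-level
  draws and raw creatinine/urine/fluid trajectories) reproducing the
  conditional indicator frequencies and biomarker distributions of a
  66-patient septic-shock PICU cohort.

## Worked example

Simulate a cohort (66 eligible patients plus the 18 exclusion-archetype
records) and run the full analysis:

```sh
renal-angina simulate --mode trajectories --n 66 --out demo
renal-angina report --cohort demo/cohort.csv --timeseries demo/timeseries.csv --out demo_report
```

which prints (deterministic for the default seed):

```
renal-angina 0.1.0 analysis report

eligible patients: 66
rai_positive: OR 4.63 (95% CI 1.63-13.17), AUC 0.6801
scr_gt_base: OR 2.68 (95% CI 0.99-7.26), AUC 0.6204
fo_positive: OR unavailable (zero cell 'b' (enable the Haldane correction)), AUC 0.5882
lactate: AUC 0.5083, Youden cutoff 4.95 mmol/L
combined RAI+ & lactate: AUC 0.6820
```

Here 18 of 84 simulated records were excluded by the eligibility filter,
and on the remaining 66 an early RAI+ multiplies the odds of severe AKI
by 4.6 (read from the RAI+ × severe-AKI 2×2 table) and discriminates with
AUC 0.68 — single draws of a 66-patient cohort are noisy, which is the
point of carrying the full uncertainty through. The bundle under
`demo_report/` contains every intermediate table (`eligibility.csv`,
`aki_assessments.csv`, `fluid_summaries.csv`, `rai_results.csv`,
`summary_tables/`, per-predictor ROC coordinates and `results.json`); all
report numbers re-derive from those files.

The library surface mirrors the CLI:

```python
from renal_angina import ContingencyTable, odds_ratio_wald, auc_binary

t = ContingencyTable(a=30, b=8, c=6, d=22)   # RAI+ × severe AKI counts
odds_ratio_wald(t)   # OR 13.75, 95% CI (4.17, 45.33)
auc_binary(t).auc    # 0.7833
```

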