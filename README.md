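# healthineq

Income-related health-inequality analysis for basic medical-insurance
cohorts.

`healthineq` is aimed at health economists and epidemiologists studying how
a social medical-insurance scheme — one with a flat premium contribution,
out-of-pocket treatment spending, and partial reimbursement — redistributes
income among its participants and thereby moves income-related inequality
in health. It implements the full survey-microdata workflow on one-row-per-
respondent tables: ordinal self-rated health (SRH), per-capita household
income, insurance money flows, outpatient/inpatient utilization, and
standard demographic controls. A synthetic cohort generator with known
ground truth makes every step testable end to end.

## Methods at a glance

**Cardinalization.** SRH (5-point Likert) is ordinal, but concentration
indices need cardinal health. An ordered probit

&nbsp;&nbsp;&nbsp;&nbsp;H\*ᵢ = α₁·log(1 + incomeᵢ) + α₂'Xᵢ + εᵢ,&nbsp;&nbsp;ε ~ N(0, 1)

is fitted with controls X (gender, age, education years, marital status,
region); the predicted linear index Hᵢ is min–max rescaled to the unit
interval, SaHᵢ = (Hᵢ − min H)/(max H − min H).

**Concentration index (CI).** With fractional income ranks
Rᵢ = (i − 0.5)/n (ties averaged),

&nbsp;&nbsp;&nbsp;&nbsp;CI = (2/μ)·cov(SaH, R),

positive when health is concentrated among the rich. The Erreygers
corrected index for health bounded in [a, b],

&nbsp;&nbsp;&nbsp;&nbsp;EI = (1/n)·Σᵢ [4hᵢ/(b − a)]·(2Rᵢ − 1),

equals 4·μ·CI on [0, 1] health with untied ranks and serves as the
robustness companion.

**Insurance stages.** Each participant's income is tracked through four
states — initial, after the premium (contribution), after out-of-pocket
spending (treatment), after reimbursement — and the CI/EI are recomputed on
each stage's income ranking. Δ_total = CI_initial − CI_reimbursement
summarizes the scheme's net effect (negative = inequality widened).

**Relative deprivation.** RD(xᵢ) = (1/(n·μ))·Σⱼ max(xⱼ − xᵢ, 0), whose
population mean is the Gini coefficient of health; it is regressed on
income-quintile dummies as a second robustness check.

**Horizontal equity.** Utilization is indirectly standardized: a linear
model on need factors (gender, age, SRH) and non-need factors (income,
education, marital status, urban/rural, region) yields the need-expected
utilization Ŷᵢ (non-need factors at sample means), and
Y⁽ˢ⁾ᵢ = Yᵢ − Ŷᵢ + Ȳ. Per-quintile coverage ratios 100·actual/expected
below 100% flag unmet need.

## Worked example

```python
import healthineq as hq

config = hq.RunConfig(
    simulate=hq.CohortConfig(n_individuals=5_000, seed=1),
    cardinalization_mode="per_stage",
    bootstrap_B=0,
)
bundle = hq.run_pipeline(config)
print(bundle.table2_ci_stages.round(4))
```

```
              initial  contribution  treatment  reimbursement  delta_total
group
total          0.0935        0.0935     0.0383         0.0271       0.0665
low            0.0517        0.0499     0.0761         0.0363       0.0153
lower_middle   0.0188        0.0190     0.0402         0.0191      -0.0003
middle         0.0209        0.0210     0.0207         0.0098       0.0112
upper_middle   0.0256        0.0255     0.0184         0.0100       0.0156
high           0.0342        0.0340     0.0104         0.0091       0.0251
```

All stage CIs are positive: on this synthetic cohort (income-graded latent
health) health is concentrated among the rich at every insurance stage. The
treatment stage re-ranks sick, high-spending participants downward; by the
design of this generator's reimbursement (a fixed fraction of spending) the
final CI ends below the initial one, so Δ_total > 0 here. The utilization
table from the same run shows the pro-rich pattern in care:

```
                 outpatient_actual  outpatient_expected  outpatient_standardized  coverage_pct
low                          4.020                4.653                    3.746         86.39
lower_middle                 3.909                4.550                    3.738         85.92
middle                       4.354                4.428                    4.305         98.33
upper_middle                 4.609                4.281                    4.707        107.66
high                         5.003                3.983                    5.399        125.62
```

The poorest quintile uses only 86% of its need-expected outpatient care
while the richest uses 126%; the gradient survives need-standardization
(standardized means rise with income), i.e. horizontal equity fails.

The same pipeline runs from the shell:

```bash
healthineq simulate --n 5000 --seed 1 --out cohort.csv
healthineq run --input cohort.csv --mode per_stage --out report/
healthineq verify delta 0.0706 0.0291    # -> 0.0415
healthineq verify ratio 3.724 4.500      # -> 82.76
```

`healthineq verify` exposes the Δ/coverage arithmetic for checking numbers
from printed stage-CI and utilization tables.

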