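# lactocurve

Longitudinal metabolic-biomarker profiling and prognostic classification of
hyperketonemia in transition dairy cows.

Around calving, high-yielding dairy cows run a negative energy balance that
drives fat mobilisation and ketogenesis.  Elevated blood ketones
(hyperketonemia, serum β-hydroxybutyrate BHB > 0.8 mmol/L; subclinical
ketosis above 1.2 mmol/L) mark cows at risk of displaced abomasum, infection
and reduced fertility — but a single spot measurement misses a large share
of the cows that will become ketotic later in lactation.  `lactocurve`
implements, as a tested reusable pipeline, the full surveillance analysis a
herd-health study runs on weekly serum panels (BHB, non-esterified fatty
acids, total bilirubin, aspartate aminotransferase):

* **Cohort handling** — tidy cow-visit CSVs, visit-count filters, strict
  threshold case labelling with onset days, Shapiro–Wilk transform screening.
* **Longitudinal profiles** — a three-stage mixed-effects natural cubic
  spline model of the log-scale biomarker course from 27 d ante partum to
  80 d post partum.  Stage 1 fits the spline with a per-cow random
  intercept; stage 2 adds ketosis status interacted with every spline
  coefficient; stage 3 adds a per-cow random case effect.  Stages are
  compared by likelihood-ratio χ² (ML fits, so the tests on fixed effects
  are valid).
* **Onset epidemiology** — empirical CDFs of first-exceedance days,
  incidence proportions, the undetected-case fraction of any single-day
  measuring scheme, and the maximum pre-partum sampling gap that bounds a
  classification grid.
* **Interval screens** — Welch tests of case-vs-control per-cow mean log
  values on 6-day tiles of the window from 15 d ante to 62 d post partum.
* **Prognostic classifiers** — per-cow features (ante-partum median and
  maximum, value at parturition, interpolated daily values on days 1–10
  post partum, increases, parity), ROC/AUC ranking, a cost-weighted Youden
  cut-point, and a small CART learner with cost-complexity pruning as a
  multivariate cross-check.
* **Synthetic herds** — a generator with known ground truth (group-specific
  log-scale spline mean curves, per-cow random effects, log-normal noise,
  jittered calving dates) so every stage is testable without any download.

The cut-point criterion is the generalized Youden index

```
J(c) = Se(c) + r·Sp(c) − 1,    r = (1 − p)·CFP / (p·CFN),
```

with prevalence `p` and misclassification costs CFN (missed future case,
default 4) and CFP (unnecessary propylene-glycol supplementation, default
1): missing a cow that will become ketotic is weighted four times an
unnecessary treatment, which pushes the selected threshold down.

## Worked example

```python
from lactocurve import (simulate_herd, label_cows, incidence_proportion, onset_ecdf,
                        undetected_fraction, fit_stage, compare_stages,
                        extract_features, rank_classifiers, optimal_cutpoint)

sim = simulate_herd(seed=1)           # 99 cows, 14 weekly visits
table = sim.table
labels = label_cows(table, threshold=0.8)
print(f"hyperketonemia incidence: {incidence_proportion(labels):.1%}")

ecdf = onset_ecdf(table, 0.8)
print(f"cases undetected by a day-10 measurement: {undetected_fraction(ecdf, 10):.1%}")

f1 = fit_stage(table, "bhb", labels, stage=1)
f2 = fit_stage(table, "bhb", labels, stage=2)
f3 = fit_stage(table, "bhb", labels, stage=3)
lrt = compare_stages(f1, f2, f3)[2]   # stage 3 vs stage 1
print(f"BHB group effect: chi2({lrt.df}) = {lrt.chi2:.2f}, p = {lrt.p:.2e}")

features = extract_features(table, labels)
best = rank_classifiers(features, labels).iloc[0]
cut = optimal_cutpoint(features[best["feature"]],
                       features.index.map(labels.is_case), cfn=4)
print(f"best classifier: {best['feature']} (AUC = {best['auc']:.3f})")
print(f"cost-weighted Youden cut-off: {cut.cutoff:.2f} mmol/L "
      f"(Se = {cut.metrics.se:.2f}, Sp = {cut.metrics.sp:.2f})")
```

prints

```
hyperketonemia incidence: 52.5%
cases undetected by a day-10 measurement: 26.9%
BHB group effect: chi2(10) = 309.19, p = 1.77e-60
best classifier: bhb_t1_d5 (AUC = 0.944)
cost-weighted Youden cut-off: 0.51 mmol/L (Se = 1.00, Sp = 0.68)
```

About half the herd develops hyperketonemia; roughly a quarter of those
cases would be missed by measuring once on day 10.  Ketosis status changes
the whole BHB course (the stage-3-vs-stage-1 likelihood ratio), and an
early-lactation BHB measurement around 0.5 mmol/L — well below the usual
1.2 mmol/L diagnostic threshold — is the strongest single prognostic
classifier under 4:1 false-negative costing.

The same steps are available from the shell:

```sh
lactocurve simulate --seed 1 --out herd.csv --truth truth.csv
lactocurve validate herd.csv
lactocurve label herd.csv --threshold 0.8
lactocurve incidence herd.csv --out ecdf.csv
lactocurve fit-profile herd.csv --biomarker bhb --out fit.json --curves-out curves.csv
lactocurve interval-tests herd.csv --biomarker bhb --out tests.csv
lactocurve classify herd.csv --cfn 4 --out cutpoint.json
```

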