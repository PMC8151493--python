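# Methods

## Data model

The pipeline's universal input is a long-format table of cow-visits: cow id,
parity class (primiparous/multiparous), integer day relative to parturition
(negative = ante partum, 0 = calving, admissible range −60…+120), and the
serum panel BHB (mmol/L), NEFA (mmol/L), total bilirubin (µmol/L) and AST
(U/L).  All concentrations must be strictly positive so the log transform is
always defined; missing biomarker values are NaN.  Cohort construction keeps
cows with at least `min_obs = 11` visits (i.e. more than 10).  A cow is a
*case* at threshold *t* iff any of her BHB samples strictly exceeds *t*
(0.8 mmol/L for hyperketonemia, 1.2 mmol/L for subclinical ketosis); the
onset day is the sample day of the first exceedance, with no interpolation
between visits — a weekly surveillance reading.  Samples drawn after a
supplementation week carry a `post_treatment` flag and are retained by
default (they are rare; a switch drops them).

Because the case definition takes a maximum over ~14 noisy samples, a herd's
realized incidence always exceeds the fraction of cows whose *mean* curve
crosses the threshold.  Every labelling step in the package therefore works
from the observed data, exactly as a field study must.

## Transform screening

Each biomarker is screened with the Shapiro–Wilk test on the raw and the
natural-log scale; the recommendation is "log" when the log scale is closer
to normality (larger p).  The natural log is used throughout the modelling —
the base only rescales coefficients, never test statistics.  Skewed,
multiplicative-error serum chemistry makes the log scale the expected
outcome for all four markers.

## Spline basis

Biomarker courses are modelled as natural cubic splines of the day relative
to parturition: piecewise cubic, C² at the knots, linear at and beyond the
boundary knots.  The default layout places 7 interior knots at −20, −7, 0,
+7, +14, +25 and +50 d — time points where structural metabolic changes are
expected, roughly uniform over the window — with boundary knots at the fit
range endpoints −27 and +80 d.  With *m* interior knots the family has
*m* + 1 degrees of freedom excluding the intercept, so the default basis has
8 columns.  The implementation uses the truncated-power construction; any
basis spanning the same space is equivalent, and the tests compare fitted
*curves*, which are parameterization-invariant, rather than coefficients.
The unit tests verify the space against a brute-force construction that
solves the continuity and natural-tail constraints directly.

Smaller candidate bases thin the interior knots in the fixed priority order
−20, +50, +14, +25, −7, +7, keeping parturition longest; the basis size is
selected by AIC over stage-2 fits, ties toward the smaller basis.

## Three-stage mixed-effects model

For one biomarker, with `A(t) = [1, B(t)]` the intercept-augmented spline
row and `case_i` the cow's ketosis status:

* **stage 1**: `log y_ij = A(t_ij)·β + b0_i + ε_ij` — spline only, per-cow
  random intercept `b0_i ~ N(0, τ0²)`, residual `ε ~ N(0, σ²)`;
* **stage 2**: adds `case_i · A(t_ij)·δ` — ketosis as a fixed effect on the
  intercept and every spline coefficient;
* **stage 3**: adds `g_i · case_i` with `g_i ~ N(0, τg²)` — a scalar per-cow
  random case shift.

The stage-3 random term is deliberately a *scalar* shift: a full unstructured
random interaction with all 8 spline coefficients is unidentifiable at herd
scale (hundreds of cows, 14 visits), and the scalar shift preserves the
strict nesting the stage comparison requires.  Repeated measures within a
cow are correlated only through the random effects; no serial correlation
structure is added.

All stages are fitted by maximum likelihood (not REML) so likelihood-ratio
tests on fixed effects are valid.  The marginal covariance of a cow's
responses is compound symmetric, `V_i = σ² I + (τ0² + case_i τg²) J`, which
gives the likelihood in closed form via Sherman–Morrison.  Numerically:

* fixed effects and σ² are profiled out; the remaining one or two variance
  *ratios* are optimized on the log scale (non-negativity by
  parameterization), with `log λ ∈ [−14, 8]`;
* the GLS step whitens each cow's block with the analytic square root of
  `W_i = I − c_i J` and solves a plain least-squares problem, so the design's
  condition number is not squared — this is what makes the noise-free limit
  (exact interpolation, recovery of the generating coefficients to 1e−6)
  work at cubic column scales;
* stage 3 optimizes two ratios by Nelder–Mead from a fixed grid of four
  starts, keeping the best (deterministic given the data);
* a residual variance collapsing below 1e−12 (the exact-interpolation limit)
  is reported with a warning, not fatal; the no-random-effect boundary λ = 0
  is allowed to win.

Parameter counts: stage 1 has 9 fixed + 2 variance parameters, stage 2
18 + 2, stage 3 18 + 3.  Stage comparisons report χ² = 2Δloglik with df from
parameter-count differences.  The stage-3-vs-2 comparison tests a variance
component on the boundary of its space; the naive χ²₁ reference used here
(as in standard mixed-model ANOVA tables) is anti-conservative for it.
Fits are cross-checked in the test suite against statsmodels' `MixedLM`
(column-standardized design, Powell optimizer), which agrees in
log-likelihood to ~1e−10; statsmodels is never used as the implementation.

## Interval tests

The window [−15, 62] d is tiled into thirteen 6-day half-open intervals.
Within an interval each cow's log values are averaged first — one value per
cow, so multiple visits cannot pseudo-replicate — and groups are compared
with a Welch two-sample t-test.  Two single-day tests at parturition (t0)
and day 10 (t1) use nearest-neighbour linear interpolation per cow.
P-values are reported uncorrected (a descriptive screen); Benjamini–Hochberg
adjustment is optional.  A literal one-sample variant (case means against
the control mean as a fixed constant) sits behind a flag; it ignores
control-group sampling error and is anti-conservative, so the Welch form is
primary.

## Incidence statistics

The onset ECDF is over eventual cases only: `F(d)` = fraction of cases with
onset ≤ d, so `1 − F(d)` is the share of future cases a single measurement
on day *d* misses.  Incidence = cases / cows tested.  The maximum over cows
of the span from last ante-partum sample to calving (day 0 itself is not
ante partum) bounds from below the grid a classification scheme can use
while guaranteeing every cow one pre-partum measurement; under weekly
sampling with jittered calvings this is typically ~7–14 d.

## Prognostic classifiers

Per cow and biomarker, on the natural concentration scale (the classifier
stage is never log-transformed): ante-partum median (baseline) and maximum,
value at parturition (t0), interpolated values on days 1–10 post partum,
the increases baseline→day 10 and parturition→day 10, and the parity class.
A cow missing the flanking observations for an interpolation has that
feature missing, never zero or extrapolated.  The increases are taken at
day 10 because that is the headline single-measurement day of the t1 grid.
Parity enters as one binary column; parity-stratified copies of every
feature were considered and rejected because a stratified copy is undefined
for whole-cohort ROC ranking (missing on the complementary stratum), while
the CART learner already combines parity with all other features.

ROC curves use the rule *score ≥ threshold ⇒ positive* (higher biomarker =
sicker); tied scores collapse to one threshold so the trapezoidal AUC equals
the Mann–Whitney estimator with half credit for ties (verified to 1e−12
against pair enumeration).  The cut-point maximizes the generalized Youden
index `J(c) = Se + r·Sp − 1` with `r = (1−p)·CFP/(p·CFN)`; CFN = 4, CFP = 1,
and `p` defaults to sample prevalence.  Candidates are the midpoints between
adjacent distinct scores plus one point below and above all scores; ties
break toward the lower cutoff, favouring sensitivity, consistent with
CFN > CFP.  Confusion-metric intervals are Clopper–Pearson 95%.

One caveat is mirrored deliberately: the day-10 BHB feature can contain the
very sample that labels a cow hyperketonemic (onset on or before day 10).
`strict_prognostic_labels` restricts cases to onsets strictly after the
feature day for a genuinely prognostic evaluation; the default matches the
surveillance design, leakage included.

The CART learner is greedy binary splitting by Gini impurity.  `min_node =
10` is the minimum rows a node must have for a split to be *attempted*
(rpart's `minsplit` semantics; leaves may be smaller).  Cost-complexity
pruning builds the weakest-link subtree sequence; 5-fold cross-validation
over the geometric-mean penalty grid picks the simplest tree within one
standard error of the minimum CV error.  Fold assignment is the only use of
the seed, so fits are reproducible.  The root split is verified against
exhaustive (feature, threshold) enumeration and against scikit-learn's tree
on the same data.

## Synthetic herd generator

The generator draws the study conditions directly: 99 cows, 14 weekly
visits starting 14 d before the *expected* calving, actual calving jittered
by a rounded N(0, 3²) days so visit days relative to parturition vary
across cows; 52% of cows are assigned the hyperketonemic-type mean curve;
26% are primiparous.  On the log scale, cow *i*'s biomarker at day *t* is

```
log y = A(t)·β_group(i) + b0_i + g_i·1[case]·A(t)·δ + ε
```

with `b0 ~ N(0, σ_int²)`, `g ~ N(0, σ_case²)` modulating how strongly a case
cow expresses the case-minus-control difference curve `δ`, and `ε ~ N(0,
σ_resid²)`.  Values are exported exponentiated, hence strictly positive.
Defaults: σ_int = 0.20, σ_case = 0.15, σ_resid = 0.20 — log-scale spreads of
the size seen in peripartal serum metabolites.  Mean curves are specified as
spline coefficients solved exactly from nine anchor values per group; the
default anchors encode the qualitative peripartal shapes (BHB: parturition
peak and a second case-group peak near day 30, case curve elevated through
day 80; NEFA: single parturition peak declining; bilirubin and AST:
parturition peak).  The BHB anchor levels and noise SDs were fixed together,
once, so that the realized max-over-visits label incidence lands near one
half (hyperketonemia) and one fifth (subclinical ketosis) — the label is a
running maximum, so curve levels alone do not determine incidence.

What the generator does *not* emulate: treatment effects (the
post-treatment flag is assigned at random to case-cow post-partum visits,
default probability 0.026, with no effect on values), parity-specific
curves, within-day variation, informative dropout (dropout is optional and
completely at random), and cross-biomarker correlation within cow (random
effects are drawn independently per biomarker).  Passing tests therefore
demonstrate correctness of the estimators under the assumed data-generating
process, not robustness to these real-data features.

## Test design and problem sizes

Oracle tests pin every numerical claim to an independent computation:
brute-force pair counting for AUC, exhaustive threshold search for the
cut-point, direct multivariate-normal density for the mixed-model
likelihood, constraint-solving for the spline space, exhaustive Gini
enumeration for tree splits, and hand-computed Welch statistics.  Simulation
checks use 20 replicates of 200-cow herds for parameter recovery (fitted
log-curves compared on a 5-day grid with a Bonferroni-sized 3-SE band for
the 10 correlated grid comparisons; the two variance components at 2 MC-SE),
200 replicates of 80-cow herds for null calibration of the stage-2-vs-1
likelihood-ratio p-values (Kolmogorov–Smirnov against U(0,1)), and 20
replicates at a +0.5 log-unit group offset for power.  These sizes give
Monte-Carlo standard errors a few times smaller than the effects being
checked while keeping the default suite around half a minute.

## Known limitations

* The stage-3 random case effect is a scalar shift; cow-specific *shape*
  deviations of the case profile are only captured through the generator's
  `g_i` modulation, which the fitted model absorbs into the shift and the
  residual.
* Boundary-respecting p-values for variance-component tests (mixture χ²)
  are not implemented; the naive reference is anti-conservative.
* The basis-size selector compares AIC across fits with different knot
  sets but a common day window; it does not search knot positions.
* Onset days are visit days, so incidence timing is right-censored at the
  weekly grid; no interval-censored survival machinery is provided.
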