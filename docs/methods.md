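# Methods

## The composition and its geometry

The analysis unit is one participant-day summarised as hours of physical
activity (PA, any intensity while awake), sedentary behaviour (SB, awake at
or below the MET threshold) and sleep (overnight sleep plus naps). The
three parts are strictly positive and closed to 24 h. All inference happens
in isometric log-ratio (ilr) coordinates: `z = V' ln(x)` with `V` a 3x2
orthonormal zero-column-sum contrast. The default basis is the pivot basis
in part order (pa, sb, sleep); any other valid basis is an orthogonal
rotation/reflection of it in coordinate space, and every reported quantity
(means, adjusted means, changes, interaction p-values, confidence regions)
is basis-invariant — asserted in the test suite across random bases at
1e-9/1e-10 tolerances. Closure sets the last part by subtraction, so stored
compositions sum to 24.0 bit-exactly.

Zeros are never imputed anywhere in the package. A person-day with a zero
part cannot be log-ratio transformed and is excluded before analysis, with
a per-wave tally by reason in the fixed order sleep -> PA -> SB (a day with
several zero parts counts once, under the first). This mirrors the
exclusion-based handling of zero-part respondents in the survey analyses
this pipeline supports; multiplicative replacement is deliberately out of
scope.

## Diary classification

Diaries carry 144 ten-minute slots. An activity map resolves each slot's
code to PA/SB/sleep: a direct lookup first, then ordered MET rules (glob
code pattern, optional occupation/location qualifier, MET value) for work-
and travel-related codes — sedentary at or below `met_threshold` (default
1.5 MET, the conventional boundary), active above. Sleep is only ever
assigned directly. The shipped map is a compact documented default, not the
authentic published lookup; real analyses supply their own table in the
same YAML format. Aggregation is pure counting: `hours = slots/6`, sleep by
subtraction so the day closes at 24.0 exactly. In strict mode an unmapped
code is an error naming the code; lenient mode falls back to a configured
category with a warning.

## Weights

Each person-day carries a supplied survey population weight (the sampling
design itself is consumed, never re-derived). Because diary days are not
uniform over the week, a per-(wave, day-of-week) factor
`(W_total/7)/W_day` rescales the weighted mass so each day of week carries
exactly 1/7 of its wave's total; factors are computed within wave because
the waves are modelled separately, and the stage is mass-preserving and
skippable for pre-aggregated inputs without day-of-week labels. Weights are
then treated as frequency/precision weights throughout: WLS point
estimates, weight-normalised residual scatter, observation-count degrees of
freedom. See Limitations for what this convention does to test calibration
under heavy random weights.

## Regression, adjusted means, margins

Per wave, both ilr coordinates are regressed on all eight categorical
covariates (main effects only, treatment coding, shared design matrix —
equivalently a multivariate WLS). Adjusted ("least-squares") means for a
category are margin predictions with the other factors averaged over their
levels. Two conventions are implemented:

* `margins="observed"` (default): other factors at their weighted observed
  level shares — equivalently proportional margins. This is the default
  because it is demonstrably the convention behind the published tables
  this pipeline emulates: the share-weighted category average of the
  printed adjusted means is constant across all eight variables (spread
  ~0.001 ilr units), which is the algebraic signature of proportional
  margins in a main-effects model; under equal margins that spread would be
  two orders of magnitude larger.
* `margins="equal"`: the classical textbook LS mean, available everywhere
  the observed convention is.

Margins are back-transformed by inverse ilr and closed to 24 h. Between-
wave changes are `(part_2015 − part_2009) x 60` min/day; for any scope the
three changes sum to zero exactly before rounding. Reported precision
follows the field convention: compositions to 0.01 h, changes to 0.01
min/day.

The covariate x wave interaction is tested by comparing pooled two-wave
multivariate fits with and without the interaction columns: hypothesis and
error SSCP matrices from weighted residuals, Pillai's trace (Wilks' lambda
optional) with the standard F approximation, error df = n − rank. On
unweighted data this reproduces a MANOVA term test to machine precision
(cross-checked against statsmodels in the suite).

## Bootstrap

Percentile bootstrap throughout: person-days resampled with replacement,
stratified by wave, with the *entire* pipeline — day-of-week factors,
fits, margins, back-transforms, differences — re-run inside each replicate;
2.5/97.5 percentiles over B replicates (reference analyses use B = 1000).
Replicates where estimation fails (e.g. a category empty in the resample)
are dropped with a tally; more than 10% dropped aborts. Percentile rather
than BCa because the estimands are smooth near-normal functionals at survey
sample sizes; the coverage simulation is the arbiter: over 500 simulated
surveys (n = 2000, B = 200) the 95% CI covered the true mean composition
part-wise in 94.6–95.2% of runs.

Confidence regions for compositional means on the ternary diagram are
normal-approximation ellipses fitted to replicate means in ilr space
(chi-square radius, >= 100 boundary points), back-transformed and mapped to
barycentric coordinates with vertex order PA-SB-sleep; a convex hull over
the replicate cloud is available as a nonparametric alternative.
Zero-variance replicate sets yield a degenerate point region with a logged
notice.

## Synthetic generator and calibration

The generator draws covariates categorically with wave-specific
prevalences, then `z ~ Normal(mu(design), Sigma)` and `x = ilr^{-1}(z)`
closed to 24 h — the logistic-normal family, chosen because it is the model
under which the regression is exactly correctly specified, making recovery
tests sharp. Weights are log-normal (sigma = 0.5, independent of
everything), diary days are sampled from a non-uniform week, day type is
derived from the sampled day, and a configured number of zero-part days per
wave is planted (one part overwritten with zero, the rest re-closed) with
exact bookkeeping.

`GeneratorConfig.thai_like()` calibrates defaults to a published two-wave
national study's margins — a resemblance, not a replication:

* category prevalences from the printed per-category counts;
* per-category ilr effects as differences of the printed adjusted means
  within each variable and wave;
* wave intercepts chosen so the *population* mean composition equals the
  printed whole-sample means (9.50/5.30/9.20 h and 8.60/5.96/9.44 h);
  printed adjusted means are then reproduced up to a small wave-level
  constant (~0.03 ilr units — the real-data gap between weighted
  whole-sample means and unweighted-margin predictions), which cancels to
  ~0.003 in every reported contrast;
* residual covariance scaled so the marginal total variance (sum of the
  upper-triangle variation-matrix entries; `D x trace` of the clr
  covariance) matches the reported 1.85 after subtracting the
  between-covariate ilr variance implied by the effects;
* zero-part planting rates matching the published exclusion counts at the
  authentic sample sizes (367/69/28 and 184/80/22).

Covariates are drawn independently of each other; real sociodemographics
are correlated (age with employment, region with area), activity sequencing
within the day is arbitrary, and weights are independent of covariates.
Passing tests therefore demonstrate correctness of the estimators under the
assumed sampling model, not robustness to real-data structure.

Diary expansion apportions `hours x 6` to integer slot counts by largest
remainder (deterministic, exact 144). Integer counts constrained to sum to
144 cannot in general land within half a slot of every part simultaneously
(about a quarter of continuous compositions admit no such assignment), so
the guaranteed round-trip accuracy of expand -> classify -> aggregate is
one slot (1/6 h) per part; largest remainder is min-max optimal under the
sum constraint.

## Numerical and design choices

* Total variance is reported as the sum of the unique (upper-triangle)
  variation-matrix entries, matching the headline convention it emulates;
  the textbook `sum/(2D)` normalisation is exposed alongside as
  `total_variance_normalised`.
* Weighted variance uses normalised frequency weights with no small-sample
  correction.
* Rank deficiency is detected via the QR diagonal of the weighted design
  and reported with the aliased column names.
* Determinism: every stochastic step takes a seed or Generator;
  fixed seed + fixed input gives byte-identical CLI outputs.
* Exit codes: 0 success, 2 validation/configuration error, 3 estimation
  error.
* Problem sizes used by the shipped verification runs were chosen to give
  tight Monte-Carlo error at desk scale: parameter recovery at
  n = 20 000/wave, type-I calibration over 1000 replicates of n = 400/wave,
  coverage over 500 surveys of n = 2000 with B = 200, and the acceptance
  script at the authentic n (66 652 + 69 922).

## Limitations

* Frequency-weight inference: with heavy random sampling weights the
  model-based MANOVA-type tests are anticonservative by roughly
  `E[w^2]/E[w]^2` (no linearised survey variance estimation — explicitly
  out of scope). The type-I calibration band (3.5–6.5% at alpha = 0.05)
  holds in the equal-weight regime; weighted analyses should lean on the
  bootstrap CIs, which resample the weights correctly.
* The exclusion-based zero handling presumes zero-part days are recording
  artefacts, not structural zeros.
* Three-part compositions only are guaranteed (the code partially
  generalises, tests target D = 3); no alr/clr regression variants.
* Single-day diaries, primary activities only; proxy-respondent logic and
  secondary activities are out of scope.
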