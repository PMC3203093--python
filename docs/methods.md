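# Methods

## The screening statistic

A scale is q numeric items at known 1-based positions t₁ < … < t_q
within a longer questionnaire. After restricting to complete cases on
the scale (each scale keeps its own N), the pipeline is:

1. **Two-subset clustering.** Respondents are partitioned by exact
   k-medoids (PAM: BUILD then SWAP until no swap lowers the total
   within-cluster distance to medoids), k = 2, Euclidean distance on
   the raw responses of the scale's own items. No standardisation is
   applied: in the motivating instruments all items share one response
   scale. All tie-breaks go to the lowest row index, so the partition
   is deterministic. A subsampling (CLARA-style) mode is unnecessary at
   hundreds of respondents; exact PAM is the reference behaviour.
2. **Per-item variance decomposition.** For each item, the one-way
   random-intercept model y_gi = μ + u_g + e_gi is fitted with the two
   clusters as the grouping factor, giving ICC_t =
   σ²_b,t / (σ²_b,t + σ²_w,t) ∈ [0, 1].
3. **Slope.** Unweighted OLS of ICC_t on t over the converged items
   (≥ 3 required). The slope — the awareness measure — has units of
   ICC per questionnaire position; multiplied by the declared
   questionnaire length it gives the total ICC change, the scale on
   which effect sizes are easiest to judge.

The position regressor is the *full-questionnaire* position, not the
within-scale rank, so scales whose items cluster early or late are
treated correctly and the total-change rescaling is coherent.

## Variance-component estimators

Two estimators are shipped because a random effect with only two
levels sits at the edge of mixed-model practice:

* `reml` (default). The one-way model admits a profiled REML criterion
  in the single ratio λ = σ²_b/σ²_w (group sizes n_g, group means m_g,
  pooled within sum of squares SSW, weights w_g = n_g/(1+λn_g)):
  σ̂²_w(λ) = (SSW + Q(λ))/(N−1) with Q the weighted between-group sum
  of squares, and the criterion
  (N−1)·log σ̂²_w + Σ_g log(1+λn_g) + log Σ_g w_g
  is minimised over λ ≥ 0 by a coarse log-grid bracket, 20
  golden-section steps and one parabolic vertex polish (step 1e-4 in
  log λ — large enough that the vertex fit is not dominated by
  floating-point round-off, small enough to stay in the locally
  quadratic regime). The λ = 0 boundary is checked explicitly. This
  is orders of magnitude faster than a generic mixed-model fitter,
  which matters because the bootstrap re-fits every item thousands of
  times; the test suite cross-checks it against statsmodels MixedLM.
* `anova`. Method of moments from the one-way ANOVA table with the
  unbalanced-design correction n₀ = (N − Σn_g²/N)/(G−1), between
  component truncated at 0. For balanced groups with an interior
  estimate the two coincide (exercised to 1e-6 relative in tests).

Degenerate cases: a constant item column (zero total variance) or a
non-finite fit marks the item *non-converged*; it is logged and
excluded from the regression, never dropped silently. Zero
within-group variance with distinct group means yields ICC = 1 via the
moment decomposition. Negative between-variance estimates are
truncated to 0 rather than allowed as negative ICCs.

## Bootstrap and significance

The resampling unit is the respondent (whole row); each of the B
replicates re-runs clustering, ICC estimation and the regression.
Replicates where the pipeline degenerates are dropped and counted
(retrying would bias towards clusterable resamples); a failure rate
above 10% flags the result unreliable. The 95% interval is BCa: bias
correction z₀ = Φ⁻¹(#{θ* < θ̂}/B) (clamped to ±Φ⁻¹(1−1/B) when all
replicates fall on one side), acceleration from the jackknife skewness
of leave-one-subject-out estimates, endpoints read from the empirical
replicate distribution by order statistics with linear interpolation —
all conventions fixed so results are bit-reproducible given the seed.
The slope is called significant when zero is outside the interval.

**Known limitation — the BCa rule is anti-conservative here.** The
pipeline statistic is non-smooth: duplicating subjects in a resample
perturbs the adaptive PAM partition, so the bootstrap distribution is
not centred on the original-data estimate and z₀ is large and
dataset-specific even under the null. Measured at desk scale (a = b,
n = 300, q = 4, B = 500) the nominal-5% rule excludes zero in ~10–14%
of experiments, and the inflation persists at n = 600 and q = 13. The
interval *width* is right (bootstrap SD matches the true sampling SD
within a few percent) and the plain percentile interval is, if
anything, conservative; the distortion is specifically the doubled
bias-correction shift. `scripts/acceptance.py` recomputes this null
exclusion rate. Practically: treat the significance flag as a screen,
not a calibrated test.

## The simulator

`simulate_dataset` draws y_it = (f_i + e_it)/√(1+σ_t²) with a single
latent factor f_i ~ N(0,1) per respondent and independent item errors
e_it ~ N(0,σ_t²), σ_t linear from a at the first scale position to b at
the last. The division standardises every item to exactly unit
population variance, so reliability 1/(1+σ_t²) is the only thing that
drifts; inter-item covariance is analytically
1/√((1+σ_s²)(1+σ_t²)), which the tests verify empirically at n = 10⁵.
Scale items are spread evenly over the questionnaire:
t_j = round(1 + (j−1)(T−1)/(q−1)) over T total positions, collisions
bumped to the next free slot.

Scenario defaults are the reference study design: n = 600 respondents,
T = 50 positions, q ∈ {13, 4}; error profiles (a, b) = (0.5, 2.0)
rising, (1.0, 1.0) constant, (2.0, 0.5) falling — symmetric σ ranges
about 1 that make the drift clearly visible at a few hundred
replicates. Replicate counts in the shipped tests and the acceptance
script are 300–500 per condition, at which the Monte-Carlo standard
error of a mean slope is ≈ 1e-4 — an order of magnitude below the
effects of interest. Under these conditions the mean awareness measure
is ≈ 0 at a = b, ≈ −0.008 per position at (0.5, 2.0) with q = 13 and
mirrored for (2.0, 0.5).

**Scale-length effect.** Fewer items over the same span give a *more
variable* slope (SD roughly 1.5–2× larger for q = 4 than q = 13) but a
*smaller* mean displacement (≈ −0.0054 vs ≈ −0.0082 at (0.5, 2.0)).
The mechanism: with small q each respondent's own item noise carries
more weight in their cluster assignment, which inflates the ICC of
noisy (late) items and flattens the fitted slope. This was confirmed
independently with an R implementation of the same pipeline
(cluster::clara + nlme::lme), which reproduces both means within
Monte-Carlo error, so it is a property of the procedure, not of this
implementation.

## The ordinal fixture generator

`make_fixture` emulates a long coping-style instrument: each scale is
simulated continuously from its own latent factor (with its own a, b
profile over the scale's positions) and discretized at the per-item
empirical quartiles into 0–3 categories; items belonging to no scale
are independent uniform filler. Quartile cuts keep categories balanced
and preserve the null (a = b fixtures show mean slope ≈ 0 across
seeds). What the fixture does *not* emulate: item difficulty or
discrimination differences, ordinal floor/ceiling asymmetry,
respondent-specific satisficing styles, missingness mechanisms, or
correlation between different scales' factors. Tests passing on these
fixtures therefore show the pipeline's mechanics are right under the
stated generative model, not that real instruments satisfy that model.

## Design choices where the design was open

* **Clustering variables**: the scale's own q items only (each scale
  keeps its own complete-case population). This is config-visible, not
  silently changed.
* **Minimum q = 3**: a two-point regression is an exact fit and
  carries no screening information.
* **Complete-case per scale**, no imputation; scoring and total-score
  computation are out of scope.
* **Unweighted OLS** for the slope: per-item ICC precision is not
  propagated; uncertainty is handled wholesale by the bootstrap.
* **Bootstrap inside scenarios**: not run — the scenario study
  characterises the slope distribution itself; interval behaviour is
  measured in dedicated coverage experiments.
* **Estimator default REML** with the moment estimator as fallback and
  oracle; ML-vs-REML and truncation conventions are declared rather
  than inherited from a black-box fitter, so the "regression on the
  remaining items" rule for non-converged fits is deterministic and
  testable.
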