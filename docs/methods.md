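# Methods notes

This note documents the models, conventions and numerical choices behind
`boardmap`, and what its synthetic-data studies do and do not demonstrate.

## Coordinates and grid geometry

All analysis happens in Bookstein two-point shape coordinates. The transform is
the complex-plane map `w = (z − a) / (b − a)` with the bottom-left corner `a`
and bottom-right corner `b` of the board as landmarks, which sends them to
(0, 0) and (1, 0) exactly. It is a pure similarity (translation + rotation +
uniform scale, no reflection), so relative configuration is untouched; x is
the medio-lateral axis and y the proximodistal axis of the board as held.

The nominal grid geometry is internally inconsistent by 1 mm: 3.3 cm between
marks *and* between the outer marks and the edge implies 7 × 3.3 = 23.1 cm on
a 23 cm board. `build_grid` places the marks centered with equal outer margins
(3.25 cm for the default geometry) and accepts a nominal-footprint mismatch of
up to 2% of the board side; anything larger is a geometry error. With the
default board the columns sit at x = 0.1413, 0.2848, …, 0.8587 Bookstein
units, with a constant gap of 3.3/23 ≈ 0.1435.

## Procrustes superimposition

`procrustes_align` solves the least-squares similarity superimposition of one
labelled configuration onto another: center both, take the SVD of the
cross-covariance `A = Xc' Yc`, rotation `R = U V'`, scale
`s = trace(Σ)/‖Xc‖²`. When reflections are disallowed and `det(R) < 0`, the
smaller singular value's sign is flipped (`R = U diag(1, −1) V'`,
`s = (σ₁ − σ₂)/‖Xc‖²`); a non-positive effective trace (possible only in that
branch) pins the scale at 0. The reported distance is the RMS of homologous
point-pair distances after alignment, in target units — deliberately *not* the
sum-of-squares-normalized dissimilarity some libraries return, because the
variable errors are reported in the same Bookstein units and the two scales
should be comparable.

Reflection is **allowed by default**. Whether the original analysis permitted
it is not determinable from the verbal description ("translates, scales, and
rotates"); the full-similarity fit is what the common MATLAB implementation
computes, and the flag `allow_reflection` records the ambiguity. For data that
localize above chance the choice is immaterial; it matters only for
pathological maps (e.g. an axis inverted), which the reflection fit rescues.

The Monte-Carlo null uses a second, independent derivation of the same
quantity: for 2×2 cross-covariances the effective trace has the closed form
`(σ₁ ± σ₂)² = ‖A‖²_F ± 2·det A`, which avoids a per-simulation SVD and makes
10⁶ simulations cheap. The SVD path, the closed-form path, and a brute-force
grid search over rotation angle (with the closed-form optimal non-negative
scale per angle — no SVD anywhere) are cross-checked against each other in the
test suite to 10⁻³ and typically agree to machine precision.

## The chance model

"Random data" is modeled as clicks uniform over the board square, independent
of the stimulus, averaged per location with the experiment's repetition count
(8, or 4 per posture), then scored exactly like real maps. The repetition
count is a parameter, so the alternative reading (one random point per
location, `reps = 1`) can be run as well. The group null resamples cohort
means with replacement; at 10⁶ source values, with- versus without-replacement
is numerically indistinguishable and with-replacement is standard.

Empirical p-values use the strict inequality (proportion of null values
*smaller than* the observed distance); ties count against significance. Chance
distances for the default geometry concentrate around 0.34 Bookstein units
(1st percentile ≈ 0.32): a structureless map shrinks to near the grid centroid
under the optimal scale, leaving a residual of about the grid's own RMS
radius.

Simulation sizes: the library default for `simulate_null_single` is the
study-scale 10⁶. The validation studies and pipeline default use 10⁴–2×10⁵
simulations, sizes chosen so the whole suite and the acceptance script run in
minutes while leaving Monte-Carlo error far below every tolerance used (the
1st-percentile threshold, for example, is stable to ~10⁻³ across these sizes).

## Statistics

* Slopes are trial-level OLS per participant and axis. Whether the original
  regressions were trial-level or on per-location means is not stated; both
  are provided (`on_location_means=True`), and for balanced noise they
  estimate the same quantity — the trial-level fit is the default because it
  uses all data.
* Variable error is the per-location sample SD (n−1) per axis, averaged
  unweighted over the 36 locations, giving one value per participant and axis
  before the paired comparison.
* All t and r tests are two-tailed; no multiplicity correction is applied.
  Effect sizes: Cohen's d = mean/SD for one-sample tests, dz = mean
  difference / SD of differences for paired tests.
* Boundary clicks (exactly on the board edge) are kept; "outside" is strict.
* Degenerate group statistics (zero-variance differences, constant slopes
  across a cohort) are reported as structured errors in the group report
  rather than raised, so a pathological cohort still yields a report.

## The synthetic participant model

A non-lapse response is

```
percept = center + (slope_x, slope_y) ∘ (actual − center) + N(0, diag(σx², σy²))
click   = clip(percept, 0, 1)        # the participant clicks on the board picture
```

with probability `lapse_rate` replaced by a uniform draw over the extended
region [−0.1, 1.1]² (width configurable), so some lapses land outside the
board and are caught by the exclusion step while others are silent.

Design choices worth flagging:

* **Clipping.** With the study-scale parameters (medio-lateral slope 0.84,
  noise SD 0.121) an unbounded Gaussian would put ~5% of edge-column clicks
  outside the board — an order of magnitude more than the observed
  outside-board rates (~0.2–0.4%) — and the resulting censoring would bias
  recovered medio-lateral slopes by about −0.03. Clipping the percept to the
  response square keeps ordinary responses on-board, makes lapses the only
  source of exclusions (so the exclusion rate ≈ lapse rate × outside-area
  fraction of the lapse region), and leaves slope recovery essentially
  unbiased (residual bias ≈ −0.01, from the clipped tail at edge columns).
* **Heterogeneity.** Per-participant slopes are drawn from untruncated
  Normals at the printed means and SDs (0.840 ± 0.213 medio-lateral,
  0.428 ± 0.229 proximodistal). Truncating to [0, 1] would clip ~23% of the
  medio-lateral distribution and shift its mean by ~−0.06, making recovery
  of the stated mean impossible; overshoot (slope > 1) is in any case
  meaningful. A consequence of the Gaussian tail: roughly 2×10⁻⁴ of
  synthetic participants draw both slopes near zero and are genuinely
  chance-level, so "every participant in every cohort beats the null's 1st
  percentile" holds for most but not all seeds at 200 cohorts × 20
  participants. Noise SDs and lapse rate are constant across participants
  (no between-participant spread for them is available).
* **Not modeled.** The between-axis correlation of slopes across participants
  (observed ≈ 0.77), heavier-than-Gaussian response-noise tails, constant
  error (spatial bias fields), sequential/block effects, and any biomechanics
  of the tap. Passing recovery tests therefore show that the *analysis chain*
  is unbiased and calibrated for this response family — not that real data
  follow it.
* Blocks are single randomized sweeps of the 36 locations; the two-posture
  design orders sweeps ABBA. (The physical experiment grouped two sweeps per
  block; block structure is ignored by the analysis, so only the sweep-level
  randomization matters here.)
* The per-location sample SD at 8 repetitions estimates `c4(8)·σ ≈ 0.965·σ`,
  the well-known small-sample bias of the Gaussian SD. Recovery tests of the
  noise parameters therefore compare the c4-corrected estimate to the
  generating σ; the variable-error *comparison between axes* is unaffected,
  since both axes carry the same factor.

## Validation studies

`boardmap.validation` packages the simulation experiments used by the test
suite and `scripts/acceptance.py`:

* `svd_bruteforce_max_discrepancy` — alignment oracle agreement on random
  configurations.
* `procrustes_p_calibration` — 2000 uniform responders, run through the trial
  generator, exclusion and map construction, scored against a 10⁴-simulation
  null: p-values are checked for Uniform(0, 1) by a KS test.
* `slope_type1_rate` — 2000 chance-level cohorts of 20; the group slope
  t-test should reject at the nominal 5%. Slopes here use the closed-form OLS
  estimator, cross-checked against the per-participant regression path.
* `recovery_study` — 200 cohorts at the study-scale generating parameters;
  reports mean recovered slopes (generating values recovered within 0.02),
  recovered variable errors, anisotropy-detection rates (at these parameters,
  essentially 100%: the per-participant variable-error difference has an
  effective dz ≈ 2), and the fraction of cohorts in which every participant
  beats the null's 1st percentile.

Determinism: every random draw descends from an explicit seed via
`numpy.random.SeedSequence` spawning; identical configurations produce
byte-identical trial CSVs, null caches and JSON reports.

## Known limitations

* The converter contract for externally recorded data expects the documented
  CSV schema; no parser for any particular lab's raw format is included.
* The pipeline analyzes each posture condition independently, mirroring the
  original two-stage approach; no mixed-effects or Bayesian alternatives.
* General Procrustes analysis of more than two configurations and deformation
  visualizations are out of scope.
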