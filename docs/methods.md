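# Methods

## The photothermal index

The package's driving variable is TEP, the accumulated product of a
trapezoidal thermal-response function and PAR.  The trapezoid
(`relative_thermal_effectiveness`) is continuous, piecewise linear, equals 1
exactly on the optimum plateau `[t_ob, t_ou]`, and is clamped to zero below
the lower and above the upper critical temperature.  The upper branch is
implemented as "0 for T > T_m": a trapezoid is the only reading that keeps
the function single-valued and continuous.  The default cardinals
(15, 22, 28, 35 °C) are the ripening-period values for greenhouse tomato;
they are validated to be strictly increasing at construction.

Units: the hourly step multiplies an RTE fraction by a PAR *flux* in W·m⁻²
and by 3600×10⁻⁶, which is exactly the W·m⁻² → MJ·m⁻²·h⁻¹ conversion, so
the engine ingests PAR as W·m⁻².  Sensors reporting photon flux are
converted with the standard quantum ratio 1 W·m⁻² ≈ 4.57 μmol·m⁻²·s⁻¹
(configurable in `par_umol_to_w`).

Aggregation choices: sub-hourly records are averaged to hourly means before
the trapezoid is applied (RTE is defined on hourly mean temperature, and
averaging temperature before the nonlinearity is not the same as averaging
RTE).  Day boundaries are the local calendar dates of the timestamps; no
time-zone arithmetic is attempted.  Missing hours contribute zero and are
logged with a gap count; `strict=True` rejects series with more than 5 %
missing hours.  Accumulation starts from zero at a caller-supplied
`origin_date`, exposed as an explicit parameter because the biological
origin (anthesis, fruit set, planting) is a study-design choice the data
cannot decide.

## Response models

Three fixed forms are fitted: logarithmic (`y = a ln X + b`) for soluble
sugar and the sugar–acid ratio, linear for organic acid, logistic
(`y = K/(1+e^{−r(X−X₀)})`) for the comprehensive score.  The log and linear
forms are solved by ordinary least squares on the (transformed) regressor —
no iteration, exactly reproducible; the test suite cross-checks them
against a closed-form normal-equations oracle at 1e-8.

The logistic is fitted by Levenberg–Marquardt nonlinear least squares with
the deterministic initialization `K₀ = 1.05·max(y)`, `r₀ = 4/range(x)`,
`X₀₀ = median(x)` (the `4/range` rule puts the initial slope at roughly one
logistic transition across the observed range).  On non-convergence, up to
20 multiplicative jittered restarts (uniform on [0.5, 1.5], seeded by
`random_state`) are attempted before a `FittingError` is raised with
diagnostics.  The exponent is clipped at ±500 to avoid overflow during line
searches.

Validation statistics: `R² = 1 − SS_res/SS_tot` about the observed mean
(the conventional definition; no formula ambiguity arises for the
closed-form fits) and RMSE with denominator `n` — the population form used
for crop-model validation, not the `n−p` estimator variant.  Resubstitution
(fit and evaluate on the same 21 calibration means) is the validation
protocol: the calibration data are stage means, replicate-level values are
not published, and resubstitution on the means reproduces the published
SSC, SSC/OAC and comprehensive RMSE values.

Units inside fits: SSC and OAC are fitted in g/100 g.  Parameter-value
assertions are made only for the sugar–acid ratio (dimensionless, and its
published parameters are consistent with the data); SSC and OAC fits are
validated through scale-invariant R²/RMSE, because their published
parameter vectors correspond to a g/g scaling and (for SSC) an intercept
sign inconsistent with the calibration means.

A note on the comprehensive logistic: on the packaged 21 calibration pairs
the global least-squares optimum is R² = 0.7437, RMSE = 0.1582 with
parameters (1.218, 0.090, 271.96) — verified by dense multistart.  The
historically reported statistics for this fit (R² = 0.757, RMSE = 0.154)
imply a residual sum of squares slightly *below* that optimum, so they
cannot be reproduced from the three-decimal published scores; the package
reports what it computes.

## Comprehensive evaluation

Hierarchy: appearance (CI, firmness), taste (SSC, OAC, SSC/OAC), nutrition
(lycopene, Vc).  Factor weights are subjective AHP weights — either derived
from a user 1–9 judgment matrix via power iteration with Saaty's
consistency ratio (CR ≤ 0.1 passes), or supplied directly; the study preset
(0.158, 0.680, 0.162) is the default because the original judgment matrix
is not published.

Sub-factor weights are entropy weights computed on the *direction-free*
(benefit-form) min–max standardization, with `0·ln 0 := 0`, normalized
within each factor; combined weights are the factor × sub-factor products.
Computing entropy on the direction-free standardization (rather than after
cost reversal) is deliberate: it reproduces the published sub-factor
weights of the 21-record calibration to ±0.001 in all seven positions,
pinning down the protocol actually used.  The corresponding weights for the
10-batch table do not reproduce exactly under any standardization variant
tried (they were most likely computed on unpublished replicate-level data);
only the published weight *arithmetic* is asserted for that table.

Criterion directions: organic acid is the only cost criterion.  Firmness is
kept as a benefit despite softening with ripeness — firm fruit stores and
ships better, and treating firmness as a cost inverts the published batch
ranking (the mid-August batch must come first), while the OAC-only
configuration reproduces both published extremal orderings.  Directions are
user-overridable per criterion.

TOPSIS: the direction-aware standardized matrix is weighted by the combined
weights; ideal/anti-ideal vectors are column-wise maxima/minima; distances
are Euclidean (with the square root — required for `C = D⁻/(D⁺+D⁻)` to be a
genuine relative distance; rankings on the calibration data are insensitive
to the choice).  Degenerate inputs (a single option, a constant column, an
option equal to both ideal and anti-ideal) are rejected with explicit
errors.  When scoring new data against a fitted calibration, standardized
values are clipped to [0, 1] so out-of-range samples cannot leave the score
interval.

## Synthetic data

The climate generator produces hourly series as diurnal sinusoids (minimum
~05:00, maximum ~17:00) around a seasonally modulated midpoint with
Gaussian noise, and a PAR half-sine (or flat) daylight profile scaled so
the hourly series integrates *exactly* to the scenario's daily solar total.
Defaults mirror the study greenhouse's ripening optimum (night minimum
14.3 °C, day maximum 26.3 °C, ±4 °C seasonal modulation, 8.5 MJ·m⁻²·d⁻¹
over a 10 h window), which keeps default daily means inside the observed
annual envelope (10.75–33.99 °C) and makes a ripening-length accumulation
span the calibration TEP range (~230–290 MJ·m⁻²).

The quality generator evaluates ground-truth response models (defaults: the
calibration fits) on a TEP grid — 21 points over 232–290 MJ·m⁻² by default —
and adds Gaussian noise with per-index SDs comparable to the calibration
replicate SDs (SSC 0.15 g/100 g, OAC 0.03 g/100 g, ...).  SSC, OAC and
SSC/OAC are drawn from their *own* models (so each model's parameters are
recoverable; the generated ratio is therefore not exactly SSC/OAC once
noise is added).  The remaining indices follow monotone trends whose
correlation signs against TEP match the observed pattern.  CIELAB
coordinates are generated and CI computed from them.

What the generators do **not** emulate: weather fronts and sensor dropouts
in climate; between-batch heterogeneity, replicate correlation structure,
and measurement rounding in quality.  Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the assumed noise
model, not robustness to real-world artefacts.

Seeding: a scenario seed fans out through `numpy.random.SeedSequence.spawn`
into per-component child streams, so adding a generator never perturbs
existing streams; the Monte-Carlo harness derives per-replicate seeds from
`SeedSequence.generate_state` reduced mod 2³¹.  The recovery experiment
(200 replicates by default, ~1 s) reports mean bias and RMSE per parameter;
under the default noise all estimates are unbiased within the Monte-Carlo
sampling band.

## Problem sizes and runtime

All calibration computations run on the 21-record fixture in well under a
second.  The test suite uses 40-replicate sign checks and 60–200-replicate
recovery runs, completing in a few seconds total — sizes chosen because the
Monte-Carlo standard errors they give are already an order of magnitude
below the assertion thresholds.

## Known limitations

* The package models quality *formation during ripening* against TEP; it
  does not model radiation transfer, energy balance, humidity/VPD, or
  cultivation management.
* The color index at mid-veraison is ill-summarized by stage means: CI is
  nonlinear in a*, whose replicate spread peaks during color change, so
  CI computed from mean CIELAB coordinates can deviate by up to ~0.5 units
  from the mean of replicate CIs.  The packaged tables keep the published
  per-table values verbatim (including one CI cell whose SD differs between
  the two source tables).
* Exact reproduction of published comprehensive *score values* is not
  claimed — they depend on unpublished direction/normalization choices;
  the package asserts the published weight arithmetic, both extremal
  orderings, and rank correlation with TEP instead.
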