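# Methods

## The buildup–tail PDD model

`dosefit` represents a flattened megavoltage photon central-axis percent
depth dose as

    PDD(d) = A · d / (d² + n) · e^(−μd),   d in cm,

a deliberately minimal two-shape-parameter form. The buildup factor
`d/(d²+n)` is zero at the surface and peaks at `d = √n`; `n` (dimension
treated as a bare scalar with depth in cm) grows with beam energy and
acts as a beam-hardening/dose-maximum-depth parameter. The tail factor
`e^(−μd)` is an effective exponential attenuation, `μ` in cm⁻¹. The
amplitude `A` is an explicit normalization constant: the model family
is defined only up to scale, and published depth-dose tables normalise
to 100% at the depth of dose maximum, so `evaluate_pdd` offers three
modes — `max100` (default; 100% at the analytic d_max), `at_depth`
(100% at a chosen reference depth) and `raw`.

**Depth of dose maximum.** Differentiating the product gives the cubic
`μd³ + d² + μnd − n = 0`, whose coefficient signs (+, +, +, −)
guarantee a single positive root; it lies in `(0, √n]` and is found by
a bracketed Brent solver (xtol 1e−12). `μ = 0` is admitted as a
degenerate limit with closed form `d_max = √n`, which also provides a
continuity test of the solver.

**Assumptions and scope.** No inverse-square, spectral-softening or
electron-contamination terms are included. Consequences, verified on
the packaged reference dataset: (i) in the buildup region the model is
badly wrong (tens of percent at 0.1 cm) — this is an intrinsic property
of the form, reported but never "fixed"; (ii) beyond d_max the form
decays like `e^(−μd)/d`, steeper than the near-constant log-slope of
real measured curves, so the best achievable fit to a measured column
over 1.5–23 cm still leaves a misfit of order 30% (a brute-force grid
search over (n, μ, A) confirms this is the global optimum, not an
optimiser failure). The packaged per-energy (n, μ) values are therefore
treated as reference coefficients for evaluation examples, and fit
quality on measured columns is a reported diagnostic rather than an
asserted bound. The packaged "modeled" depth-dose columns likewise
cannot be regenerated from the formula with any (n, μ, A) — the
comparison tables ship as data precisely so their error columns can be
reproduced arithmetically.

## Fitting

`BuildupTailModel(curve, FitConfig(...)).fit()` minimises the sum of
squared residuals over a depth window with `scipy.optimize.least_squares`
(trust-region reflective, bounds n ∈ (1e−6, 1e4), μ ∈ [0, 5], A > 0,
tolerances 1e−12; deterministic, no random restarts). Two residual
scales are offered:

* `relative` (default) — `(model − meas)/meas`; matches the field's
  percent-deviation reporting convention and is used for measured-data
  comparison reports.
* `absolute` — `model − meas`; statistically matched to additive noise
  on the percent scale, and used by the synthetic parameter-recovery
  harness. With relative weighting the deepest points of a max100 curve
  (PDD ≈ 1–2%, so 0.2% absolute noise ≈ 10–20% relative) dominate the
  objective and noticeably degrade recovery of n and μ.

The default window runs from the measured curve's maximum to its last
depth, excluding the buildup region for the reasons above; any window
may be set explicitly. The comparison table attached to a fit always
covers *all* depths of the input curve so that out-of-window misfit
stays visible.

**Initialization** is closed-form and deterministic: μ₀ is the negative
log-slope of the deepest third of the window (floored at 1e−4; it
over-estimates μ by roughly `mean(1/d)` because of the buildup factor's
`1/d` asymptote, which the optimiser subsequently removes), and for
each candidate n on a fixed log-spaced grid the amplitude minimising
the residual has the closed form `A = Σ(y·f)/Σ(f²)`, `f` being the unit
model. The best grid point starts the optimiser; the final objective
never exceeds the initializer's (trust-region steps are descent steps).

**Error tables.** Percent error is `100·(modeled − measured)/measured`,
stored unrounded and displayed rounded half-away-from-zero to 2
decimals (the convention of printed dose-report tables; numpy's
half-to-even would disagree on boundary cells). `summarize_errors`
reports the maximum absolute error (rounded to 2 decimals) and the RMS
error over rows at or beyond a minimum depth. Recomputing the packaged
reference error columns from their measured/modeled columns agrees with
the stored error cells within ±0.025 percentage points (the stored
columns carry their own upstream rounding; observed max discrepancy
0.021). One subtlety: the stored 6 MV error column has maximum
magnitude 1.17 for depths ≥ 1 cm, while errors recomputed from the
rounded measured/modeled cells peak at 1.178 (depth 20.5 cm) → 1.18;
summaries of the *packaged comparison* therefore use its stored error
cells, and summaries of recomputed comparisons use the recomputed
values.

## Collimator scatter factors

**Square fields.** `S_c(FS) = n_E · FS^(k·μ_E)` with `k` fixed at 0.63
by default (kept configurable; it is an empirical constant, not
derived). Calibration is least squares on relative deviations,
initialised by the closed-form log–log regression; the constrained
variant substitutes `n_E = 10^(−k·μ_E)` so that S_c(10×10) = 1 exactly
and fits μ_E alone. On the packaged measured tables (19 field sizes,
4–40 cm) the unconstrained fit tracks every row within 0.53% (6 MV)
and 0.29% (10 MV), inside the 0.8% working tolerance used for this
parameterization. The packaged tables' own printed deviation columns
are not used as ground truth (their two energy columns are on
mutually inconsistent scales — one in percent, one fractional); all
deviations are recomputed as `100·(model − meas)/meas`.

**Asymmetric jaws.** `S_c(U, L) = A · (U^w_upper · L^w_lower)^p`. Only
`A` and the products `p·w_upper`, `p·w_lower` are identifiable, so
fitted weights are reported normalised to `w_upper + w_lower = 1`;
calibration is least squares on relative deviations of all matrix
cells, initialised by the log-linear regression
`ln S_c = ln A + α ln U + β ln L`. The shipped default coefficients
(A = 0.88, w_upper = 0.65, w_lower = 0.35, p = 0.06) are a published
stand-alone calibration; they do **not** reproduce the packaged 6 MV
jaw matrix (they give 1.010 at 10×10 where the matrix has 1.0000), so
the package ships them verbatim *and* provides the refit path, without
declaring either authoritative. Refitting the packaged matrix yields
w_upper ≈ 0.59 > w_lower ≈ 0.41, consistent with the observed
collimator exchange effect; `exchange_effect` computes
`S_c(U, L) − S_c(L, U)` by exact-cell lookup (no interpolation between
jaw settings, to keep matrix comparisons unambiguous) or by model
evaluation, and is antisymmetric by construction.

Phantom scatter (S_p) and total scatter (S_cp) are out of scope, as is
equivalent-square conversion of rectangular fields.

## Synthetic data

`SyntheticScanConfig`/`gen_scan` emulate a water-phantom central-axis
scan: the model is evaluated on a regular grid (default 0.1–23 cm,
step 0.1 cm — 230 points, the usual scan geometry at SSD 100 cm),
normalised max100, with iid additive Gaussian noise on the percent
scale (default sd 0.2%, the order of chamber-scan repeatability;
film-vs-chamber agreement for such scans is typically better than
0.5%). `gen_sc_table` does the same for scatter tables and jaw
matrices. A seed is mandatory whenever noise is requested; generation
is reproducible bit-for-bit.

What the generator deliberately does not emulate: correlated detector
drift, depth-dependent noise, chamber-positioning error, spectral
changes with field size, or any misfit between the buildup–tail form
and real beams. Passing recovery tests therefore demonstrates that the
estimator is correct and well-conditioned *under the model*, not that
the model matches any particular linac.

**Recovery performance** (absolute-residual fits, full 0.1–23 cm
window, noise sd 0.2%, 20 seeds): worst-case relative error across the
four reference parameter sets is ≤ 0.8% for n and ≤ 1.9% for μ; biases
are below 0.1% (n) and 0.3% (μ). Estimator error shrinks monotonically
as the noise sd is lowered through 0.5/0.2/0.05/0.

## Numerical choices

* All model evaluations are vectorised closed forms; accuracy is set by
  double precision (~1e−15 relative), root-finding by Brent bracketing.
* Optimisation is deterministic end to end (fixed initial grid, no
  restarts); rerunning any fit or CLI command with identical inputs and
  seed is byte-identical.
* Exact-grid lookups (curve depths, jaw-matrix cells) use an absolute
  tolerance of 1e−9 and never interpolate.
* Degenerate inputs fail loudly: non-increasing depths, non-positive
  doses or field sizes, windows with fewer than 4 points, normalization
  at a depth where the model vanishes.

## Test-problem sizes

The suite fits 230-point synthetic scans (a few milliseconds each); the
recovery harnesses use 20 seeds, the d_max solver is cross-checked
against a 1e−4 cm brute-force grid arg-max on 100 random parameter
sets, and the full suite runs in a few seconds.

## Known limitations

* The two-parameter form cannot represent measured buildup regions or
  the quasi-linear log-slope of real tails to tabulated precision; use
  the error reports, not the raw coefficients, when judging clinical
  acceptability.
* `n` is treated as a bare scalar although it is added to d² (cm²); the
  dimensional mismatch is inherited from the functional form and left
  unresolved.
* The square-field S_c law assumes flattened beams and square fields;
  the jaw law's weights are machine-specific and must be recalibrated
  per linac.
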