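# Methods

## The analysis

Superficial white matter (SWM) lies within roughly 1–2 mm below the
grey/white (GM/WM) boundary, close enough to cortex and CSF that regional
diffusion measures are easily contaminated by partial volume.  The pipeline
therefore characterizes each region not by a single value but by a *cortical
profile*: each scalar metric volume is sampled along every boundary vertex's
outward unit normal at four signed offsets — +1 mm (likely GM), 0 mm
(boundary), −1 mm (likely SWM) and −2 mm (SWM/deep-WM mixture) — and group
differences are modelled jointly across those depths.

Five metrics enter the analysis: FA and MD from a weighted-least-squares
single-shell tensor fit, and NDI (neurite density), ODI (orientation
dispersion) and TF (tissue fraction, 1 − free-water fraction) from a
multi-compartment model.  NDI and ODI are only defined within the tissue
fraction of a voxel, so their regional summaries are *tissue-weighted* means
(weights = the TF sample at the same vertex and depth); FA, MD and TF use
conventional means.  ROI summaries are computed per hemisphere over a
15-region bilateral Desikan–Killiany selection and then averaged across
hemispheres (mean of the two hemisphere summaries, not a pooled vertex
mean).

### The mixed model

For each (ROI, metric) pair, with depth index d ∈ {0, 1, 2, 3} (the GM
sample is the intercept at d = 0) and group g ∈ {0 = control, 1 = case}:

    y_id = β0 + β1 d + β2 d² + β3 g + β4 g·d + β5 g·d² + β6 thickness_i
           + b0_i + b1_i d + ε_id

where thickness is the participant's mean cortical thickness of the ROI
(an atrophy proxy), (b0_i, b1_i) ~ N(0, Σ_g(i)) are participant random
intercept/slope with a full 2×2 covariance **per group**, and
ε_id ~ N(0, σ²).  Age and sex are not included.  A configuration option
codes the deepest point as distance 4 instead of 3 for sensitivity analyses
(four unit-spaced points make 3 the arithmetically consistent default).

Group-specific random-effect covariances are not expressible in
`statsmodels.MixedLM` (one shared covariance) nor as independent variance
components, so estimation is implemented directly: the exact Gaussian
marginal likelihood is evaluated per participant (V_i = Z_i Σ_g Z_iᵀ + σ²I,
Z_i = [1, d]), the fixed effects are profiled out by GLS, and the profiled
REML criterion (ML available) is maximized by L-BFGS-B over a log-Cholesky
parameterization of (Σ_control, Σ_case, σ²).  The likelihood implementation
is verified in the test suite against a dense multivariate-normal evaluation
at 1e-8 absolute tolerance.

**Numerical policy.**  The outcome is standardized internally (divided by
its SD) so variance parameters are O(1) across metrics whose natural scales
differ by 10³ (MD vs. the unit-interval metrics).  Starting values are
method-of-moments: covariances of per-participant OLS intercepts/slopes and
their residual variance.  Convergence requires a relative log-likelihood
change below 1e-10 or a projected gradient below 1e-6.  Three safeguards
handle degenerate surfaces:

* *Exact interpolation* (y = Xβ exactly): the (RE)ML supremum sits on the
  σ² → 0 boundary and interior quasi-Newton searches stall on a flat ridge,
  so a zero-residual check takes the limit analytically — β from OLS, zero
  random-effect covariance, σ² at a 1e-12 floor (standardized scale).
* *Runaway ridges*: a Cholesky off-diagonal pinned at its bound or a
  variance at its ceiling marks a pathological ridge; the fit restarts from
  a conservative fixed point and deterministic jitters of the start.
* *Fallback*: if the optimizer still fails, the model is refit with the
  control group's random slope removed (intercept-only control covariance)
  and flagged `fallback_used`; if that also fails the cell's AMEs are
  reported missing and the run continues.

### AMEs and multiplicity

The average marginal effect of group at depth d is the mean over observed
covariate rows of the predicted case-minus-control difference.  Because
thickness enters additively without a group interaction this equals the
coefficient contrast AME(d) = β3 + β4 d + β5 d² exactly (asserted to 1e-10
in tests).  Standard errors come from the delta method,

    se² = var β3 + d² var β4 + d⁴ var β5
          + 2d cov(β3,β4) + 2d² cov(β3,β5) + 2d³ cov(β4,β5),

with Wald 95% intervals (z = Φ⁻¹(0.975)) and two-sided normal p-values; no
small-sample degrees-of-freedom correction (Satterthwaite/Kenward–Roger) is
applied.  A 600-replicate simulation at the study's size (22 + 29) in the
test suite shows pooled CI coverage near 94–95%.  All AME p-values from all
models form one Benjamini–Hochberg family (step-up, q(i) = min_{j≥i}
p(j)·m/j, order-independent under ties), significant at adjusted p < 0.05.

## The synthetic cohort

The generator emulates the study's structure so that every stage is testable
without data: two groups (defaults 22 controls, 29 cases), 15 bilateral
ROIs, five metrics, four depths.

**Geometry.**  Each hemisphere is a sphere (default radius 49 mm, matching a
human-scale cortical radius of curvature) so the signed depth of any world
point from the boundary is exact: d(x) = 1 + R − ‖x − centre‖ in model
distance units (0 at the GM sample point, 3 at 2 mm into WM).  Vertices are
a seeded random rotation of a golden-angle spiral; ROI labels partition the
sphere into contiguous latitude/longitude patches, and the partition edges
are stored so any voxel can be labelled by the same analytic rule.  Faces
come from the convex hull, oriented outward.  Voxels default to 1 mm
isotropic (a config switch coarsens the grid for partial-volume
experiments).

**Signal model.**  The voxel value for participant i, metric m at world
point x is

    f(m, roi(x), group_i, d(x)) + b0_im + b1_im d(x) + noise,

clamped to the metric's valid range, with f a quadratic depth polynomial per
(metric, group) plus the configured case-group effect δ(m, roi, d).  Default
polynomials (configuration, not empirical claims) follow the qualitative
trends of real profiles at plausible magnitudes: FA 0.15 + 0.07d,
MD (1.00 − 0.06d)·10⁻³ mm²/s, NDI 0.35 + 0.07d, ODI 0.45 − 0.06d,
TF 0.68 + 0.06d.  TF additionally falls at 0.25 per mm outward of model
distance −1.5 — the approximate pial position under ~2.5 mm thickness — to
mimic CSF partial volume.  The onset and the TF slope are chosen so that
every slope kink and range clamp lies outside trilinear-interpolation reach
of the four sample points; otherwise the generator's closed form would not
be realizable by any sampler on a 1 mm grid.  Effects are either quadratic
polynomials in model distance or per-depth tables (piecewise linear in
between); `true_ame(config, roi, metric, depth)` returns the implied
population contrast exactly.

**Randomness.**  Participant random effects (intercept/slope SD defaults
0.02/0.005, ×10⁻³ for MD), voxel noise (SD 0.02, ×10⁻³ for MD) and per-ROI
thickness (control N(2.59, 0.08²), case N(2.49, 0.12²) mm) are drawn from
independent streams keyed by (master seed, participant index, purpose), so
cohorts are bit-reproducible, volumes can be generated lazily one
participant at a time, and resizing the cohort leaves earlier participants'
data unchanged.  The default thickness effect on metrics is zero, so with a
zero effect template the expected group difference of every regional summary
is exactly zero.  The default effect template is empty: real-data regional
effects depend on the original scans and are not reproduction targets.

A regional-summary-level simulator (`simulate_long_table`) realizes the same
model — template + planted effect + random intercept/slope + residual noise
(default SD: voxel SD / 8, the attenuation of ~64 effective vertices per
ROI) — without voxel grids.  Replicate-heavy statistical checks (CI
coverage, null FDR control, permutation invariance) use it because hundreds
of voxel-level cohorts would add only interpolation error to the quantity
under test; single voxel-level runs with planted effects are still exercised
end to end.

**What the generator does not emulate:** raw multi-shell NODDI signals (NDI/
ODI/TF are generated directly as scalar fields), head motion, eddy currents,
susceptibility distortion, spatially correlated noise (a config hook exists),
folded gyral geometry, or between-ROI heterogeneity of profiles (per-ROI
offsets default to zero).  Passing tests therefore demonstrate correctness
of the sampling, weighting and inference machinery under a known model —
not robustness to real-data artefacts.

## Sampling and interpolation

Surface sampling is trilinear by default (cubic optional); volume-to-volume
resampling (`resample_volume`) defaults to cubic, with out-of-field voxels
set to missing, never extrapolated.  Trilinear interpolation of a radial
field has an irreducible curvature error of order h²·f′/(4R) (~4 × 10⁻⁴ for
the default FA profile at h = 1 mm, R = 49 mm), which is why the
analyticity contract — sampled profiles match the generating closed form —
is stated as 1e-3 of each metric's representable full scale (1.0 for the
unit-interval metrics; 3 × 10⁻³ mm²/s, free-water diffusivity, for MD) at
the default geometry.  On smaller test spheres the error grows as 1/R, which
the test suite accounts for by checking the contract at the default radius.

## Tensor fit

The design matrix maps (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to log-signals;
multiple b=0 rows enter as ordinary rows (not pre-averaged) so the
reweighting treats them consistently.  Rows with non-positive signal are
dropped per voxel before the log transform; voxels with fewer than 7 usable
rows, or a rank-deficient remaining design, are flagged invalid and
propagate as missing FA/MD.  Negative eigenvalues from noisy fits are
retained (no positivity constraint); FA is clipped to [0, 1] and defined as
0 for an all-zero tensor.  On noiseless data the reweighted pass equals OLS
exactly, giving machine-precision round trips.

## Known limitations

* Wald/normal inference, no small-sample df correction: CI coverage at
  n = 51 participants is ~94–95%, slightly below nominal.
* The spherical phantom has no curvature variation, so ROI-boundary voxels
  mix neighbouring labels only through interpolation (~5–10% dilution of a
  planted single-ROI effect at 600 vertices/hemisphere).
* The fallback rate under the synthetic defaults (typically 0–2%) is a
  property of those conditions, not a reproduction target.
* Whether TF weights should be taken at each sampled depth or only at the
  boundary is ambiguous in the field; depth-matched weighting is the default
  and the `tissue_boundary` weighting scheme provides the alternative for
  sensitivity analyses.
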