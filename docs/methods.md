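# Methods

## Pulsatility metrics

A `FlowWaveform` is one cardiac cycle of volumetric flow rate Q(t) (ml/s)
sampled at strictly increasing times within `[0, RR)`, treated as
periodic: the last sample connects back to the first at `t0 + RR`.

**Cycle mean.** Q_mean is the integral of a *periodic cubic-spline*
interpolant over one full cycle divided by RR. The spline (rather than a
piecewise-linear/trapezoidal rule) is the package's integration choice
throughout: at the 20-phase temporal resolution typical of gated
reconstructions, the composite cumulative trapezoid carries an O(h²)
error of ≈0.8% on a sinusoid, whereas the spline antiderivative is
accurate to ~1e-5 there and ~1e-9 at 1000 samples. The spline is linear
in the data, so the linearity/shift invariances of the metrics are exact.

**PI (Gosling).** `(max Q − min Q) / Q_mean`, with extremes taken over
the *raw samples*, no smoothing — 20-phase data are already temporally
smoothed by reconstruction, and further smoothing would double-count the
blunting. PI is undefined (a `DomainError`) when the cycle-mean flow is
not positive; a signed PI for net-retrograde flow has no meaning in the
arteries modeled here.

**FVP.** The residual r(t) = Q(t) − Q_mean is interpolated periodically
and integrated; FVP is `max V − min V` of the antiderivative V. Because
V′ = r, the extrema of V fall exactly at the roots of the residual
spline, which are located analytically per cubic segment — no dense grid
is involved. FVP is invariant to vertical shifts of Q and homogeneous of
degree 1 in its amplitude.

**R–R standardization** divides either metric by RR in seconds,
normalizing to a 1-second reference cycle. The direction of the
adjustment (divide, not multiply) encodes the exposure argument: at equal
per-beat excursion, a shorter cycle delivers more excursions per unit
time, so the standardized value must *increase* as RR shrinks. Reported
segment-level values in the synthetic cohort are the standardized ones.

**Bilateral averaging.** Paired arteries (ICA, M1, M3) are summarized as
the mean of left and right; a missing side falls back to the
contralateral value; both sides missing propagates as a missing metric.
Total cerebral blood flow is the sum of mean flows of both ICAs and the
basilar artery and has *no* fallback — any missing vessel is an error.

Metrics are computed on the six-voxel-averaged segment waveform, not
averaged over per-voxel metrics: the segment waveform is the measured
object, and averaging first suppresses uncorrelated voxel noise before
the nonlinear max/min operations.

## Vessel phantom and emulated acquisition

The phantom is a tube of radius R (mm) on an isotropic voxel grid, with
an ordered centerline (points ≤ 1 voxel apart, ≥ R margin to the grid
boundary, R ≥ 2 voxels). At every cardiac phase the axial velocity is the
fully developed Poiseuille profile `2Q(t)/(πR²)·(1 − r²/R²)` along the
local centerline tangent. Womersley (oscillatory) profiles are
deliberately out of scope: the parabolic profile gives closed-form truth
(the analytic cross-section integral is exactly Q(t)) at every voxel, and
profile shape does not affect the flux a plane integrates. Velocities are
stored in cm/s, geometry in mm, flows in ml/s; the conversions are
centralized constants. A peak velocity above the velocity-encoding limit
(VENC, default 110 cm/s) is a configuration error unless aliasing is
enabled, in which case velocities wrap into `[−VENC, VENC)` by modular
arithmetic, as phase-contrast data would.

**Cross-section flux** at a centerline point sums the tangent-projected
velocity over voxels whose centers lie within half a voxel of the normal
plane, times the voxel cross-sectional area. For a straight tube at 0.5 mm
voxels and R = 2 mm this recovers Q to well under 3% (measured ≈0.5–0.9%
depending on grid alignment), and the error shrinks by ~3–4× when the
voxel size is halved (the profile vanishes at the wall, making the
boundary-cell error second order). Straight-tube constructors place the
tube axis on voxel centers, which is also the symmetric, least-biased
alignment.

**Segment flow** is the cross-section flux averaged over six consecutive
centerline voxels — the segment-length convention of centerline
processing schemes, where six voxels frequently span the M1 segment
proximal to its first bifurcation. The window start is a parameter, since
where the window sits inside a named segment is a free choice.

**Gated reconstruction** emulates retrospective cardiac gating:
acquisition samples at pseudo-random times over a train of heartbeats
(with configurable R–R jitter) are mapped to cardiac phase within their
own cycle and combined into n = 20 uniform phase bins, each sample
weighted triangularly to its two nearest bin centers (linear temporal
interpolation). Bin-averaging is a low-pass operation: it cannot exceed
the true systolic maximum, so the reconstructed PI is biased low, and the
bias grows as the systolic peak narrows relative to the bin width. The
cumulative-volume metric FVP is nearly unaffected. This asymmetry —
reconstructed PI ≤ dense PI, FVP's relative error below PI's for peaks
narrower than ~10% of the cycle — is asserted in the acceptance tests and
is the mechanistic reason FVP is proposed as the more robust biomarker.

**Parametric waveforms.** Q(t) = Q_mean + A·g(φ) + D·g_d(φ) + noise,
where g is a periodized Gaussian bump (FWHM = `peak_width` of the cycle)
made zero-mean and normalized to unit peak-to-peak — so the densely
sampled PI equals `A / Q_mean` when D = 0 — and g_d is an optional
dicrotic bump a quarter-cycle later. Defaults (mean 4.4 ml/s, A = 5.5
ml/s, RR = 0.9 s, peak at 16% of the cycle) give an internal-carotid-like
waveform of an elderly cohort with PI 1.25.

## Synthetic cohort

One row per subject; every random draw comes from one seeded generator.

* **Covariates.** Age ~ N(70.2, 8.9²) truncated to [50, 85]; 30% women;
  DBP ~ N(78, 10²) with pulse pressure ~ N(69, 15²); MAP = DBP + PP/3
  (the standard clinical estimate; the source context never defines MAP);
  hypertension 86.5%; four antihypertensive classes with cohort-typical
  prevalences; stroke vs TIA 72/28; tCBF ~ N(10.8, 1.7²) ml/s.
* **Pulsatility.** Per segment and metric, subject values are Gaussian
  with ICA PI 1.26 (0.37), M1 PI 1.28 (0.37), M3 PI 1.40 (0.51), ICA FVP
  0.47 (0.15), M1 FVP 0.28 (0.11), M3 FVP 0.06 (0.02) — standardized
  units — correlated 0.4 with age; left/right sides add 15%-of-SD noise;
  each side is missing independently at 5%. Outcomes are generated from
  the *pre-missingness* bilateral mean (physiology does not depend on
  whether a measurement succeeded), and the analysis then sees the
  post-missingness fallback values.
* **Outcomes.** WMH %ICV ~ Gamma(shape 1.2) with log-mean linear in age,
  sex, MAP, hypertension, tCBF, and one pulsatility term (default:
  ICA-FVP with slope 1.67, a headline-magnitude effect); values floored
  at 1e-4 %ICV so the gamma support holds. TBV %ICV and the cognitive
  aggregate are Gaussian with identity-link predictors (default slopes:
  −4.4 per unit M1-PI on cognition; 0 on TBV). Cognition is observed for
  ~54% of subjects (follow-up attrition).
* **Derived quantities.** ICV ~ N(1450, 130²) ml; GM/WM/CSF are solved
  from ICV and the generated TBV% so that ICV = GM + WM + CSF and
  TBV% = 100(GM+WM)/ICV hold exactly. Periventricular and deep Fazekas
  grades round a latent `a + 0.55·log(WMH%) + N(0, 0.5)` into 0–3; the
  intercepts (1.75 / 1.55) were fixed so that the SVD composite —
  Fazekas total ≥ 4, or recent subcortical infarct (17%), or lacune
  (15%), or > 2 microbleeds (Poisson 0.5) — has ~46% prevalence at
  n = 5000. Battery subtest scores are constructed from the target
  aggregate under the shipped norms (timed tests sign-flipped), so
  summing the per-test Z-scores reproduces the generated aggregate
  exactly; within-cohort standardization is the fallback when no norms
  are supplied, since the reference population of such batteries is a
  genuinely open choice.

What the generator does *not* emulate: images (volumes are numbers, not
segmentations), measurement error in the pulsatility values themselves,
covariate interdependence beyond the age links, scanner drift of FVP, or
informative missingness. Passing recovery tests therefore show the
*estimator* is correct under the assumed generative model, not that the
model describes any real cohort.

## Association analysis

GLMs are fit by iteratively reweighted least squares (statsmodels) with
convergence at relative deviance change < 1e-8 within 100 iterations;
non-convergence flags the result rather than raising. WMH uses
gamma/log (positive, right-skewed); TBV and cognition use
Gaussian/identity. Dispersion is Pearson χ²/(n − p) — the mainstream GLM
convention — and confidence intervals are Wald, estimate ± z₀.₉₇₅·SE, on
the coefficient scale; p-values are normal-based. Complete-case deletion
drops rows with any missing model variable; the battery requires ≥ 10
complete cases and otherwise skips the variant with a logged warning.
Sex is coded female = 1, hypertension 1 = present; antihypertensives
enter as four class indicators (an indicator-vs-count choice the source
context leaves open). Rank-deficient designs raise an error naming the
collinear columns (via pivoted QR). No multiple-testing correction is
applied (α = 0.05 throughout). M3 pulsatility is excluded from
multivariable modeling, and the SVD-subgroup battery fits WMH and TBV
only — follow-up cognition is too sparse in a subgroup. The ordinal
models for periventricular/deep Fazekas grades are documented as out of
scope, not implemented.

ICC(2,1) — two-way random effects, single rater, absolute agreement — is
computed directly from the ANOVA mean squares,
`(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))` with k = 2, and
cross-checked in the tests against both a brute-force sums-of-squares
oracle and pingouin's ICC(A,1).

## Pipeline and reproducibility

`run_pipeline` executes simulate-flow → metrics → simulate-cohort →
analyze. One global seed spawns per-stage substreams
(`numpy.random.SeedSequence`), so disabling a stage never shifts the
randomness of the others; the manifest records the seeds, configuration,
and SHA-256 of every output, and reruns are byte-identical. Velocity
fields are written as one NIfTI per component (4th dimension = phase,
float32) with a JSON sidecar for VENC, phase times, voxel size and R–R.

## Problem sizes and numerical choices

Default problem sizes keep everything desk-scale: phantom grids of ~25³
voxels at 0.5 mm (one refinement step to 0.25 mm), 20 cardiac phases,
demo cohorts of 400 subjects, and recovery studies of 200 replicates
(coverage) and 400 replicates (type-I) at n = 2000 — large enough that
the Monte-Carlo standard error of a 5% rejection rate is ~1%, small
enough to run in seconds. Waveform validation requires ≥ 3 samples,
strictly increasing times inside `[0, RR)`, finite values. FVP of a
constant waveform is exactly 0; degenerate rating vectors (zero total
variance) make the ICC undefined rather than silently 0/0.

## Known limitations

The phantom has no branches, no Womersley flow, no background phase or
eddy-current artifacts, and no k-space simulation; centerline geometry is
known, not discovered from an angiogram. The cohort generator's
covariates are mostly marginally independent, so confounding structure
beyond the age links cannot be studied with the defaults. Venous and CSF
pulsatility are out of scope.
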