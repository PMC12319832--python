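# Methods

This note documents the models, numerical choices and known limitations of
`mmnflow`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Paradigm

A tone sequence is generated from a piecewise-constant probability
schedule. Phase labels live on the *schedule*, not the realised draws: a
maximal run of constant probability of at least `stable_min_len` trials
(default 90) is stable, everything else volatile. Adjacent segments with
equal probability are merged before labelling, since stability is a
property of the generative probability.

Trial types are defined by local run structure. A deviant follows at least
5 repetitions of the other tone; a standard is *exactly* the 6th
consecutive repetition of the same tone — the 7th and later repetitions
are "other". We read "6th repetition" strictly as run position 6: a
12-trial run contributes one standard, not two. A deviant is defined by
the preceding run only, so a deviant can itself start a run that later
yields a standard. Both rules are checked against an independent
brute-force run-length scanner in the tests.

The default template alternates long stable blocks (120 trials at extreme
probabilities, 0.9/0.1 style) with 90-trial volatile blocks composed of
rapid switches between extreme probabilities plus a short stochastic
(p ≈ 0.5) stretch. Volatile phases with only p = 0.5 segments would starve
the per-phase standard/deviant counts; rapid extreme switches produce
standards and deviants at rates comparable to the stable phases, which is
what a volatility-manipulating oddball design requires. The template
composes for any length ≥ 90 trials; deposited designs can be loaded from
TSV instead.

## Hierarchical Gaussian filter

The 3-level binary HGF is implemented in observer mode with no drift and
fixed κ = 1 by default. Update order per trial: level-1 prediction
μ̂₁ = logistic(μ₂⁻); prediction error δ₁ = u − μ̂₁; predicted level-2
variance σ̂₂ = σ₂⁻ + exp(κμ₃⁻ + ω₂); posterior precision
π₂ = π̂₂ + μ̂₁(1−μ̂₁); mean update μ₂ = μ₂⁻ + δ₁/π₂; volatility prediction
error δ₂ = (σ₂ + Δμ₂²)/σ̂₂ − 1; level-3 update with weight (κ/2)·w₂·δ₂
where w₂ = exp(κμ₃⁻+ω₂)/σ̂₂.

Two variants are provided. The classical variant updates the level-3
precision first and raises a `PrecisionViolation` naming the trial if it
goes non-positive. The enhanced variant (default) updates the level-3
mean first using the *predicted* precision (μ₃ = μ₃⁻ + σ̂₃·(κ/2)·w₂·δ₂),
then the precision, floored at 1e−8 with a counter of floored trials.
The floor value only engages in pathological parameter regions; the
published enhanced implementation could not be compared line by line in
this environment, so the exact stabilisation here is this package's own
convention and is recorded in every output header.

Precision-ratio conventions: the generic update Δμᵢ ∝ (π̂ᵢ₋₁/πᵢ)·δᵢ₋₁ is
ambiguous at the binary bottom level. The default is ψ₂ = 1/π₂, which
makes ε₂ = ψ₂δ₁ equal the level-2 belief update exactly; a config switch
(`psi2_convention="pihat1_ratio"`) exposes ψ₂ = π̂₁/π₂ instead. ψ₃ = π̂₂/π₃
throughout. Surprise is in natural log (nats); the base only rescales the
observer objective.

Default initial conditions are μ₂₀ = 0, σ₂₀ = 0.1, μ₃₀ = 1, σ₃₀ = 1,
matching common published defaults for this model family. A 3-trial
golden trajectory, recomputed independently at 50-digit precision, pins
the arithmetic to 1e−10 in the tests.

## Bayes-optimal observer

Because the task is passive, the perceptual parameters (free set: ω₂, ω₃)
are fitted by minimising total surprise plus a Gaussian prior penalty —
a MAP ideal-observer fit. Default priors are N(−3, 16) for ω₂ and
N(−6, 16) for ω₃; they are deliberately weak and config-overridable, and
are assumptions of this package, not published values.

The surprise surface on realistic sequences is *multimodal*: a
slow-learning basin near the prior mean can coexist, behind a barrier of
a few tenths of a nat, with a fast-learning basin at much larger ω
values. Plain multi-start from jittered prior means missed the global
basin on roughly one sequence in ten. The fit therefore first evaluates
the objective (a jit-compiled scalar kernel, ~20 µs per 200-trial
sequence) on 256 Latin-hypercube points spanning ±2.5 prior SD per free
parameter, seeds 8 L-BFGS-B restarts from the prior mean and the best
scan points, and polishes the winner with a Nelder-Mead simplex. The
agreement check against an exhaustive 201×201 grid refines the grid
argmin by a local descent so both sides measure the same continuum
optimum; parameter-space agreement is then at the 1e−4 level.
Parameter values that violate a precision constraint or overflow map to
+∞ in the objective (penalised, not raised).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- **Layout**: the 64-electrode cap from the standard `biosemi64` montage,
  normalised to the unit sphere and projected azimuthal-equidistant from
  the vertex into the unit disc. Reduced-channel layouts take an evenly
  spread subset; component centres are always resolved against the full
  cap so effect geometry is montage-independent.
- **Epochs**: trials × channels × 154 samples at 256 Hz, −100 to ~498 ms,
  in µV.
- **ERP backbone**: Gaussian space × time components with unit peak — an
  N1-like common negativity (100 ms, −1 µV), an MMN-like frontocentral
  deviant negativity (175 ms, FWHM 50 ms) and a P3a-like central deviant
  positivity (275 ms). The MMN amplitude is phase-dependent: −3.3 µV in
  stable and −1.0 µV in volatile phases. These values were calibrated so
  that, at the study's scale (43 subjects, 1800 trials, the default noise
  model), the paired stable-vs-volatile contrast has a per-subject
  standardised effect of ≈0.9 — the magnitude implied by the reported
  peak statistics of the phenomenon this generator emulates. They are
  part of the study conditions, not tuning knobs.
- **Trajectory coupling**: voltage adds A·g(c)·h(t)·z(k) per effect, with
  z the z-scored trajectory. Default effects follow the reported sensor
  geometry: δ₁ at FCz/137 ms (1.2 µV/z), δ₂ at FCz/141 ms (1.0),
  ψ₂ at Cz/117 ms (0.8), ψ₃ at Fz/207 ms (1.2); subject amplitudes vary
  around the group mean with SD 0.3 µV/z.
- **Noise**: zero-mean Gaussian, marginal SD 8 µV, exponential spatial
  kernel (length scale 0.35 disc units) via Cholesky mixing, AR(1) in
  time (φ = 0.8) with unit-marginal parameterisation.
- **Artifacts**: with probability 0.028 per trial a ±150 µV square pulse
  on one random channel (mirroring a ~97% artifact-free rate). Eyeblink
  morphology is not simulated.
- **Covariates**: integer GF scores 6–10 skewed toward 9, age ≈ N(22.9,
  6.8²) clipped, working memory ≈ N(6.6, 2.1²), cannabis y/n ≈ 27/16.
  If a covariate link is configured, each subject's extra volatile-phase
  deviant-P3a amplitude is intercept + slope·(GF_social − 8) + noise
  (default slope 0.5 µV per score unit), giving second-level covariate
  regressions a known slope.

What passing tests on these cohorts do *not* show: robustness to real
EEG nuisances absent from the generator — eyeblinks and other structured
artifacts, non-stationary noise, channel drift, inter-subject latency and
topography variability, volume-conduction correlation structure beyond an
isotropic kernel.

## Preprocessing

Order: baseline correction (−100..0 ms mean per trial and channel), then
bad-channel interpolation, then threshold rejection. A channel is bad when
its own ±75 µV exceedance rate across trials is above 20%; it is replaced
on all trials by an inverse-distance-weighted mean of its 4 nearest clean
channels (chosen over spherical splines for determinism; the method name
is recorded in the report). Rejection then drops any trial with any
channel/sample beyond ±75 µV; with a repaired channel the trial is judged
on the repaired data. More than 50% bad channels is a hard error.
Band-limiting is zero-phase Butterworth (HP 0.1 Hz, LP 30 Hz, 4th order)
with polyphase resampling to 256 Hz; the high-pass uses padding on the
scale of its own time constant because a 0.1 Hz corner rings for ~10 s.

## Sensor statistics

Channel data are mapped to a 2-D grid by precomputed barycentric linear
interpolation over the Delaunay triangulation of the projected positions
(exact for planar fields; voxels outside the convex hull are invalid).
The default grid is 32×32 over the unit disc; the projection is scaled at
100 mm per disc radius, and the default spatial smoothing of 16 mm FWHM
is converted through that scale. Smoothing is mask-aware: image and mask
are smoothed separately and renormalised, so no kernel mass is attributed
to invalid voxels; FWHM 0 is the identity.

First-level GLMs regress per-trial images on an intercept plus
z-standardised trajectories (z-scored over retained trials only, never
orthogonalised); three canonical designs are exposed: `lowlevel`
(δ₁, ψ₂), `highlevel` (δ₂, ψ₃), `pwpe` (ε₂, ε₃). OLS is solved by normal
equations per voxel; t = β/SE and the single-column F is t². Zero
residual variance yields flagged infinite t (sign 0 maps to t = 0).

Second-level models are one-sample t over subject images or a regression
on [1, covariate, nuisance...]. Inference is restricted to 100–400 ms.
Clusters are 26-connected components over (x, y, time) of |t| above the
two-sided cluster-defining threshold (p < 0.001 under the t distribution
at the model's dof). Family-wise error is controlled by permutation —
sign-flipping subject images for one-sample designs, covariate-row
shuffling otherwise — using the max-cluster-mass null for cluster p and
the max-|t| null for peak p, with the standard add-one estimator
p = (1 + #{null ≥ obs})/(1 + n_perm). This replaces random-field-theory
correction deliberately: permutation is exact under exchangeability and
needs no smoothness estimator; the method tag is recorded on every
StatMap so results are never mislabelled. Peak grid locations are mapped
to the nearest projected channel name as a reporting convention.

A practical note on small cohorts: the two-sided max statistic is
invariant under a global sign flip, so n subjects give 2^(n−1) distinct
sign-flip classes. With 5 subjects the smallest attainable corrected p is
~1/16 = 0.0625; calibration studies of the 0.05 level therefore use 8
subjects (128 classes), the smallest cohort for which the level is
attainable.

## Validation studies (mmnflow.validation)

Problem sizes were chosen once, as the package's own desk-scale study
conditions: FWE calibration uses 200 null cohorts of 8 subjects × 60
trials × 16 channels on a 12×12 grid with 200 permutations;
effect-recovery power uses 50 cohorts of 20 subjects × 400 trials (a
pilot power calculation shows the cluster-defining threshold is not
attainable at much smaller n); the stable-vs-volatile MMN contrast runs
one cohort at the study's own scale, 43 subjects × 1800 trials. Detection
is defined as a significant cluster *containing* the embedded
topography-centre voxel within ±12 ms of the embedded latency. The
first-level betas in these studies are computed on channel-level data and
then mapped and smoothed; this equals mapping and smoothing per-trial
images first (mapping and smoothing are fixed linear operators and OLS
is linear in the data) and the equivalence is asserted by a unit test.

## Known limitations

- No source reconstruction; sensor space only.
- No continuous-data vendor format I/O; epochs travel as HDF5 + JSON.
- The observer is never fitted to behaviour; model comparison across
  observer families is out of scope.
- The eHGF stabilisation is this package's convention (see above).
- IDW interpolation is biased toward the neighbour centroid for strongly
  tilted fields; the bias bound is asserted in tests.
- Permutation p-values are Monte-Carlo estimates; with n_perm = 1000 the
  resolution is ~1e−3 and results near a threshold should be rerun with
  more permutations.
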