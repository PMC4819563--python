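# Methods

## Signal model

Transverse relaxation of the multi-echo signal is modeled as a pure
exponential (single component) or a convex mixture of exponentials
(multi-compartment) with all times in milliseconds and amplitudes in
arbitrary scanner units:

* mono: S(TE) = S₀ e^(−TE/T2)
* multi: S(TE) = S₀ Σᵢ vᵢ e^(−TE/T2ᵢ), vᵢ ≥ 0, Σvᵢ = 1

The default basis T2 = [20, 80, 2000] ms encodes myelin water, intra- and
extra-cellular tissue water, and free water (CSF). No T1 effects,
stimulated-echo corrections, B1 inhomogeneity, or EPG modeling are included:
the decay model is deliberately the plain exponential family, and the
fraction at 20 ms is read directly as the myelin water fraction (MWF). Over
a 13–150 ms echo train the 2000 ms column is nearly constant, so the
three-column design is poorly conditioned (condition number ≈ 21 raw, ≈ 15
after column normalization); `basis_condition_report` exposes this so users
understand that the free-water fraction is the least-determined coordinate.

## Mono-exponential estimation

1. **Log-linear initialization.** OLS of ln S on TE. Echoes with
   non-positive signal are excluded from this stage only; with fewer than
   two usable echoes the fallback (S₀ = max signal, T2 = 70 ms — mid-range
   for adult white/gray matter) is used. A non-negative slope (flat,
   CSF-like data over this echo range) initializes T2 = 2000 ms.
2. **Gauss–Newton refinement** of (T2, S₀) minimizing the original-space
   SSE via the normal-equations update. Safeguards beyond the raw update:
   * *Backtracking:* a step that would raise the SSE or drive T2 ≤ 0 is
     halved up to 20 times (counted as one iteration), so the accepted
     residual sequence is non-increasing.
   * *Damping:* Levenberg term λ = 1e−10·trace(DᵀD) added only when the 2×2
     normal matrix condition exceeds 1e12.
   * *Convergence:* |Δ SSE| < 1e−6 evaluated on signals normalized by the
     first-echo scale (the mean first-echo intensity of the fitted set for
     volumes; the curve's own first echo for single fits), because an
     absolute SSE tolerance is meaningless across arbitrary intensity
     scales. Reported S₀ and residuals are rescaled to original units. Cap:
     500 iterations.

`fit_mono_volume` runs a vectorized batch implementation of the identical
update over all masked voxels; the scalar `gauss_newton_fit` is the readable
reference path and the test suite asserts their agreement on noisy volumes.
Unmasked voxels carry NaN, which every downstream ROI statistic skips and
counts.

## Three-compartment estimation

Both model constraints with a free overall amplitude are satisfied by
unconstrained-scale NNLS on amplitudes aᵢ = S₀vᵢ followed by normalization
(S₀ = Σaᵢ, v = a/S₀). No explicit regularization is added; the implicit L1
shrinkage of NNLS already yields sparse amplitude vectors. All-zero
solutions (background voxels) are flagged degenerate, reported as NaN, and
excluded from ROI statistics.

## ROI and cohort statistics

Label images use codes 0/1/2/3 = background/CSF/GM/WM. Volumes are voxel
counts × voxel volume (mm³ → liters); intracranial volume is defined as the
sum of the three segmented classes, which makes volume additivity exact by
construction. ROI curve averages are arithmetic means per echo; map
summaries report mean, sample SD (n−1 throughout), and the number of valid
voxels. Label resampling between grids is nearest-neighbour only —
registration estimation is out of scope and synthetic data are generated
co-registered.

Group comparisons are two-sided pooled-variance Student's t-tests (Welch
available behind a flag); significance is conventionally read at p < 0.05
with no multiple-testing correction by default, mirroring the analysis
style this package reproduces (a Holm option would be a deliberate
extension). The covariate-adjusted contrast fits OLS
`variable ~ group + covariate` and reports the group-coefficient t and p;
the default covariate for WM T2 contrasts is WM volume, configurable since
"brain volume" admits several measures.

## MCMC posterior

Metropolis–Hastings over (v, S₀) for one ROI-averaged curve:

* fraction proposal v′ ~ Dirichlet(κ·v), κ = 500 by default — simplex-valid
  by construction, with the asymmetric proposal density in the Hastings
  ratio (current fractions are floored at 1e−8 to keep concentrations
  positive);
* flat Dirichlet(1,1,1) prior on fractions (no information invented);
* S₀: log-normal random walk (1% step), flat positive prior, s0′/s0
  Jacobian included;
* Gaussian iid likelihood with fixed σ; the default plug-in is the RMS
  residual of an NNLS fit to the same curve;
* chain initialized at the NNLS point estimate; defaults 100k burn-in +
  100k further iterations, keeping every 20th post-burn-in state (5000
  samples); the `scaled()` preset (2k/2k/500) is used throughout the tests.

Two caveats are documented as deliberate choices. First, for *synthetic
group-averaged* curves the NNLS-residual plug-in collapses (measurement
noise averages out over ~10⁴ voxels), freezing the chain; the pipeline
therefore uses the per-echo standard error of the group-mean curve across
subjects (RMS over echoes) as σ, which is the relevant uncertainty of a
group mean and restores healthy acceptance rates (~0.1 with κ = 500).
Second, κ trades acceptance against mixing: in the flat-likelihood regime a
smaller κ (wider proposal) is needed for adequate effective sample size,
and the prior-recovery test uses κ = 50 for exactly that reason.

## Synthetic cohort generator

The generator emulates a two-group, two-sex study: 43 extremely-preterm
subjects (16 male, 27 female) and 20 term-born controls (10, 10), imaged
with ten echoes at TE = {13, 16, 20, 25, 30, 40, 50, 85, 100, 150} ms and
2.5 × 2.5 × 3.0 mm voxels. Stratum-level ground truths (WM/GM/CSF volume
means ± SD, WM MWF mean ± SD, WM effective T2 mean ± SD, defaults in
`cohort_defaults.yaml`) are the published group summaries of the study this
pipeline re-implements; where only marginal (group or sex) summaries exist,
per-stratum values were allocated so the size-weighted marginals reproduce
them. GM and CSF volumes, not printed in that source, are realistic
adolescent values respecting the reported direction of group differences.

**Fraction calibration.** On the fixed basis, the effective mono-fit T2 of
a WM mixture falls with the myelin fraction (≈ −57 ms per unit MWF locally)
and rises with the free-water fraction (≈ +165 ms per unit). With MWF ≈
0.25 the attainable floor at zero free water is ≈ 67.2 ms, so drawing MWF
and effective T2 independently is infeasible roughly half the time and
clamping would bias group T2 upward by > 1 ms. Instead, per stratum the
free-water fraction c̄ is solved (bisection) so the mean mixture's mono fit
hits the stratum T2 mean; per subject the myelin fraction is a logit-normal
draw whose location is quadrature-corrected to make its *expectation* equal
the stratum MWF mean, and c is a truncated-normal draw whose location is
likewise corrected for the truncation at zero. The free-water spread is set
from the residual T2 variance not already induced by the MWF spread (zero
when the MWF-induced spread covers the target, which slightly widens the
realized T2 SD in the tightest strata — a documented approximation).
Realized effective T2 per subject is recorded by actually mono-fitting the
noiseless mixture, so the truth ledger is exact by construction rather than
by formula.

**Geometry and noise.** Concentric shells ordered by distance from the grid
center (CSF core, WM interior, GM shell) with voxel counts matched exactly
to the drawn volumes; anatomy is deliberately schematic because every ROI
statistic depends only on label membership. Noise is additive iid Gaussian
with SD = (mean WM first-echo signal)/SNR, SNR 150 by default — a declared
choice, as is the Gaussian (not Rician) model, which matches the
least-squares estimators being validated. All randomness flows from one
seed through per-subject `SeedSequence` spawns.

**Desk scaling.** The default cohort uses voxel_scale 2 (5 × 5 × 6 mm
voxels on a 26 × 26 × 16 grid, ~7–9k tissue voxels per subject), chosen so
a full 63-subject run completes in seconds while volume quantization error
(< 1e−4 l) stays negligible against the 0.03–0.04 l between-subject SDs.
Setting voxel_scale 1 restores the native resolution on a proportionally
larger grid.

**What the generator does not emulate:** real anatomy, partial-volume
mixing at tissue boundaries, spatially correlated or Rician noise, motion
and bias fields, registration error between the label and echo spaces.
Passing recovery tests therefore demonstrate estimator correctness under
the stated generative model, not robustness to those real-data effects.

## Validation strategy

* Noiseless exactness: both fitting stages recover mono parameters to
  ≤ 1e−6 relative error; NNLS recovers basis-generated fractions to 1e−6.
* Independent oracles: Gauss–Newton T2 against a dense profiled grid search
  (0.001 ms refinement) on 100 seeded noisy curves; NNLS against a 0.001
  simplex-grid enumerator — elementwise agreement scaled by the design
  conditioning (the grid argmin slides along the flat long-T2 valley) plus
  an exact SSE-dominance check.
* Cohort recovery: one full default cohort run must reproduce the
  generating group summaries within twice the Monte-Carlo SD of each group
  mean across repeated cohorts, estimated from 1500 subject-level draws per
  stratum of the generator itself.
* Sampler validity: posterior concentration at the NNLS estimate under a
  sharp likelihood; prior recovery in the flat-likelihood limit; bitwise
  determinism under fixed seeds.
* Statistical calibration: ~5% type-I rate of the prematurity t-test over
  200 null-cohort replicates; and a volume-mediated construction in which
  the raw WM T2 group difference is significant but vanishes after volume
  adjustment.

## Known limitations

* The fixed three-point basis cannot represent continuous T2 spectra; no
  regularized inverse-Laplace estimation is attempted.
* The free-water fraction is weakly identified over a 150 ms echo train
  (see conditioning above); its per-voxel estimates are noisy and its
  posterior is the widest relative to its magnitude.
* The mono-fit convergence tolerance normalization makes `tol` scale-free
  but means residual thresholds are not comparable across masks with very
  different first-echo intensities.
* Group-level MCMC σ is a modeling choice (see above); users comparing
  against per-voxel noise should pass `noise_sd` explicitly.
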