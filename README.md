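# relaxo

Quantitative multi-echo T2 relaxometry for brain MRI: single-component T2
mapping, three-compartment myelin water fraction (MWF) estimation, ROI and
cohort statistics, and MCMC posterior analysis of compartment fractions —
plus a synthetic multi-echo cohort generator so the whole pipeline can be
exercised and validated end to end without access to scanner data.

## Who this is for

Researchers analyzing multi-echo T2-weighted acquisitions (e.g. a ten-echo
train at TE = 13–150 ms) who want per-voxel tissue parameters and
group-level comparisons — the motivating application is comparing white
matter composition and tissue volumes between extremely-preterm-born and
term-born cohorts, where reduced brain volume coexists with apparently
normal tissue composition.

## The models

**Single-component decay.** Each voxel's signal is modeled as
S(TE) = S₀·e^(−TE/T2). A log-linear least-squares fit of ln S on TE
initializes (S₀, T2); Gauss–Newton iterations on the *original* signal
scale then refine the estimate, with Jacobian columns
∂S/∂S₀ = e^(−TE/T2) and ∂S/∂T2 = S₀·(TE/T2²)·e^(−TE/T2), stopping when the
residual change falls below 1e−6 (or 500 iterations).

**Three-compartment decay.** S(TE) = S₀·Σᵢ vᵢ·e^(−TE/T2ᵢ) with vᵢ ≥ 0 and
Σvᵢ = 1 on the fixed basis T2 = [20, 80, 2000] ms (myelin water, intra- and
extra-cellular tissue water, free water/CSF). Non-negative least squares on
the amplitudes aᵢ = S₀vᵢ enforces non-negativity; normalizing by S₀ = Σaᵢ
supplies the sum-to-one constraint. The MWF is v at 20 ms.

**Posterior analysis.** For an ROI-averaged curve, a Metropolis–Hastings
chain samples (v, S₀) under a Gaussian signal-space likelihood, with
simplex-valid Dirichlet(κ·v) proposals for the fractions, a flat Dirichlet
prior, and a log-normal random walk on S₀.

**Group statistics.** Two-sample pooled-variance Student's t-tests across
prematurity and sex, and a covariate-adjusted contrast
(variable ~ group + volume) for testing whether a group difference survives
controlling for brain volume.

## Worked example

```python
import numpy as np
from relaxo import (EchoSeries, DEFAULT_BASIS, DEFAULT_ECHO_TIMES_MS,
                    predict_multi, gauss_newton_fit, nnls_fractions,
                    ChainConfig, run_chain)

te = np.asarray(DEFAULT_ECHO_TIMES_MS)           # 13 ... 150 ms
rng = np.random.default_rng(0)

# A white-matter-like voxel: 25% myelin water, 2% free water, SNR 150.
signal = predict_multi(1000.0, (0.25, 0.73, 0.02), DEFAULT_BASIS, te)
curve = EchoSeries(te, signal + rng.normal(0, signal[0] / 150, te.size))

mono = gauss_newton_fit(curve)
print(f"effective T2 = {mono.t2:.1f} ms")

multi = nnls_fractions(curve, DEFAULT_BASIS)
print(f"MWF = {multi.mwf:.3f}")

post = run_chain(curve, DEFAULT_BASIS, ChainConfig.scaled(seed=1))
print(f"posterior MWF = {post.mean[0]:.3f} +/- {post.sd[0]:.3f}")
```

Output:

```
effective T2 = 70.5 ms
MWF = 0.225
posterior MWF = 0.226 +/- 0.011
```

The mono-exponential fit reports a single "effective" T2 (~70 ms) that
blends the fast myelin and slow free-water pools; the three-compartment fit
separates them and recovers the myelin water fraction near its true 0.25;
the MCMC posterior quantifies its uncertainty at this noise level.

Command-line equivalents: `relaxo simulate`, `relaxo fit-mono`,
`relaxo fit-mwf`, `relaxo roi-stats`, `relaxo group-compare`, `relaxo mcmc`,
and `relaxo run` (the full pipeline on a synthetic cohort). See
`relaxo --help`.

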