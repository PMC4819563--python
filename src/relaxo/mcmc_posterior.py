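"""Posterior analysis of compartment fractions by Metropolis–Hastings.

For a single ROI-averaged decay curve (typically the white-matter average of
a subject or group) the sampler explores the joint posterior of the
compartment fraction vector ``v`` on the simplex and the total amplitude
``S0`` under the multi-compartment forward model with an i.i.d. Gaussian
likelihood in signal space.

Sampler design
--------------
* Fraction proposals are drawn from a Dirichlet distribution centered on the
  current state, ``v' ~ Dirichlet(kappa * v)``, which guarantees
  simplex-valid proposals; the asymmetric proposal density enters the
  Hastings ratio.  ``kappa`` controls the step size (larger = smaller steps).
* The prior on fractions is flat, Dirichlet(1, ..., 1).
* ``S0`` takes a log-normal random walk (default 1% step) with a flat
  positive prior; the s0'/s0 Jacobian term is included.
* The likelihood noise SD defaults to the RMS residual of an NNLS fit to the
  same curve, held fixed during sampling.

The chain runs ``n_burn`` burn-in iterations, then ``n_run`` further
iterations from which every ``floor(n_run / n_keep)``-th state is retained.
Default lengths are 100,000 / 100,000 with 5,000 kept samples; the
``scaled()`` preset (2,000 / 2,000 / 500) is intended for test work.  A fixed
seed makes the chain bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .multi_fit import nnls_fractions
from .signal_models import CompartmentBasis, DEFAULT_BASIS, EchoSeries

__all__ = ["ChainConfig", "PosteriorSamples", "run_chain", "posterior_report"]

_FRACTION_FLOOR = 1e-8  # keeps Dirichlet concentrations strictly positive


@dataclass(frozen=True)
class ChainConfig:
    """Settings of one Metropolis–Hastings run."""

    n_burn: int = 100_000
    n_run: int = 100_000
    n_keep: int = 5_000
    proposal_concentration: float = 500.0  # kappa of Dirichlet(kappa * v)
    s0_step: float = 0.01  # SD of the log-normal S0 random walk
    noise_sd: float | str = "estimate"  # signal-space sigma, or NNLS plug-in
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_keep > self.n_run:
            raise ValueError("n_keep must not exceed n_run")
        if self.proposal_concentration <= 0:
            raise ValueError("proposal_concentration (kappa) must be positive")
        if self.s0_step <= 0:
            raise ValueError("s0_step must be positive")
        if not (self.noise_sd == "estimate" or float(self.noise_sd) > 0):
            raise ValueError("noise_sd must be positive or 'estimate'")

    @property
    def thin_stride(self) -> int:
        return max(self.n_run // self.n_keep, 1)

    @classmethod
    def scaled(cls, **overrides) -> "ChainConfig":
        """Short preset (2k burn / 2k run / 500 kept) for fast runs."""
        cfg = cls(n_burn=2_000, n_run=2_000, n_keep=500)
        return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class PosteriorSamples:
    """Thinned posterior draws of compartment fractions (and S0)."""

    samples: np.ndarray  # (n_keep, n_compartments)
    s0_samples: np.ndarray  # (n_keep,)
    acceptance_rate: float
    basis: CompartmentBasis
    config: ChainConfig
    noise_sd: float

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.samples.std(axis=0, ddof=1)


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    return float(gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * np.log(x)).sum())


def run_chain(curve: EchoSeries, basis: CompartmentBasis = DEFAULT_BASIS, config: ChainConfig | None = None) -> PosteriorSamples:
    """Sample the posterior of (fractions, S0) for one decay curve.

    The chain is initialized at the NNLS point estimate (or at the flat-prior
    mean when the NNLS fit is degenerate).  Identical curve, basis, and
    config (including seed) reproduce the samples bitwise.
    """
    if config is None:
        config = ChainConfig()
    rng = np.random.default_rng(config.seed)
    A = basis.design_matrix(curve.echo_times)
    y = curve.signals
    if not np.any(np.abs(y) > 0):
        raise ValueError("zero-amplitude curve: posterior is undefined")

    point = nnls_fractions(curve, basis)
    k = basis.n_compartments
    if point.degenerate:
        v = np.full(k, 1.0 / k)
        s0 = float(np.abs(y).max())
    else:
        v = np.clip(point.fractions.fractions, _FRACTION_FLOOR, None)
        v = v / v.sum()
        s0 = point.s0

    if config.noise_sd == "estimate":
        sigma = float(np.sqrt(point.residual_norm / len(curve)))
        if sigma <= 0:  # noiseless curve: fall back to a tiny relative scale
            sigma = 1e-6 * max(s0, 1.0)
    else:
        sigma = float(config.noise_sd)

    kappa = config.proposal_concentration
    inv_two_sigma2 = 0.5 / sigma**2

    def loglik(v_, s0_):
        r = y - s0_ * (A @ v_)
        return -inv_two_sigma2 * float(r @ r)

    ll = loglik(v, s0)
    n_total = config.n_burn + config.n_run
    stride = config.thin_stride
    kept = np.empty((config.n_keep, k))
    kept_s0 = np.empty(config.n_keep)
    n_kept = 0
    n_accept = 0

    for it in range(n_total):
        alpha_fwd = kappa * np.clip(v, _FRACTION_FLOOR, None)
        v_prop = rng.dirichlet(alpha_fwd)
        v_prop = np.clip(v_prop, _FRACTION_FLOOR, None)
        v_prop = v_prop / v_prop.sum()
        s0_prop = s0 * np.exp(config.s0_step * rng.standard_normal())

        alpha_rev = kappa * v_prop
        ll_prop = loglik(v_prop, s0_prop)
        # flat Dirichlet(1,..,1) prior on v; flat positive prior on S0 with
        # log-normal random-walk Jacobian s0'/s0
        log_ratio = (
            ll_prop
            - ll
            + _dirichlet_logpdf(v, alpha_rev)
            - _dirichlet_logpdf(v_prop, alpha_fwd)
            + np.log(s0_prop / s0)
        )
        if np.log(rng.uniform()) < log_ratio:
            v, s0, ll = v_prop, s0_prop, ll_prop
            if it >= config.n_burn:
                n_accept += 1
        post = it - config.n_burn
        if post >= 0 and post % stride == stride - 1 and n_kept < config.n_keep:
            kept[n_kept] = v
            kept_s0[n_kept] = s0
            n_kept += 1

    return PosteriorSamples(
        samples=kept[:n_kept],
        s0_samples=kept_s0[:n_kept],
        acceptance_rate=n_accept / max(config.n_run, 1),
        basis=basis,
        config=config,
        noise_sd=sigma,
    )


def posterior_report(samples: PosteriorSamples, n_bins: int = 50) -> dict:
    """Per-compartment posterior mean ± SD plus histogram data.

    The summary mirrors the group-level myelin-density readout: the posterior
    over the shortest-T2 fraction is the myelin water fraction distribution.
    """
    if samples.samples.shape[0] == 0:
        raise ValueError("empty posterior sample set")
    draws = samples.samples
    n = draws.shape[0]
    report: dict = {
        "n_samples": int(n),
        "acceptance_rate": float(samples.acceptance_rate),
        "noise_sd": float(samples.noise_sd),
        "compartments": {},
    }
    for i, name in enumerate(samples.basis.names):
        x = draws[:, i]
        counts, edges = np.histogram(x, bins=n_bins)
        report["compartments"][name] = {
            "t2_ms": float(samples.basis.t2_values[i]),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if n > 1 else 0.0,
            "histogram_counts": counts.tolist(),
            "histogram_edges": edges.tolist(),
        }
    return report
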