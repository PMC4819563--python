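import numpy as np
import pytest

from relaxo.signal_models import DEFAULT_BASIS, DEFAULT_ECHO_TIMES_MS


@pytest.fixture(scope="session")
def echo_times():
    """The ten-echo acquisition grid (ms) the pipeline is designed around."""
    return np.asarray(DEFAULT_ECHO_TIMES_MS)


@pytest.fixture(scope="session")
def basis():
    """The literature three-compartment basis [20, 80, 2000] ms."""
    return DEFAULT_BASIS


@pytest.fixture(scope="session")
def cohort_run():
    """One full default synthetic cohort pushed through the pipeline.

    Session-scoped: the cohort recovery checks and report assertions share
    this single run (seed 1, SNR 150, desk-scale grid).
    """
    from relaxo.pipeline import run_cohort_analysis
    from relaxo.synthetic_cohort import default_cohort_spec

    spec = default_cohort_spec(seed=1)
    return spec, run_cohort_analysis(spec)


def grid_search_t2(echo_times, signals, t2_lo=1.0, t2_hi=500.0, resolution=0.001):
    """Brute-force T2 minimizer of the original-space SSE, profiling S0.

    For fixed T2 the optimal amplitude is the closed-form projection
    S0*(T2) = <S, e> / <e, e>, so the search is a dense 1-D scan over T2
    refined to ``resolution`` — an oracle independent of the Gauss-Newton
    path.
    """

    def best(grid):
        E = np.exp(-echo_times[None, :] / grid[:, None])
        num = E @ signals
        den = np.einsum("ij,ij->i", E, E)
        sse = signals @ signals - num**2 / den
        return grid[int(np.argmin(sse))]

    coarse = best(np.arange(t2_lo, t2_hi, 0.1))
    fine = best(np.arange(max(coarse - 0.2, 1e-3), coarse + 0.2, resolution))
    return fine


def simplex_grid_fractions(echo_times, signals, basis, resolution=0.001):
    """Dense simplex-grid least-squares oracle for the 3-compartment fit.

    Scans (v1, v2) on a grid of the given resolution (v3 = 1 - v1 - v2),
    profiling the amplitude in closed form, and returns the SSE-minimizing
    fraction vector.  Independent of the NNLS implementation.
    """
    steps = int(round(1.0 / resolution))
    v1 = np.repeat(np.arange(steps + 1), steps + 1)
    v2 = np.tile(np.arange(steps + 1), steps + 1)
    keep = v1 + v2 <= steps
    V = np.column_stack([v1[keep], v2[keep], steps - v1[keep] - v2[keep]]) * resolution
    A = basis.design_matrix(echo_times)
    M = V @ A.T  # (n_points, n_echoes)
    num = M @ signals
    den = np.einsum("ij,ij->i", M, M)
    den[den == 0] = np.inf
    sse = signals @ signals - np.maximum(num, 0.0) ** 2 / den
    return V[int(np.argmin(sse))]
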