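"""Forward models for transverse (T2) relaxation decay.

Two models are provided:

* a mono-exponential decay ``S(TE) = S0 * exp(-TE / T2)``, appropriate when a
  voxel is treated as a single homogeneous compartment, and
* a multi-compartment decay ``S(TE) = S0 * sum_i v_i * exp(-TE / T2_i)`` in
  which the signal is a convex mixture of exponentials with fixed, known time
  constants ``T2_i`` and non-negative volume fractions ``v_i`` summing to one.

All times (TE, T2) are in milliseconds; amplitudes are in arbitrary scanner
units.  These functions are deterministic and noise-free — measurement noise
is the business of the synthetic cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_ECHO_TIMES_MS",
    "DEFAULT_BASIS",
    "EchoSeries",
    "CompartmentBasis",
    "FractionVector",
    "predict_mono",
    "predict_multi",
]

#: Echo times (ms) of the ten-echo acquisition the pipeline is designed around.
DEFAULT_ECHO_TIMES_MS: tuple[float, ...] = (13.0, 16.0, 20.0, 25.0, 30.0, 40.0, 50.0, 85.0, 100.0, 150.0)

#: Simplex tolerance for fraction vectors.
_SIMPLEX_TOL = 1e-9


def _validate_echo_times(echo_times: np.ndarray) -> np.ndarray:
    te = np.asarray(echo_times, dtype=float)
    if te.ndim != 1 or te.size < 1:
        raise ValueError("echo_times must be a 1-D sequence")
    if np.any(te <= 0):
        raise ValueError("echo times must be strictly positive")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    return te


@dataclass(frozen=True)
class EchoSeries:
    """One decay curve: echo times (ms) paired with signal intensities.

    Invariants: at least two echoes, echo times strictly increasing and
    positive, one signal per echo.
    """

    echo_times: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        te = _validate_echo_times(self.echo_times)
        sig = np.asarray(self.signals, dtype=float)
        if te.size < 2:
            raise ValueError("an EchoSeries needs at least two echoes")
        if sig.shape != te.shape:
            raise ValueError("signals and echo_times must have the same length")
        object.__setattr__(self, "echo_times", te)
        object.__setattr__(self, "signals", sig)

    def __len__(self) -> int:
        return int(self.echo_times.size)


@dataclass(frozen=True)
class CompartmentBasis:
    """Fixed set of compartment T2 constants (ms) with human-readable labels.

    The default three-point basis [20, 80, 2000] ms encodes myelin water,
    intra/extra-cellular tissue water, and free water (CSF).  The fraction at
    the shortest T2 is the myelin water fraction (MWF).
    """

    t2_values: np.ndarray = field(default_factory=lambda: np.array([20.0, 80.0, 2000.0]))
    names: tuple[str, ...] = ("myelin_water", "tissue_water", "free_water")

    def __post_init__(self) -> None:
        t2 = np.asarray(self.t2_values, dtype=float)
        if t2.ndim != 1 or t2.size < 1:
            raise ValueError("t2_values must be a 1-D sequence")
        if np.any(t2 <= 0):
            raise ValueError("basis T2 values must be positive")
        if np.any(np.diff(t2) <= 0):
            raise ValueError("basis T2 values must be strictly increasing (no duplicates)")
        names = tuple(self.names)[: t2.size]
        if len(names) != t2.size:
            names = tuple(f"t2_{v:g}ms" for v in t2)
        object.__setattr__(self, "t2_values", t2)
        object.__setattr__(self, "names", names)

    @property
    def n_compartments(self) -> int:
        return int(self.t2_values.size)

    @property
    def shortest_index(self) -> int:
        """Index of the shortest-T2 (myelin water) compartment."""
        return 0

    def design_matrix(self, echo_times: np.ndarray) -> np.ndarray:
        """Exponential design matrix A[j, i] = exp(-TE_j / T2_i)."""
        te = _validate_echo_times(echo_times)
        return np.exp(-te[:, None] / self.t2_values[None, :])


#: The literature three-compartment basis used throughout the pipeline.
DEFAULT_BASIS = CompartmentBasis()


@dataclass(frozen=True)
class FractionVector:
    """Compartment volume fractions on the probability simplex.

    Every fraction is non-negative and the fractions sum to one (within
    1e-9), mirroring the constraints v_i >= 0 and sum(v_i) = 1 of the
    multi-compartment model.
    """

    fractions: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.fractions, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("fractions must be a 1-D sequence")
        if np.any(v < 0):
            raise ValueError("fractions must be non-negative")
        if abs(v.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"fractions must sum to 1 (got {v.sum()!r})")
        object.__setattr__(self, "fractions", v)

    def __len__(self) -> int:
        return int(self.fractions.size)


def predict_mono(s0: float, t2: float, echo_times) -> np.ndarray:
    """Mono-exponential decay S(TE) = S0 * exp(-TE / T2).

    Parameters
    ----------
    s0 : float
        Signal amplitude at TE = 0 (arbitrary units, >= 0).
    t2 : float
        Transverse relaxation time in ms (> 0).
    echo_times : array-like
        Strictly increasing, positive echo times in ms.
    """
    te = _validate_echo_times(echo_times)
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    if t2 <= 0:
        raise ValueError("t2 must be strictly positive")
    return s0 * np.exp(-te / t2)


def predict_multi(s0: float, fractions, basis: CompartmentBasis, echo_times) -> np.ndarray:
    """Multi-compartment decay S(TE) = S0 * sum_i v_i * exp(-TE / T2_i).

    ``fractions`` may be a :class:`FractionVector` or a plain sequence, in
    which case simplex validity is enforced here.  With a one-hot fraction
    vector this reduces exactly to :func:`predict_mono` at the corresponding
    basis T2.
    """
    te = _validate_echo_times(echo_times)
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    if not isinstance(fractions, FractionVector):
        fractions = FractionVector(np.asarray(fractions, dtype=float))
    v = fractions.fractions
    if v.size != basis.n_compartments:
        raise ValueError("fraction vector length must match the basis")
    return s0 * (basis.design_matrix(te) @ v)
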