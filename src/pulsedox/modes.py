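"""Fourier-mode bookkeeping and the planar-geometry theory.

A periodic vessel-wall oxygen signal Φ(t) with fundamental angular
frequency ω is expanded as Φ(t) = Σ_n c_n e^{inωt}; since Φ is real the
n < 0 coefficients are the conjugates of the n > 0 ones and are never
stored.  Each retained harmonic is a :class:`FourierMode`.

In a half-space fed through the plane x = 0, every mode decays as
exp(−s_n x) with the complex decay rate

    s_n = sqrt((γ + iω_n) / D),   Re(s_n) > 0,

so the mode's amplitude falls off exponentially with the
frequency-dependent decay length λ_n = 1/Re(s_n) = sqrt(2D/(γ +
sqrt(γ² + ω_n²))).  The decay-length curve is flat for ω_n ≪ γ (where
λ ≈ sqrt(D/γ)) and follows the power law sqrt(2D/ω_n) for ω_n ≫ γ; the
consumption rate γ marks the transition between the two regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InfiniteDecayLengthError",
    "ComplexDecayRate",
    "FourierMode",
    "BoundarySignal",
    "RadialProfile",
    "decay_rate",
    "planar_mode_profile",
    "decay_length_curve",
    "reconstruct_time_series",
]


class InfiniteDecayLengthError(ValueError):
    """Raised for γ = ω_n = 0, where the mode does not decay at all.

    The degenerate constant mode would give an infinite decay length and
    silently poison downstream root-finding, so it is rejected outright.
    """


@dataclass(frozen=True)
class ComplexDecayRate:
    """The mode-dependent complex rate s_n, in 1/μm."""

    s: complex

    @property
    def decay_length(self) -> float:
        """Planar decay length λ_n = 1/Re(s_n), μm."""
        return 1.0 / self.s.real


@dataclass(frozen=True)
class FourierMode:
    """One harmonic of the boundary oxygen signal.

    ``omega_n`` is the angular frequency nω in rad/s and ``amplitude``
    the complex boundary coefficient at the vessel wall (or x = 0).
    """

    n: int
    omega_n: float
    amplitude: complex = 1.0 + 0.0j

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("negative harmonics are implied by conjugation, not stored")
        if self.omega_n < 0:
            raise ValueError("omega_n must be non-negative")
        if self.n == 0 and self.omega_n != 0.0:
            raise ValueError("the n = 0 mode is the constant term: omega_0 = 0")


@dataclass(frozen=True)
class BoundarySignal:
    """A periodic vessel-wall signal as its non-negative Fourier modes."""

    fundamental_omega: float
    modes: tuple

    def __post_init__(self) -> None:
        if self.fundamental_omega <= 0:
            raise ValueError("fundamental_omega must be positive")
        object.__setattr__(self, "modes", tuple(self.modes))
        seen = set()
        for m in self.modes:
            if m.n in seen:
                raise ValueError(f"duplicate harmonic n={m.n}")
            seen.add(m.n)
            expected = m.n * self.fundamental_omega
            if not np.isclose(m.omega_n, expected, rtol=1e-12, atol=1e-15):
                raise ValueError(
                    f"mode n={m.n} has omega_n={m.omega_n}, expected n*omega={expected}"
                )
        for m in self.modes:
            if m.n == 0 and abs(m.amplitude.imag) > 1e-12 * max(1.0, abs(m.amplitude)):
                raise ValueError("the constant term of a real signal must be real")

    @property
    def period(self) -> float:
        """Fundamental period 2π/ω, s."""
        return 2.0 * np.pi / self.fundamental_omega

    @property
    def mean(self) -> float:
        """Time average of the signal = the n = 0 amplitude."""
        for m in self.modes:
            if m.n == 0:
                return float(np.real(m.amplitude))
        return 0.0

    def reconstruct(self, t) -> np.ndarray:
        """Evaluate the real time series on ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for m in self.modes:
            if m.n == 0:
                out = out + np.real(m.amplitude)
            else:
                out = out + 2.0 * np.real(m.amplitude * np.exp(1j * m.omega_n * t))
        return out


@dataclass
class RadialProfile:
    """Complex mode amplitude ϕ_n(r) on a radial grid starting at the wall.

    ``r_grid`` holds strictly increasing distances from the vessel axis
    with ``r_grid[0] = R``.  When ``normalized`` the stored values are
    ϕ_n(r)/ϕ_n(R), so ``values[0] == 1``.  Solver outputs also carry a
    continuous ``evaluator`` (r → complex ratio) used for root refinement
    beyond the grid resolution.
    """

    r_grid: np.ndarray
    values: np.ndarray
    mode: FourierMode
    normalized: bool = True
    evaluator: Optional[Callable[[float], complex]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.r_grid.ndim != 1 or self.r_grid.size < 1:
            raise ValueError("r_grid must be a non-empty 1-D array")
        if np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r_grid must be strictly increasing")
        if self.values.shape != self.r_grid.shape:
            raise ValueError("values and r_grid must have matching shapes")
        if self.normalized and not np.isclose(abs(self.values[0]), 1.0, rtol=1e-9):
            raise ValueError("normalized profile must have |values[0]| = 1")

    @property
    def abs_values(self) -> np.ndarray:
        return np.abs(self.values)

    def value_at(self, r: float) -> complex:
        """Value at radius ``r``: exact grid hit or continuous evaluator."""
        idx = np.flatnonzero(np.isclose(self.r_grid, r, rtol=1e-12, atol=1e-9))
        if idx.size:
            return complex(self.values[idx[0]])
        if self.evaluator is not None:
            return complex(self.evaluator(r))
        raise ValueError(f"r={r} not on the grid and no continuous evaluator available")


def decay_rate(gamma: float, omega_n: float, D: float) -> ComplexDecayRate:
    """Complex decay rate s_n = sqrt((γ + iω_n)/D), principal branch.

    Parameters are the consumption rate γ (1/s), angular frequency ω_n
    (rad/s) and diffusion coefficient D (μm²/s).  With γ, ω_n ≥ 0 the
    principal square root automatically has Re(s) > 0, which the planar
    boundedness condition requires; this is asserted rather than
    re-derived.

    Raises
    ------
    InfiniteDecayLengthError
        If γ = ω_n = 0 (no decay at all).
    """
    if gamma < 0 or omega_n < 0:
        raise ValueError("gamma and omega_n must be non-negative")
    if D <= 0:
        raise ValueError("D must be positive")
    if gamma == 0.0 and omega_n == 0.0:
        raise InfiniteDecayLengthError(
            "gamma = omega_n = 0 gives an infinite decay length; "
            "the constant mode is not representable as a decaying one"
        )
    s = complex(np.sqrt(complex(gamma, omega_n) / D))
    assert s.real > 0.0
    return ComplexDecayRate(s=s)


def planar_mode_profile(x: float, mode: FourierMode, gamma: float, D: float) -> complex:
    """Planar half-space solution ϕ_n(x) = ϕ_n(0)·exp(−s_n x) for x ≥ 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("the planar solution lives in the half-space x >= 0")
    s = decay_rate(gamma, mode.omega_n, D).s
    out = mode.amplitude * np.exp(-s * x)
    return complex(out) if out.ndim == 0 else out


def decay_length_curve(gamma: float, D: float, omega_grid: Sequence[float]) -> pd.DataFrame:
    """Decay length versus frequency for fixed γ and D.

    Returns a DataFrame with columns ``omega_over_gamma``,
    ``decay_length_um`` and ``decay_length_normalized`` (normalized to
    the stationary value sqrt(D/γ)).  The curve is monotonically
    non-increasing: essentially flat below ω ≈ γ and proportional to
    ω^(−1/2) far above it.
    """
    if gamma <= 0:
        raise ValueError("decay_length_curve requires gamma > 0 for normalization")
    omega_grid = np.asarray(omega_grid, dtype=float)
    if omega_grid.ndim != 1 or np.any(omega_grid <= 0):
        raise ValueError("omega_grid must be a 1-D array of positive frequencies")
    if np.any(np.diff(omega_grid) <= 0):
        raise ValueError("omega_grid must be sorted increasing")
    lengths = np.array([decay_rate(gamma, w, D).decay_length for w in omega_grid])
    lam0 = np.sqrt(D / gamma)
    return pd.DataFrame(
        {
            "omega_over_gamma": omega_grid / gamma,
            "decay_length_um": lengths,
            "decay_length_normalized": lengths / lam0,
        }
    )


def reconstruct_time_series(
    signal: BoundarySignal,
    profiles: Sequence[RadialProfile],
    r: float,
    t_grid: Sequence[float],
) -> np.ndarray:
    """Superpose the modes at radius ``r`` into the real series Φ(r, t).

    Each mode contributes ϕ_n(r)·e^{inωt} plus its conjugate; the time
    average over one period equals the n = 0 profile value at ``r``.  The
    imaginary part of the superposition is checked to be at round-off
    level and then discarded.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    by_n = {p.mode.n: p for p in profiles}
    if len(by_n) != len(profiles):
        raise ValueError("profiles must belong to distinct harmonics")
    if {m.n for m in signal.modes} != set(by_n):
        raise ValueError("need exactly one profile per mode of the signal")

    series = np.zeros(t_grid.shape, dtype=complex)
    for m in signal.modes:
        prof = by_n[m.n]
        phi = prof.value_at(r)
        if prof.normalized:
            phi = phi * m.amplitude
        if m.n == 0:
            series = series + phi
        else:
            series = series + phi * np.exp(1j * m.omega_n * t_grid)
            series = series + np.conj(phi) * np.exp(-1j * m.omega_n * t_grid)

    scale = np.max(np.abs(series.real)) or 1.0
    if np.max(np.abs(series.imag)) > 1e-10 * scale:
        raise AssertionError("reconstructed series is not real to round-off")
    return series.real
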