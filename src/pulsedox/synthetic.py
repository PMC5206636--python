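"""Synthetic inputs: pulsatile vessel-wall signals and pseudo-measurements.

The "bursting" oxygen inflow regime — widely separated reoxygenation
events — is emulated by a rectangular pulse train, chosen because its
Fourier coefficients are available in closed form and therefore exactly
testable: for a pulse of height ``amplitude`` on a fraction
``duty_cycle`` of each period on top of ``baseline``,

    c₀ = baseline + amplitude·d,
    |c_n| = amplitude·d·|sinc(n·d)|,   sinc(x) = sin(πx)/(πx),

with d the duty cycle.  Small d realizes the bursting regime: the
constant term c₀ = amplitude·d is small against the lowest harmonics
(|c₁| ≈ amplitude·d), matching the observation that at depth such
signals are well represented by the first-harmonic modulus.

Noisy pO₂-vs-distance pseudo-measurement sets (Gaussian noise around the
model's time-averaged profile, clipped at zero, 15 replicates per
distance with s.e.m. error bars by default) close the pipeline
end-to-end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .modes import BoundarySignal, FourierMode
from .parameters import MediumParameters
from .solvers import cord_mode_profile, cylindrical_mode_profile

__all__ = [
    "BurstSignalSpec",
    "PseudoMeasurementSet",
    "burst_signal_fourier",
    "sample_time_series",
    "generate_pseudo_profile",
    "estimate_half_distance",
    "bootstrap_half_distance",
]


@dataclass(frozen=True)
class BurstSignalSpec:
    """A rectangular reoxygenation pulse train, in normalized pO₂ units."""

    period: float                 # s
    duty_cycle: float             # fraction of the period spent "on", (0, 1]
    amplitude: float = 1.0
    baseline: float = 0.0
    n_harmonics: int = 10

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not (0.0 < self.duty_cycle <= 1.0):
            raise ValueError("duty_cycle must lie in (0, 1]")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("amplitude and baseline must be non-negative")


@dataclass
class PseudoMeasurementSet:
    """Noisy replicate pO₂ ratios per distance, with s.e.m. error bars."""

    distances: np.ndarray     # μm, from the vessel wall
    replicates: int
    mean_ratio: np.ndarray
    sem: np.ndarray
    seed: Optional[int]
    samples: np.ndarray       # (n_distances, replicates) raw draws

    def to_frame(self) -> pd.DataFrame:
        """The CSV dialect the comparison overlay reads."""
        return pd.DataFrame(
            {"distance_um": self.distances, "po2_norm": self.mean_ratio,
             "sem": self.sem}
        )


def burst_signal_fourier(spec: BurstSignalSpec) -> BoundarySignal:
    """Exact Fourier coefficients of the pulse train, truncated.

    The pulse is centred on t = 0, so all coefficients are real.  The
    truncated AC power (the Parseval deficit of the dropped harmonics)
    is stored on the returned signal as ``truncation_energy``.
    """
    d = spec.duty_cycle
    omega = 2.0 * np.pi / spec.period
    c0 = spec.baseline + spec.amplitude * d
    modes = [FourierMode(n=0, omega_n=0.0, amplitude=complex(c0))]
    retained_ac = 0.0
    for n in range(1, spec.n_harmonics + 1):
        cn = spec.amplitude * d * np.sinc(n * d)
        modes.append(FourierMode(n=n, omega_n=n * omega, amplitude=complex(cn)))
        retained_ac += 2.0 * cn * cn
    total_ac = spec.amplitude**2 * d * (1.0 - d)
    signal = BoundarySignal(fundamental_omega=omega, modes=tuple(modes))
    # dataclass is frozen; attach the bookkeeping value via object.__setattr__
    object.__setattr__(signal, "truncation_energy", max(total_ac - retained_ac, 0.0))
    return signal


def sample_time_series(
    signal: BoundarySignal,
    t_grid: Sequence[float],
    jitter_sd: float = 0.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Reconstruct the signal on ``t_grid``, optionally with Gaussian jitter."""
    series = signal.reconstruct(np.asarray(t_grid, dtype=float))
    if jitter_sd > 0.0:
        rng = np.random.default_rng(seed)
        series = series + rng.normal(0.0, jitter_sd, size=series.shape)
    return series


def _stationary_ratio(params: MediumParameters, r_grid: np.ndarray) -> np.ndarray:
    mode = FourierMode(n=0, omega_n=0.0)
    if params.uniform:
        return np.abs(cylindrical_mode_profile(params, mode, r_grid).values)
    return np.abs(cord_mode_profile(params, mode, r_grid).profile.values)


def generate_pseudo_profile(
    params: MediumParameters,
    signal: BoundarySignal,
    distances: Sequence[float],
    replicates: int = 15,
    noise_sd: float = 0.05,
    seed: Optional[int] = None,
) -> PseudoMeasurementSet:
    """Draw noisy replicate measurements around the model profile.

    ``distances`` are measured from the vessel wall.  The time-averaged
    normalized concentration at each distance equals the stationary-mode
    ratio (only the constant term survives the time average, and the
    wall normalization cancels its amplitude), so the signal must have a
    non-zero constant term.  Gaussian noise of standard deviation
    ``noise_sd`` is clipped at zero, since pO₂ ratios cannot be
    negative; the s.e.m. is the sample standard deviation over the
    replicates divided by sqrt(replicates).
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates for an s.e.m.")
    if signal.mean == 0.0:
        raise ValueError("signal has no constant term: time average is zero")
    distances = np.asarray(distances, dtype=float)
    if np.any(distances < 0):
        raise ValueError("distances from the wall must be non-negative")

    order = np.argsort(distances)
    r_grid = np.concatenate([[params.R], params.R + distances[order]])
    # deduplicate while keeping the wall point
    r_grid = np.unique(r_grid)
    model_at = dict(zip(r_grid, _stationary_ratio(params, r_grid)))
    model = np.array([model_at[params.R + d] for d in distances])

    rng = np.random.default_rng(seed)
    if noise_sd > 0.0:
        samples = rng.normal(model[:, None], noise_sd,
                             size=(distances.size, replicates))
        samples = np.clip(samples, 0.0, None)
    else:
        samples = np.tile(model[:, None], (1, replicates))
    mean = samples.mean(axis=1)
    sem = samples.std(axis=1, ddof=1) / np.sqrt(replicates)
    return PseudoMeasurementSet(
        distances=distances, replicates=replicates, mean_ratio=mean,
        sem=sem, seed=seed, samples=samples,
    )


def estimate_half_distance(distances, mean_ratio) -> float:
    """Distance from the wall where the measured ratio crosses 0.5.

    Monotone (PCHIP) interpolation of the mean profile; raises if the
    profile never crosses the half level.
    """
    distances = np.asarray(distances, dtype=float)
    mean_ratio = np.asarray(mean_ratio, dtype=float)
    order = np.argsort(distances)
    x, y = distances[order], mean_ratio[order]
    if not (y.max() > 0.5 > y.min()):
        raise ValueError("measured profile does not cross 0.5")
    interp = PchipInterpolator(x, y - 0.5)
    roots = interp.roots(extrapolate=False)
    if roots.size == 0:
        raise ValueError("no crossing found by interpolation")
    return float(roots[0])


def bootstrap_half_distance(
    measurements: PseudoMeasurementSet,
    n_boot: int = 200,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Point estimate and bootstrap s.e. of the measured half-distance.

    Resamples the replicates within each distance (with replacement),
    re-estimates the crossing per resample, and returns (estimate, s.e.).
    """
    est = estimate_half_distance(measurements.distances, measurements.mean_ratio)
    rng = np.random.default_rng(seed)
    n_d, n_rep = measurements.samples.shape
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_rep, size=(n_d, n_rep))
        means = np.take_along_axis(measurements.samples, idx, axis=1).mean(axis=1)
        try:
            boot.append(estimate_half_distance(measurements.distances, means))
        except ValueError:
            continue
    if len(boot) < n_boot // 2:
        raise RuntimeError("bootstrap failed to locate the crossing in most resamples")
    return est, float(np.std(boot, ddof=1))
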