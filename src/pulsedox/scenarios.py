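"""Oxygenation scenario classes, the fixed-parameter prediction band, and
robustness sweeps.

Five qualitative classes of tumour oxygenation are encoded as forward-model
presets (no fitting anywhere):

1. compact tissue, low consumption, quasi-regular flow — uniform-γ solver;
2. compact tissue, medium/high consumption, quasi-regular flow — uniform-γ;
3. tumour cords, high consumption, quasi-regular flow — cord solver;
4. compact tissue, low consumption, bursting flow — uniform-γ, with the
   first-harmonic modulus as the representative signal;
5. tumour cords, low consumption with necrosis, bursting flow — cord
   solver, first-harmonic modulus at the band-edge frequencies.

"Bursting" oxygen flow means widely separated reoxygenation events: the
constant Fourier term is small compared with the lowest harmonics, so the
signal at depth is well represented by the modulus of the first harmonic,
evaluated at the limiting pathophysiological frequencies 0.01 and 0.1 Hz
(the band observed in tumour microcirculation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .modes import FourierMode
from .parameters import MediumParameters
from .solvers import cord_mode_profile, cylindrical_mode_profile, RadialProfile

__all__ = [
    "ScenarioSpec",
    "SCENARIO_PRESETS",
    "scenario_profile",
    "fig7_prediction",
    "robustness_sweep",
    "BAND_FREQS_HZ",
    "GAMMA_IN_VIVO_LOW",
    "GAMMA_IN_VIVO_MEAN",
    "GAMMA_IN_VIVO_HIGH",
]

# in-vivo oxygen consumption rates, 1/s
GAMMA_IN_VIVO_LOW = 1.66e-4
GAMMA_IN_VIVO_MEAN = 2.16e-3
GAMMA_IN_VIVO_HIGH = 5e-3

# limiting frequencies of the observed low-frequency oxygen oscillations, Hz
BAND_FREQS_HZ = (0.01, 0.1)

_D_DEFAULT = 2000.0      # μm²/s, oxygen in tissue
_R_MEDIAN = 22.5         # μm, median vessel radius of the comparison dataset
_LAMBDA_C = 120.0        # μm, cord consumption decay length


@dataclass(frozen=True)
class ScenarioSpec:
    """A named oxygenation class with its solver and parameter preset."""

    class_id: int
    tissue: str            # compact | cords
    consumption: str       # low | medium_high | high
    flow: str              # quasi_regular | bursting
    solver: str            # bessel_uniform | cord_log_integral
    params: MediumParameters
    frequencies_hz: tuple  # () for stationary; band edges for bursting

    def __post_init__(self) -> None:
        if self.class_id not in (1, 2, 3, 4, 5):
            raise ValueError(f"unknown scenario class {self.class_id}")
        if self.solver not in ("bessel_uniform", "cord_log_integral"):
            raise ValueError(f"unknown solver {self.solver}")


SCENARIO_PRESETS: Dict[int, ScenarioSpec] = {
    1: ScenarioSpec(
        1, "compact", "low", "quasi_regular", "bessel_uniform",
        MediumParameters(D=_D_DEFAULT, gamma0=GAMMA_IN_VIVO_LOW, R=_R_MEDIAN),
        (),
    ),
    2: ScenarioSpec(
        2, "compact", "medium_high", "quasi_regular", "bessel_uniform",
        MediumParameters(D=_D_DEFAULT, gamma0=GAMMA_IN_VIVO_MEAN, R=_R_MEDIAN),
        (),
    ),
    3: ScenarioSpec(
        3, "cords", "high", "quasi_regular", "cord_log_integral",
        MediumParameters(D=_D_DEFAULT, gamma0=0.0, gammaC=GAMMA_IN_VIVO_MEAN,
                         lambdaC=_LAMBDA_C, R=_R_MEDIAN),
        (),
    ),
    4: ScenarioSpec(
        4, "compact", "low", "bursting", "bessel_uniform",
        MediumParameters(D=_D_DEFAULT, gamma0=GAMMA_IN_VIVO_LOW, R=_R_MEDIAN),
        BAND_FREQS_HZ,
    ),
    5: ScenarioSpec(
        5, "cords", "low", "bursting", "cord_log_integral",
        MediumParameters(D=_D_DEFAULT, gamma0=0.0, gammaC=GAMMA_IN_VIVO_MEAN,
                         lambdaC=_LAMBDA_C, R=_R_MEDIAN),
        BAND_FREQS_HZ,
    ),
}


def _modes_for(spec: ScenarioSpec) -> List[FourierMode]:
    if not spec.frequencies_hz:
        return [FourierMode(n=0, omega_n=0.0)]
    # bursting: the representative signal is the first-harmonic modulus,
    # evaluated at each band-edge frequency as its own fundamental
    return [FourierMode(n=1, omega_n=2.0 * np.pi * f) for f in spec.frequencies_hz]


def scenario_profile(spec: ScenarioSpec, r_grid) -> List[RadialProfile]:
    """Solve the class's preset: one normalized profile per mode."""
    if spec.class_id not in SCENARIO_PRESETS:
        raise ValueError(f"unknown scenario class {spec.class_id}")
    profiles = []
    for mode in _modes_for(spec):
        if spec.solver == "bessel_uniform":
            profiles.append(cylindrical_mode_profile(spec.params, mode, r_grid))
        else:
            profiles.append(cord_mode_profile(spec.params, mode, r_grid).profile)
    return profiles


def _band_curves(params: MediumParameters, r_grid) -> Dict[str, np.ndarray]:
    """|ϕ₁(r)/ϕ₁(R)| at the band-edge frequencies plus the stationary cord."""
    out = {}
    for f, name in zip(BAND_FREQS_HZ, ("upper", "lower")):
        mode = FourierMode(n=1, omega_n=2.0 * np.pi * f)
        out[name] = np.abs(cord_mode_profile(params, mode, r_grid).profile.values)
    out["stationary_cord"] = np.abs(
        cord_mode_profile(params, FourierMode(n=0, omega_n=0.0), r_grid).profile.values
    )
    return out


def fig7_prediction(
    params: MediumParameters | None = None, r_grid=None
) -> pd.DataFrame:
    """Parameter-free prediction band for the median-radius vessel.

    Columns: ``r_um``, ``upper`` (0.01 Hz), ``lower`` (0.1 Hz),
    ``stationary_cord`` and ``stationary_fixed`` (uniform γ = γ₀ + γ_c).
    All four are 1 at the wall; the band is ordered upper ≥ lower and
    lies below the stationary cord curve.
    """
    if params is None:
        params = MediumParameters(
            D=_D_DEFAULT, gamma0=0.0, gammaC=GAMMA_IN_VIVO_MEAN,
            lambdaC=_LAMBDA_C, R=_R_MEDIAN,
        )
    if r_grid is None:
        r_grid = np.linspace(params.R, params.R + 400.0, 81)
    r_grid = np.asarray(r_grid, dtype=float)

    curves = _band_curves(params, r_grid)
    fixed = MediumParameters(D=params.D, gamma0=params.gamma0 + params.gammaC,
                             R=params.R)
    stationary_fixed = np.abs(
        cylindrical_mode_profile(fixed, FourierMode(n=0, omega_n=0.0), r_grid).values
    )
    return pd.DataFrame(
        {
            "r_um": r_grid,
            "upper": curves["upper"],
            "lower": curves["lower"],
            "stationary_cord": curves["stationary_cord"],
            "stationary_fixed": stationary_fixed,
        }
    )


def robustness_sweep(
    base: MediumParameters,
    axis: str,
    values: Sequence[float],
    r_grid=None,
) -> tuple[Dict[float, pd.DataFrame], pd.DataFrame]:
    """Re-compute the prediction band under parameter changes.

    ``axis`` is ``"D"`` (diffusion coefficient, μm²/s) or ``"gamma"``
    (wall consumption rate γ_c, 1/s).  Returns the banded table per value
    and a summary with the maximum vertical displacement (relative to the
    base parameters) of the band edges and of the stationary cord curve.
    The oscillating band is expected to move far less than the stationary
    solution under the same sweep.
    """
    if axis not in ("D", "gamma"):
        raise ValueError("axis must be 'D' or 'gamma'")
    if r_grid is None:
        r_grid = np.linspace(base.R, base.R + 400.0, 41)
    r_grid = np.asarray(r_grid, dtype=float)

    base_curves = _band_curves(base, r_grid)
    tables: Dict[float, pd.DataFrame] = {}
    rows = []
    for v in values:
        p = base.with_(D=v) if axis == "D" else base.with_(gammaC=v)
        curves = _band_curves(p, r_grid)
        tables[v] = pd.DataFrame({"r_um": r_grid, **curves})
        band_shift = max(
            float(np.max(np.abs(curves[k] - base_curves[k])))
            for k in ("upper", "lower")
        )
        stat_shift = float(
            np.max(np.abs(curves["stationary_cord"] - base_curves["stationary_cord"]))
        )
        rows.append(
            {"axis": axis, "value": v,
             "band_displacement": band_shift,
             "stationary_displacement": stat_shift}
        )
    return tables, pd.DataFrame(rows)
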