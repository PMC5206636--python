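"""Physical parameters of the vessel/tissue system and config handling.

All internal quantities use micrometre/second units: lengths in μm, times
in s, diffusion coefficients in μm²/s, consumption rates in 1/s.  The
literature value D = 2×10⁻⁹ m²/s is therefore stored as 2000 μm²/s.
Unit conversion happens only at the config boundary (:func:`load_config`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "MediumParameters",
    "CordConsumptionProfile",
    "load_config",
]


@dataclass(frozen=True)
class MediumParameters:
    """Physical constants of the tissue/vessel system.

    Parameters
    ----------
    D : float
        Oxygen diffusion coefficient, μm²/s.  Typical interstitium value
        2000 μm²/s; pure water is about 3200 μm²/s.
    gamma0 : float
        Baseline (far-field) oxygen consumption rate γ₀, 1/s.
    gammaC : float
        Excess consumption rate at the vessel wall γ_c, 1/s.  The local
        rate decays from ``gamma0 + gammaC`` at the wall towards
        ``gamma0`` with length scale ``lambdaC``.  ``gammaC = 0`` is the
        uniform-consumption (compact tissue) configuration.
    lambdaC : float
        Decay length of the consumption-rate reduction λ_c, μm.  The
        in-vivo estimate for tumour cords is 120 μm.
    R : float
        Blood-vessel radius, μm.
    """

    D: float
    gamma0: float = 0.0
    gammaC: float = 0.0
    lambdaC: float = 120.0
    R: float = 2.5

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if self.gamma0 < 0:
            raise ValueError(f"gamma0 must be non-negative, got {self.gamma0}")
        if self.gammaC < 0:
            raise ValueError(f"gammaC must be non-negative, got {self.gammaC}")
        if not self.lambdaC > 0:
            raise ValueError(f"lambdaC must be positive, got {self.lambdaC}")
        if not self.R > 0:
            raise ValueError(f"R must be positive, got {self.R}")

    @property
    def uniform(self) -> bool:
        """True when consumption does not depend on position (γ_c = 0)."""
        return self.gammaC == 0.0

    def consumption(self, r):
        """Local consumption rate γ(r) = γ₀ + γ_c·exp(−(r−R)/λ_c), r ≥ R."""
        r = np.asarray(r, dtype=float)
        if np.any(r < self.R):
            raise ValueError("consumption rate is defined for r >= R only")
        return self.gamma0 + self.gammaC * np.exp(-(r - self.R) / self.lambdaC)

    def with_(self, **kwargs) -> "MediumParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


class CordConsumptionProfile:
    """Radially decaying consumption rate of a tumour cord.

    Callable wrapper around :meth:`MediumParameters.consumption`; the rate
    equals γ₀ + γ_c at the vessel wall, decreases strictly when γ_c > 0
    and tends to γ₀ far from the vessel.
    """

    def __init__(self, params: MediumParameters):
        self.params = params

    def __call__(self, r):
        return self.params.consumption(r)


_SI_LENGTH = 1e6      # m  -> μm
_SI_DIFFUSION = 1e12  # m²/s -> μm²/s


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration and normalize units.

    The file must carry an explicit ``units`` key, either ``"um"``
    (lengths in μm, D in μm²/s — the internal convention) or ``"si"``
    (lengths in m, D in m²/s).  Frequencies are always given in Hz under
    ``frequencies_hz`` and converted to angular frequencies in rad/s.

    Returns a dict with keys ``params`` (:class:`MediumParameters`),
    ``omegas`` (list of rad/s) and ``raw`` (the parsed file).
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)

    units = raw.get("units")
    if units not in ("um", "si"):
        raise ValueError(f"config must declare units: 'um' or 'si', got {units!r}")

    med = dict(raw.get("medium", {}))
    if units == "si":
        for key in ("lambdaC", "R"):
            if key in med:
                med[key] = med[key] * _SI_LENGTH
        if "D" in med:
            med["D"] = med["D"] * _SI_DIFFUSION

    params = MediumParameters(**med)
    omegas = [2.0 * np.pi * f for f in raw.get("frequencies_hz", [])]
    return {"params": params, "omegas": omegas, "raw": raw}
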