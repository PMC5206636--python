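"""Run manifests, the reference-quantity acceptance harness, and data overlay.

There is deliberately no fitting anywhere in this package: the model
curves are parameter-free predictions, so measured profiles are only
ever *overlaid* on them (model interpolated to the data's distances,
never the other way round) and residuals reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .modes import FourierMode
from .parameters import MediumParameters
from .scenarios import GAMMA_IN_VIVO_LOW, GAMMA_IN_VIVO_HIGH
from .solvers import asymptotic_ratio, cord_mode_profile, half_distance

logger = logging.getLogger("pulsedox")

__all__ = [
    "RunManifest",
    "run_acceptance_suite",
    "overlay_comparison",
    "fig5_quantities",
]


@dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run's outputs."""

    command: str
    parameters: dict
    seed: Optional[int]
    solver_tolerances: dict
    version: str = __version__
    outputs: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        data.pop("version", None)
        version = __version__
        m = cls(**data)
        m.version = version
        return m


# Reference quantities for the stationary cord profiles, with
# the tolerances at which the harness reports pass/fail: half-value radius
# (μm, ±3) and large-radius plateau (±0.01) for the smallest and largest
# in-vivo consumption coefficients.
_REFERENCE_TARGETS = (
    ("t1", "half_distance_um", GAMMA_IN_VIVO_LOW, 118.0, 3.0),
    ("t2", "plateau", GAMMA_IN_VIVO_LOW, 0.25, 0.01),
    ("t3", "half_distance_um", GAMMA_IN_VIVO_HIGH, 48.0, 3.0),
    ("t4", "plateau", GAMMA_IN_VIVO_HIGH, 0.12, 0.01),
)


def fig5_quantities(gamma_c: float, D: float = 2000.0, R: float = 3.0,
                    lambda_c: float = 120.0) -> dict:
    """Half-value radius and large-radius plateau of a stationary cord.

    Solves the cord log-integral profile with γ₀ = 0 and the given wall
    consumption rate, then root-finds the radius where the normalized
    modulus equals 0.5 and evaluates the plateau by radius doubling.
    """
    params = MediumParameters(D=D, gamma0=0.0, gammaC=gamma_c,
                              lambdaC=lambda_c, R=R)
    mode = FourierMode(n=0, omega_n=0.0)
    r_grid = np.linspace(R, R + 400.0, 101)
    report = cord_mode_profile(params, mode, r_grid)
    half = half_distance(report.profile)
    plateau = asymptotic_ratio(params, mode)
    return {"half_distance_um": half, "plateau": plateau,
            "converged": report.converged}


def run_acceptance_suite(params_override: Optional[dict] = None) -> pd.DataFrame:
    """Recompute the reference quantities and compare at stated tolerances.

    Returns a table (target, quantity, computed, expected, tolerance,
    passed).  ``params_override`` (e.g. a perturbed D) exists for
    sensitivity checks of the harness itself.  A solver failure marks the
    target failed but the suite continues.
    """
    over = params_override or {}
    rows = []
    cache: dict = {}
    for target, quantity, gamma_c, expected, tol in _REFERENCE_TARGETS:
        key = gamma_c
        if key not in cache:
            try:
                cache[key] = fig5_quantities(
                    gamma_c,
                    D=over.get("D", 2000.0),
                    R=over.get("R", 3.0),
                    lambda_c=over.get("lambda_c", 120.0),
                )
            except Exception as exc:  # report, do not abort the suite
                logger.error("solver failure for gamma_c=%g: %s", gamma_c, exc)
                cache[key] = None
        got = cache[key]
        computed = None if got is None else got[quantity]
        passed = computed is not None and abs(computed - expected) <= tol
        rows.append(
            {"target": target, "quantity": quantity, "gamma_c": gamma_c,
             "computed": computed, "expected": expected, "tolerance": tol,
             "passed": bool(passed)}
        )
    return pd.DataFrame(rows)


def _read_measurements(source) -> pd.DataFrame:
    """Read and normalize a measurement CSV (distance_um, po2_norm[, sem])."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        try:
            df = pd.read_csv(source)
        except pd.errors.EmptyDataError:
            return pd.DataFrame(columns=["distance_um", "po2_norm", "sem"])
        except Exception as exc:
            raise ValueError(f"malformed measurement CSV {source}: {exc}") from exc
    required = {"distance_um", "po2_norm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"measurement table lacks column(s) {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    for col in ("distance_um", "po2_norm"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"non-numeric value in column {col!r}, row {bad[0]}")
        df[col] = pd.to_numeric(df[col])
    if df["distance_um"].duplicated().any():
        logger.info("duplicate distances in measurement table: averaging")
        agg = {"po2_norm": "mean"}
        if "sem" in df.columns:
            agg["sem"] = "mean"
        df = df.groupby("distance_um", as_index=False).agg(agg)
    return df.sort_values("distance_um").reset_index(drop=True)


def overlay_comparison(model: pd.DataFrame, measurements) -> pd.DataFrame:
    """Align a model profile table with measurements; no fitting.

    ``model`` must have columns ``distance_um`` and ``abs_ratio``.  The
    model is interpolated at the measurement distances (the data are
    never interpolated) and residuals = measured − model are emitted.
    An empty measurement table yields the model-only table with a
    warning logged.
    """
    for col in ("distance_um", "abs_ratio"):
        if col not in model.columns:
            raise ValueError(f"model table lacks column {col!r}")
    meas = _read_measurements(measurements)
    if meas.empty:
        logger.warning("empty measurement table: emitting model-only overlay")
        out = model[["distance_um", "abs_ratio"]].copy()
        out["po2_norm"] = np.nan
        out["residual"] = np.nan
        return out

    lo, hi = model["distance_um"].min(), model["distance_um"].max()
    if (meas["distance_um"] < lo - 1e-9).any() or (meas["distance_um"] > hi + 1e-9).any():
        raise ValueError("measurement distances fall outside the model grid")
    model_at = np.interp(meas["distance_um"], model["distance_um"], model["abs_ratio"])
    out = meas.copy()
    out["model_ratio"] = model_at
    out["residual"] = out["po2_norm"] - out["model_ratio"]
    return out
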