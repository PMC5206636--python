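"""Stable evaluation of modified Bessel K ratios at complex argument.

The cylindrical mode solutions are K₀(s_n r)/K₀(s_n R) with complex
s_n, and the cord log-integrand needs K₁(z)/K₀(z).  Naive evaluation
overflows/underflows for |z| beyond a few hundred, so everything is
routed through the exponentially scaled functions kve (K_ν(z)·e^z); the
exponential factors are recombined analytically, which keeps the ratio
finite by construction for |z| from 1e-6 to 1e3 and beyond.

An independent evaluation route based on the integral representation
K_ν(z) = ∫₀^∞ e^{−z·cosh t}·cosh(νt) dt (valid for Re z > 0) is provided
for cross-validation of the library route on the sector arg(z) ∈ [0, π/4]
that the model actually uses.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.special import kve

__all__ = [
    "k0_ratio",
    "k1k0_ratio",
    "kv_integral",
]


def k0_ratio(s: complex, r, R: float):
    """K₀(s·r)/K₀(s·R) evaluated without overflow, for r ≥ R > 0.

    Uses scaled Bessel functions: K₀(z) = kve(0, z)·e^{−z}, so the ratio
    is kve(0, s·r)/kve(0, s·R) · e^{−s·(r−R)}.  With Re(s) > 0 and r ≥ R
    the exponential only ever shrinks, so the result is finite and its
    modulus is ≤ 1 (equal to 1 at r = R).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < R):
        raise ValueError("k0_ratio is defined for r >= R")
    if not (R > 0):
        raise ValueError("R must be positive")
    if not (complex(s).real > 0):
        raise ValueError("s must have positive real part")
    out = kve(0, s * r) / kve(0, s * R) * np.exp(-s * (r - R))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite Bessel ratio")
    return complex(out) if out.ndim == 0 else out


def k1k0_ratio(z: complex) -> complex:
    """K₁(z)/K₀(z); the scaling of kve cancels exactly."""
    return kve(1, z) / kve(0, z)


def kv_integral(nu: int, z: complex, scaled: bool = False) -> complex:
    """K_ν(z) from the integral representation, Re(z) > 0.

    Independent of the AMOS library route; used to cross-validate K₀ and
    K₁ on the sector the solvers visit.  Integrates
    e^{−z(cosh t − 1)}·cosh(νt) adaptively and reattaches e^{−z} (or not,
    when ``scaled``), so moduli as small as e^{−700} are representable.
    """
    z = complex(z)
    if not z.real > 0:
        raise ValueError("integral representation requires Re(z) > 0")

    def integrand(t, part):
        val = np.exp(-z * (np.cosh(t) - 1.0)) * np.cosh(nu * t)
        return val.real if part == "re" else val.imag

    # e^{-|z|(cosh t - 1)} is negligible past cosh t ~ 1 + 700/|z|
    upper = np.arccosh(1.0 + 720.0 / abs(z))
    re, _ = quad(integrand, 0.0, upper, args=("re",), epsabs=1e-14, epsrel=1e-12, limit=400)
    im, _ = quad(integrand, 0.0, upper, args=("im",), epsabs=1e-14, epsrel=1e-12, limit=400)
    val = complex(re, im)
    return val if scaled else val * np.exp(-z)
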