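"""Planar-geometry theory: complex decay rates, decay lengths, Fourier
reconstruction."""

import cmath

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsedox import (
    BoundarySignal,
    FourierMode,
    InfiniteDecayLengthError,
    RadialProfile,
    decay_length_curve,
    decay_rate,
    planar_mode_profile,
    reconstruct_time_series,
)

GAMMA = 2.16e-3
D = 2000.0


class TestDecayRate:
    def test_stationary_closed_form(self):
        """At omega = 0 the decay length is sqrt(D/gamma)."""
        dr = decay_rate(GAMMA, 0.0, D)
        assert dr.decay_length == pytest.approx(np.sqrt(D / GAMMA), rel=1e-12)
        assert dr.s.imag == 0.0

    def test_oscillating_mode_against_independent_arithmetic(self):
        """1/Re(sqrt((gamma+i*omega)/D)) computed with cmath as the oracle."""
        omega = 2 * np.pi * 0.1
        expected = 1.0 / cmath.sqrt(complex(GAMMA, omega) / D).real
        got = decay_rate(GAMMA, omega, D).decay_length
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(79.7, abs=0.1)
        # omega >> gamma: within 1% of the pure-oscillation power law
        assert got == pytest.approx(np.sqrt(2 * D / omega), rel=0.01)

    def test_rejects_doubly_degenerate_input(self):
        with pytest.raises(InfiniteDecayLengthError):
            decay_rate(0.0, 0.0, D)

    @settings(derandomize=True, max_examples=300)
    @given(
        gamma=st.floats(1e-6, 10.0),
        omega=st.floats(1e-6, 10.0),
        d=st.floats(1.0, 1e5),
    )
    def test_decay_length_formula_equivalence(self, gamma, omega, d):
        """1/Re(s) equals sqrt(2D/(gamma + sqrt(gamma^2 + omega^2)))."""
        got = decay_rate(gamma, omega, d).decay_length
        closed = np.sqrt(2 * d / (gamma + np.hypot(gamma, omega)))
        assert got == pytest.approx(closed, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(gamma=st.floats(1e-6, 1.0), omega=st.floats(1e-6, 1.0))
    def test_monotone_in_frequency_and_consumption(self, gamma, omega):
        lam = decay_rate(gamma, omega, D).decay_length
        assert decay_rate(gamma, omega * 1.5, D).decay_length < lam
        assert decay_rate(gamma * 1.5, omega, D).decay_length < lam
        # scales as sqrt(D)
        assert decay_rate(gamma, omega, 4 * D).decay_length == pytest.approx(
            2 * lam, rel=1e-12
        )


class TestPlanarProfile:
    def test_boundary_value_and_e_folding(self):
        mode = FourierMode(n=1, omega_n=2 * np.pi * 0.01, amplitude=0.7 + 0.2j)
        assert planar_mode_profile(0.0, mode, GAMMA, D) == mode.amplitude
        lam = decay_rate(GAMMA, mode.omega_n, D).decay_length
        ratio = abs(planar_mode_profile(lam, mode, GAMMA, D)) / abs(mode.amplitude)
        assert ratio == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_stationary_e_folding_at_closed_form_length(self):
        """gamma=2.16e-3, D=2000: ratio e^-1 at x = sqrt(D/gamma) = 962.25 um."""
        mode = FourierMode(n=0, omega_n=0.0)
        x = np.sqrt(D / GAMMA)
        val = abs(planar_mode_profile(x, mode, GAMMA, D))
        assert val == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_rejects_negative_x(self):
        with pytest.raises(ValueError):
            planar_mode_profile(-1.0, FourierMode(0, 0.0), GAMMA, D)

    @pytest.mark.parametrize("omega", [0.0, 2 * np.pi * 0.01, 2 * np.pi * 0.1])
    def test_profile_satisfies_mode_ode(self, omega):
        """D*phi'' = (gamma + i*omega)*phi, checked by central differences."""
        mode = FourierMode(n=0, omega_n=0.0) if omega == 0 else FourierMode(1, omega)
        # step balancing truncation vs round-off: (h|s|)^2 ~ sqrt(48*eps)
        h = 2.5e-4 / abs(decay_rate(GAMMA, omega, D).s)
        for x in (5.0, 50.0, 200.0):
            f = lambda z: planar_mode_profile(z, mode, GAMMA, D)
            second = (f(x + h) - 2 * f(x) + f(x - h)) / h**2
            assert D * second == pytest.approx(
                complex(GAMMA, omega) * f(x), rel=1e-6
            )


class TestDecayLengthCurve:
    def test_limits_and_monotonicity(self):
        omega = GAMMA * np.logspace(-3, 4, 60)
        df = decay_length_curve(GAMMA, D, omega)
        lengths = df.decay_length_um.to_numpy()
        assert np.all(np.diff(lengths) < 0)
        lam0 = np.sqrt(D / GAMMA)
        # flat (within 1%) for omega <= gamma/10
        low = df[df.omega_over_gamma <= 0.1]
        assert np.allclose(low.decay_length_um, lam0, rtol=0.01)
        # small-omega limit to 0.1%
        tiny = decay_rate(GAMMA, GAMMA / 1000, D).decay_length
        assert tiny == pytest.approx(lam0, rel=1e-3)
        # power law within 5% for omega >= 100 gamma, 0.2% at 1000 gamma
        high = df[df.omega_over_gamma >= 100]
        power = np.sqrt(2 * D / (high.omega_over_gamma * GAMMA))
        assert np.allclose(high.decay_length_um, power, rtol=0.05)
        big = decay_rate(GAMMA, 1000 * GAMMA, D).decay_length
        assert big == pytest.approx(np.sqrt(2 * D / (1000 * GAMMA)), rel=2e-3)

    def test_transition_sits_at_gamma(self):
        """gamma marks the crossover: at omega = gamma the curve has left
        the flat regime (several % below sqrt(D/gamma)) and is still far
        from the power law it only joins at omega >> gamma."""
        lam0 = np.sqrt(D / GAMMA)
        at_gamma = decay_rate(GAMMA, GAMMA, D).decay_length
        assert at_gamma < 0.95 * lam0                       # left the plateau
        assert at_gamma < 0.75 * np.sqrt(2 * D / GAMMA)     # not on power law
        near_power = decay_rate(GAMMA, 100 * GAMMA, D).decay_length
        assert near_power == pytest.approx(
            np.sqrt(2 * D / (100 * GAMMA)), rel=0.01
        )


def _profile_const(mode, value=None):
    grid = np.array([3.0, 10.0, 50.0])
    vals = np.ones(3, dtype=complex)
    return RadialProfile(r_grid=grid, values=vals, mode=mode, normalized=True)


class TestReconstruction:
    def test_stationary_signal_is_constant(self):
        omega = 2 * np.pi * 0.01
        sig = BoundarySignal(omega, (FourierMode(0, 0.0, 1.3),))
        prof = _profile_const(sig.modes[0])
        t = np.linspace(0, 200, 50)
        series = reconstruct_time_series(sig, [prof], 10.0, t)
        assert np.allclose(series, 1.3)

    def test_two_mode_cosine(self):
        """Modes {n=0: 1, n=1: 0.5} at the wall give 1 + cos(omega t)."""
        omega = 2 * np.pi * 0.05
        sig = BoundarySignal(
            omega, (FourierMode(0, 0.0, 1.0), FourierMode(1, omega, 0.5))
        )
        profs = [_profile_const(m) for m in sig.modes]
        t = np.linspace(0, 40.0, 101)
        series = reconstruct_time_series(sig, profs, 10.0, t)
        assert np.allclose(series, 1.0 + np.cos(omega * t), atol=1e-12)

    def test_time_average_is_the_constant_mode(self):
        """Orthogonality: the average over one period equals phi_0(r)."""
        omega = 2 * np.pi * 0.02
        sig = BoundarySignal(
            omega,
            (FourierMode(0, 0.0, 0.8), FourierMode(1, omega, 0.3 + 0.1j),
             FourierMode(2, 2 * omega, 0.05 - 0.2j)),
        )
        profs = [_profile_const(m) for m in sig.modes]
        t = np.linspace(0, sig.period, 4001)
        series = reconstruct_time_series(sig, profs, 10.0, t)
        avg = np.trapezoid(series, t) / sig.period
        assert avg == pytest.approx(0.8, abs=1e-6)

    def test_mismatched_profiles_rejected(self):
        omega = 2 * np.pi * 0.02
        sig = BoundarySignal(omega, (FourierMode(0, 0.0, 1.0),
                                     FourierMode(1, omega, 0.5)))
        profs = [_profile_const(sig.modes[0])]
        with pytest.raises(ValueError):
            reconstruct_time_series(sig, profs, 10.0, np.array([0.0]))


class TestBoundarySignal:
    def test_reconstruction_is_real_and_mean_matches(self):
        omega = 2 * np.pi * 0.01
        sig = BoundarySignal(
            omega, (FourierMode(0, 0.0, 0.4), FourierMode(1, omega, 0.2 + 0.3j))
        )
        t = np.linspace(0, 3 * sig.period, 1000)
        series = sig.reconstruct(t)
        assert series.dtype.kind == "f"
        assert sig.mean == pytest.approx(0.4)

    def test_harmonic_frequency_consistency_enforced(self):
        with pytest.raises(ValueError):
            BoundarySignal(1.0, (FourierMode(2, 3.0, 0.1),))
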