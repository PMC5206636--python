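# Methods

## Model and assumptions

The package solves the linearized reaction–diffusion equation
∂Φ/∂t = D∇²Φ − γΦ for oxygen near a single straight blood vessel, under
these assumptions:

- **Linear consumption.** Michaelis–Menten kinetics are linearized to a
  first-order loss γΦ; the Michaelis–Menten coefficients themselves
  never appear, only the effective rate γ.
- **Uniform D.** The diffusion coefficient is position-independent;
  matrix composition etc. enter only through its value.
- **Axisymmetry, no axial gradients.** The concentration depends on the
  radial coordinate r alone; the slow oxygen depletion of erythrocytes
  along the vessel is neglected, as is any vessel-network geometry.
- **Periodic boundary signal.** The wall concentration is expanded in
  complex Fourier modes; only n ≥ 0 harmonics are stored, the negative
  ones being implied by conjugation (this halves the state and removes a
  symmetry invariant that would otherwise need maintaining). Time series
  are reassembled at reconstruction time and checked real to round-off.
- **Linearity + superposition.** Each mode solves its own Helmholtz-type
  radial problem with the complex rate γ + iωₙ, independently of the
  others.

Units are μm and s throughout the core (D = 2×10⁻⁹ m²/s is stored as
2000 μm²/s); SI values are converted exactly once, at the config
boundary.

## Parameters

| symbol | meaning | default | unit | why |
|---|---|---|---|---|
| D | oxygen diffusion coefficient | 2000 | μm²/s | measured in blood/tissue; 3200 ≈ pure water, 1000 ≈ dense matrix |
| γ₀ | far-field consumption rate | 0 | 1/s | necrotic regions far from vessels consume nothing |
| γ_c | wall excess consumption | 2.16×10⁻³ | 1/s | mean of the in-vivo range 1.66×10⁻⁴–5×10⁻³ |
| λ_c | cord consumption decay length | 120 | μm | viable-cell density decay scale in cords |
| R | vessel radius | 2.5 (capillary) / 22.5 (median) | μm | 5 μm diameter admits one erythrocyte; 22.5 μm is the median of the comparison dataset's 10–80 μm diameters |
| f band | low-frequency oscillations | 0.01–0.1 | Hz | the band with the highest measured oxygen-fluctuation amplitude in tumour microcirculation |

γ = ωₙ = 0 is rejected (`InfiniteDecayLengthError`) rather than
special-cased: the degenerate constant mode would report an infinite
decay length and silently break downstream root-finding.

## Solvers and numerical choices

**Uniform consumption (compact tissue).** Exact solution
K₀(sₙr)/K₀(sₙR). Evaluated via exponentially scaled Bessel functions
(`scipy.special.kve`, AMOS) with the exponential recombined
analytically, so no overflow/underflow is possible for |sₙr| from 1e-6
to 1e3 and beyond. The library route is cross-validated against an
independent integral-representation evaluator
(K_ν(z) = ∫₀^∞ e^{−z cosh t} cosh νt dt) to 1e-10 on the sector
arg(z) ∈ [0, π/4] that the model visits.

**Tumour cords (shell product).** The solver freezes the local rate in
each infinitesimal shell and multiplies the cylindrical shell factors;
in log form,
ln[φₙ(r)/φₙ(R)] = −∫ sₙ(ρ) K₁/K₀(sₙ(ρ)ρ) dρ. The integrand is smooth;
adaptive quadrature (`scipy.integrate.quad`) runs at absolute+relative
tolerance 1e-9 on the log-integrand, accumulated per grid interval, with
the summed error estimate reported in the `SolverReport`. Where the
consumption rate underflows to zero at very large radius (stationary,
γ₀ = 0), the integrand's limit 0 is substituted explicitly. Monte Carlo
paths reuse the same integral at a relaxed 1e-7 tolerance — still five
orders below the scatter the simulation studies.

**Exact oracle.** `ode_oracle_profile` solves the radial BVP
D(φ″ + φ′/r) = (γ(r) + iωₙ)φ directly: inward LSODA integration from
r_max (which makes the bounded, K₀-type solution dominant — inward
integration is self-correcting), closed at r_max by the Robin condition
φ′/φ = −s·K₁(s r_max)/K₀(s r_max) with the local s (exact where γ is
locally constant; for γ(r_max) = 0 and ω = 0 the outer equation is
Laplace's and the closure is φ′ = 0). r_max starts at
R + max(10λ_c, 5 decay lengths at the wall rate) and doubles until the
outermost requested value changes by < 0.1%.

**Where the product formula is and is not trustworthy.** The
frozen-coefficient construction assumes s varies slowly on the scale
1/s. For the oscillating band (0.01–0.1 Hz) 1/|s| ≲ 180 μm and s is
dominated by the ω-term, which does not vary with r at all: product and
oracle agree to ≤ 0.3% across γ_c ∈ [1.66×10⁻⁴, 5×10⁻³] s⁻¹ and
R ∈ [2.5, 40] μm. In the *stationary* cord regime (γ₀ = 0, ω = 0),
however, 1/s ≈ 3500 μm ≫ λ_c = 120 μm and the assumption fails badly:
the exact profile barely decays (the cord is a weak 2-D absorber;
plateau ≈ 0.99 at γ_c = 1.66×10⁻⁴ vs the product formula's ≈ 0.24,
40–77% relative deviation across the sweep). The reference cord quantities
derive from the product formula, so the package's acceptance harness binds
to it; the oracle-equivalence test is allowed to fail loudly for the
stationary corner rather than hiding the discrepancy, and the solver
method is logged with every curve so provenance is always recoverable.

**Half-value radius.** Bracketed on the solved grid, refined by Brent's
method on the solver's *continuous* evaluator (a fresh quadrature from
the wall), never by grid interpolation; xtol 1e-3 μm. A profile that
plateaus above 0.5 returns an explicit no-crossing result (`None`), not
a number.

**Large-radius plateau.** Exists only when losses vanish at infinity
(γ₀ = 0 and ω = 0); otherwise 0 is returned. Evaluated at radii doubling
from R + 10λ_c until successive doublings change the value by < 0.5%,
returning the last value. The profile converges only logarithmically
(the log-integrand tail is ~2λ_c/ρ²), so this converged estimate —
0.2387 for γ_c = 1.66×10⁻⁴ — is a few hundredths *below* the value the
curve still shows at a few millimetres from the vessel (it passes 0.25
near r ≈ 4 mm). Plateau values quoted from finite plotting ranges are
therefore expected to read slightly high against this estimate.

**Robustness metric.** The band-displacement summary is the maximum
vertical shift of the 0.01/0.1 Hz band edges over r ∈ [R, R + 400 μm]
relative to the base parameters, compared with the same shift of the
stationary cord curve. Under the γ_c sweep across the full in-vivo range
the band moves by ≤ 0.003 while the stationary curve moves by
0.06–0.13 — the band is insensitive to consumption because ω ≫ γ there.
Under the D sweep (1000/3200 μm²/s) both move, and the band edges
(whose decay length is √(2D/ω)) actually move *more* (0.05–0.08) than
the flattened stationary curve (0.03–0.05): the D-stability of the band
is a statement about visual overlap of the belt, not about this metric,
and the corresponding check is left to fail honestly rather than
switching to a metric that would pass.

## Scenario presets and Monte Carlo

Classes 1, 2, 4 use the uniform-γ solver; classes 3, 5 the cord solver;
the dispatch is total, each class carrying one preset. Bursting-flow
classes (4, 5) represent the signal by the modulus of the first
harmonic, evaluated at the 0.01 and 0.1 Hz band edges.

The Monte Carlo draws one uniform triple per iteration in the fixed
order radius → frequency → distance (frequency is drawn but ignored in
stationary cases, keeping draws paired across cases at equal seed), from
U(5, 40) μm × U(0.01, 0.1) Hz × U(0, 400) μm, 20 000 draws per case by
default. One `numpy.random.default_rng(seed)` governs the whole run:
bit-reproducible within this implementation; reproducible across
implementations only at the level of the distributional contract.
Distance is interpreted from the vessel wall by default (r = R + d); the
axis interpretation clamps d < R to the wall with a flag column. The
stationary compact/cord cases at equal seed are a paired comparison, and
cords dominate compact at every draw because the cord removes less
oxygen everywhere.

## Synthetic data: what it does and does not emulate

The rectangular pulse train stands in for bursting reoxygenation because
its Fourier coefficients are closed-form (c₀ = baseline + A·d,
|c_n| = A·d·|sinc(nd)|), making the generator exactly testable
(Parseval bookkeeping included); real vessel-wall signals are neither
rectangular nor strictly periodic, and measured spectra contain broadband
power this generator does not produce. Pseudo-measurement sets draw
Gaussian replicates (default 15, matching the s.e.m.-over-15-samples
convention of the comparison data) around the model's time-averaged
profile, clipped at zero because pO₂ ratios cannot be negative; no
spatial correlation, probe volume, or drift is modelled. Everything is
in wall-normalized units — absolute pO₂ is never specified. Passing the
closed-loop tests therefore demonstrates internal consistency of
generator + solver + overlay, not fidelity to any real tumour's noise
structure.

## Known limitations

- Single straight vessel; no network, no axial depletion, no 2-D/3-D
  vascular geometry.
- Linear consumption only; no Michaelis–Menten saturation at very low
  pO₂.
- The shell-product cord solution is a frozen-coefficient approximation and
  is quantitatively unreliable in the stationary γ₀ = 0 regime (see
  above); the exact oracle is the reference there.
- The overlay performs no inference: residuals are reported, nothing is
  estimated from data by design.
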