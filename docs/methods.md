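# Methods

This note records the models implemented in `dimerbath`, the numerical
choices behind them, and what the test suite does and does not demonstrate.
Everything is in dimensionless units; there is no unit-conversion layer.

## The dimer and its macroscopic benchmark

The solute is two beads ("monomers") of mass `M` joined by a harmonic
spring `Phi(R) = k (R − l0)²/2`. The macroscopic solvent model adds
friction `γ` and noise of amplitude `γ sqrt(2D)` per velocity component, so
each monomer velocity is an Ornstein–Uhlenbeck process with stationary
per-component variance `Dγ` and the thermal energy is fixed by the
Einstein–Smoluchowski relation `k_B T = M D γ`; temperature is never a free
parameter anywhere in the package. Closed forms used as benchmarks: the
centre-of-mass VACF `(Dγ/2)e^{−γτ}`, its Green–Kubo integral `D/2`, the
stationary separation density `∝ exp[−Phi(R)/(MDγ)]`, and the first-order
stiff-spring mean length `l0(1 + 2MDγ/(k l0²))`, valid for
`ε = MDγ/(k l0²) ≪ 1` (a warning is emitted above ε = 0.1).

Integrators: explicit Euler–Maruyama (the default, matching the
mixed-resolution update of the coarse monomer) and BBK, a velocity-Verlet
scheme whose acceleration carries `−γV + γ sqrt(2D/Δt) ξ` with one fresh
`ξ` per time point, used in both half-kicks that touch that time point and
with the final half-kick solved implicitly in the friction term. The
choice matters for the stiff reference spring `k = 10⁶`: explicit
Euler–Maruyama amplifies the relative mode unless `Δt ≲ γM/(2k) = 5·10⁻⁶`,
so the Langevin benchmark at `Δt = 10⁻⁴` runs under BBK (stable for
`ω Δt < 2`; here `ω Δt ≈ 0.14`). A zero monomer separation raises an error
rather than being regularised — with stiff springs and `l0 > 0` it can only
mean a broken configuration.

## Short-range (collisional) heat bath

Solvent is an ideal gas of point particles of mass `m = M/μ` that interact
with the monomers (balls of radius `r0`) only through frictionless elastic
collisions; the normal velocity components exchange with μ-weighted
coefficients and the tangential components are untouched, conserving
momentum and energy to machine precision. To realise macroscopic `(γ, D)`
the gas must carry

    σ_μ² = (μ+1) D γ            (per-component velocity variance)
    λ_μ  = 3/(8 r0²) · sqrt((μ+1) γ / (2π D))    (number density)

The density expression inverts the specular-reflection (Epstein) drag law
`γM = (8/3) sqrt(2π) λ m σ r0²`; with this pair a single monomer feels
friction `γ(μ+1)/μ`, i.e. `γ` up to an `O(1/μ)` correction. The pair is
validated operationally: a lone monomer's VACF decay rate fits `γ` within a
few percent (tests), and the frame machinery below holds the gas at exactly
this density and temperature.

### Co-moving frame with open boundaries

Solvent is explicit only inside a cubic frame of side `L` centred on the
dimer's centre of mass (one-bath), on each monomer (two-bath; each frame
keeps its own independent particle set), or on the MD monomer (mixed). One
step of length `Δt`:

1. free flight of monomers and particles;
2. any particle whose free-flight position overlaps a monomer it can
   collide with is rewound, together with that monomer, by the unique
   positive root `τ` of the contact quadratic (separation `r0`), given the
   elastic exchange at the contact normal, and advanced again by `τ`.
   Multiple overlapping particles in one step are resolved sequentially in
   order of contact time: at the reference parameters the probability of
   two overlaps in a step is ~3·10⁻⁵, so hundreds of such events occur in a
   10⁷-step run and aborting on them would make the reference protocols
   unusable. An error is still raised if a particle was already inside a
   monomer at the start of a step or resolution fails to terminate;
3. forward-Euler spring kick on the monomer velocities (using
   post-collision velocities); in the mixed model the coarse monomer takes
   an Euler–Maruyama Langevin step instead;
4. frame recentring; particles now outside are deleted permanently (the
   scheme ignores that a particle could leave and later return — a known
   approximation of small co-moving frames);
5. boundary insertion: with the frame velocity `V_f` over the step, the
   mean number of gas particles entering a face of inward normal `ê` is
   `p_in = λ_μ L² Δt [σ_μ/sqrt(2π) e^{−V²/(2σ_μ²)} − (V/2) erfc(V/(σ_μ
   sqrt(2)))]`, `V = V_f·ê`. One face is chosen uniformly and a particle is
   inserted with probability `6 p_in(face)` (statistically identical to
   per-face Bernoulli insertions). Its depth past the face is `σ_μ Δt
   sqrt(2)` times a draw from the density `∝ erfc(z+β)`,
   `β = V/(σ_μ sqrt(2))`; transverse coordinates are uniform; the
   inward-normal velocity component is Gaussian conditioned to reach that
   depth within `Δt`. Because summing six half-space fluxes over-counts
   edges and corners, an insertion whose back-propagated position has `j`
   coordinates outside the frame is kept with probability `1/j`. Inserted
   particles overlapping a monomer are discarded (mirroring the
   initialisation rule).

The single-insertion-per-step approximation needs `6 p_in` small: the
package warns above 0.1 and refuses above 0.5. (The one-bath reference
preset `L = 0.72`, `Δt = 10⁻⁶` sits at `6 p_in ≈ 0.29` — the protocol's own
choice; the stated requirement is only `p_in ≪ 1`.) The strongest single
test of the boundary machinery is equilibrium maintenance: an empty frame,
at rest or dragged at constant velocity, holds its particle count
Poisson(`λ_μ L³`) and its velocity distribution Maxwell–Boltzmann over
4·10⁵ steps (χ² and KS tests at 1%).

Monomer–monomer excluded volume is not enforced (the model defines no such
collision); presets keep `l0 ≥ 2.25 r0` so overlap is rare.

### Acceptance–rejection samplers

The depth density `p(z; β) = C₃(β) erfc(z+β)`, `z ≥ 0`, with
`C₃(β) = sqrt(π)/(e^{−β²} − sqrt(π) β erfc β)` (fixed by normalisation), is
sampled exactly: propose `z = −a₁ ln η₁` (exponential of mean `a₁`), accept
when `η₁η₂ < a₂ erfc(z+β)`, with

    a₁(β) = (sqrt(π)/2)·erfc(β)e^{β²}  (β ≥ 0),  sqrt(π)/2       (β ≤ 0)
    a₂(β) = 1/erfc(β)                  (β ≥ 0),  e^{2β/sqrt(π)}  (β ≤ 0)

The acceptance probability is `a₂/(a₁C₃(β))` — `2/π ≈ 63.7%` at `β = 0`,
or `86.3%` with the hand-tuned pair `a₁ = 0.532`, `a₂ = 0.814` (a
numerically optimised `(a₁, a₂)` table is deliberately out of scope). For
numerical robustness `erfc(β)e^{β²}` is evaluated through the scaled
complementary error function, and the acceptance test runs in log space, so
large `|β|` can neither overflow nor underflow the comparison. Truncated
Gaussian velocities use exact rejection from the normal for low thresholds
and Robert's translated-exponential proposal in the far tail. Every sampler
takes an explicit `numpy` Generator; compiled kernels derive one integer
seed per call from it, so runs are reproducible bit for bit.

## Long-range (oscillator) heat bath

Each monomer couples linearly to `N_i` harmonic oscillators of mass `m`
with frequencies drawn i.i.d. exponential(mean `ω̄`) and couplings
`α² = 2γω̄/(N m π ω²)` (per-monomer baths) or `k_j = mω_j²/2`,
`α_j² = γω̄/(Nπk_j)` (one bath shared by both monomers with identical
couplings). These choices make the eliminated-bath friction kernel converge
to the Lorentzian `κ(τ) = (2γ/π) ω̄/(ω̄²τ²+1)` with `∫κ = γ` exactly in the
coupling-sum identities (`m Σ α²ω² = 2γω̄/π` holds for every draw). The
generalized-Langevin form itself is never integrated; the oscillators are
simulated explicitly and the kernel and noise statistics are derived
diagnostics. Oscillator velocities are initialised at `N(0, k_BT/m)` and
positions at thermal equilibrium about each oscillator's instantaneous
potential minimum (variance `k_BT`/total stiffness) — with this choice the
bath force on a pinned monomer has autocorrelation `k_B T · κ(τ)` from
`t = 0`, which the tests verify directly. Drawn frequencies are never
truncated (that would bias `κ(0)`); the step-size rule adapts instead:
default `Δt = min(10⁻³/ω̄, 0.1/ω_max)`, with a hard error at
`Δt·ω_max > 1`.

Arrangements: `two_bath` (independent baths), `shared` (every oscillator
pulls on both monomers — the bath variables then cancel from the
separation dynamics, leaving `M R̈ = −2Phi'(R)R̂ − (γω̄/π)R` and the
contracted mean length `2kπ l0/(2kπ + γω̄)`), and `split` (one population
divided into two groups, each coupled to one monomer — dynamically
identical to `two_bath`, and the tests check the trajectories agree bit
for bit given the same draw). Dynamics are velocity Verlet, time-reversible
with bounded energy drift (≈10⁻⁸ relative over 10⁴ steps in the tests).
The mixed-resolution scheme evolves monomer 1 and its oscillators by Verlet
while monomer 2 takes BBK accelerations inside the same half-kick
structure, with a fresh Gaussian per time point.

## Estimators

Mean dimer length: post-burn-in time average with a two-sided batch-means
confidence interval (20 batches, Student-t, 99% by default) — the batching
absorbs autocorrelation; the exact construction is this package's choice.
VACF: time average over all overlapping origins on the recording grid
(FFT-based). Diffusion constant: trapezoidal Green–Kubo integral of the
VACF over `[0, 1]` (the reference protocol's window); a batch variant
splits the trajectory into contiguous segments to attach a standard error.
MSD route: least-squares slope of MSD against lag over a short-lag window
(default 0.5–5% of the span, where hundreds of origins contribute; a
growing slope across the window flags a non-diffusive trajectory).
Exponential fit: nonlinear least squares of `(Dγ/2)e^{−γτ}` over the
positive part of the VACF, recovering `D` and `γ` simultaneously. On
Langevin-generated data all three diffusion routes agree within joint
confidence intervals (tested).

Trajectories record `t`, the centre of mass, its velocity, the length `R`,
and the first monomer's velocity (needed for single-monomer diagnostics),
at a sampling interval decoupled from `Δt` (default 10⁻³ time units — full
rate at `Δt = 10⁻⁶` would be enormous and is never needed by the
estimators).

## Problem sizes and what the tests show

The shipped presets carry the full reference protocols (e.g. 100–1000 time
units at `Δt = 10⁻⁶`, `N₁ = 10⁵` oscillators). The test suite and the
acceptance script run scaled-down versions chosen so each check resolves
its effect with margin on a single core:

* Langevin benchmark: `T = 200` at `Δt = 10⁻⁴` (BBK); `D_d` within 3
  standard errors of `D/2` and `L_d` CI covering the first-order mean.
* Short-range mixed resolution: `T = 20` at `Δt = 10⁻⁶`, `L = 0.32`
  (≈77 explicit particles). Single-run Green–Kubo estimates scatter by
  roughly ±0.07 around `D/2` at this length, so the acceptance script
  averages several independent runs.
* Long-range mixed resolution: `N₁ = 10³`, `T = 20`, `Δt = 2·10⁻⁵`. At
  this bath size the zero-frequency mobility is sensitive to the few
  lowest drawn frequencies, so single runs scatter by ~0.1 around `D/2`;
  estimates are therefore averaged over independent bath draws.
* Mean-length contrasts (shared vs split baths, two-bath collisional)
  use a softer spring (`k = 10³`–`10⁴`) so the predicted shifts exceed
  the CI half-width within seconds of simulated time.

Two caveats the tests make explicit rather than hide: the shared-bath
separation dynamics is undamped (the bath cancels exactly), so its mean
length agrees with the fixed-point formula only up to the oscillation and
centrifugal corrections left by the thermal initial condition (a few
percent at the test amplitudes); and the co-moving frame's no-return
approximation makes small-`L` collisional transport quantities deviate
slightly from the Langevin values — the package reproduces, rather than
corrects, this property of the scheme.

The synthetic baths emulate ideal solvents exactly (point particles with
Maxwellian statistics; linear oscillators); passing tests demonstrate the
correctness of the multi-resolution machinery, not the fidelity of these
baths to any molecular solvent.

## Known limitations

* The collisional stepper assumes rare events per step; it refuses
  `6 p_in > 0.5` and resolves, but does not chain, simultaneous collisions.
* Particles leaving a co-moving frame never return (see above).
* No monomer–monomer excluded volume; no polymers beyond the dimer.
* The fixed-subdomain hybrid (an MD region embedded in a Langevin domain
  with boundary correction forces) is out of scope.
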