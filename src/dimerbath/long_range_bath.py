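"""Harmonic-oscillator (long-range) heat bath for the dimer.

Each monomer is coupled linearly to many harmonic oscillators — a
Kac-Zwanzig-type construction. Oscillator frequencies are i.i.d.
exponential with mean ``omega_bar``; with coupling constants

    alpha_{i,j}^2 = 2 gamma omega_bar / (N_i m pi omega_{i,j}^2)

the friction kernel obtained by eliminating the bath converges (as
N -> inf) to the Lorentzian

    kappa(tau) = (2 gamma / pi) * omega_bar / (omega_bar^2 tau^2 + 1),

whose integral is exactly gamma — so for large omega_bar the dimer's
statistics approach the memoryless Langevin benchmark. Three bath
arrangements are supported: an independent bath per monomer (``two_bath``),
a single bath whose oscillators couple identically to both monomers
(``shared``, which effectively shortens the spring's rest length), and a
single bath split into two groups each coupled to one monomer (``split``,
dynamically identical to two baths). A mixed-resolution scheme evolves
monomer 1 and its oscillators by velocity Verlet while monomer 2 takes BBK
Langevin steps inside the same half-kick structure.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Optional, Tuple, Union

import numpy as np

from . import _kernels
from .errors import ConfigurationError, DegenerateSeparationError
from .model_core import (DimerState, LangevinParams, SpringParams, Trajectory,
                         _derive_seeds, _records_to_trajectory,
                         thermal_dimer_state)

__all__ = [
    "OscillatorBath",
    "OscillatorState",
    "build_bath",
    "friction_kernel",
    "empirical_friction_kernel",
    "bath_forces",
    "initialize_oscillators",
    "step_verlet_full",
    "step_mixed_long_range",
    "simulate_long_range",
    "suggest_timestep",
    "total_energy",
]

BathMode = Literal["two_bath", "shared", "split"]


@dataclasses.dataclass
class OscillatorBath:
    """Per-oscillator frequencies and couplings of the heat bath.

    Arrays are laid out over all N oscillators; k1/alpha1 couple to monomer
    1 and k2/alpha2 to monomer 2 (zero where a group does not interact, as
    in two_bath and split arrangements). kT is the thermal energy used for
    initialisation (Einstein-Smoluchowski: kT = M*D*gamma).
    """

    omega: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    m: float
    omega_bar: float
    kT: float
    mode: str
    N1: int
    N2: int

    @property
    def N(self) -> int:
        return len(self.omega)

    @property
    def omega_max(self) -> float:
        return float(np.max(self.omega)) if self.N else 0.0


@dataclasses.dataclass
class OscillatorState:
    """Positions and velocities of the bath oscillators."""

    positions: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shapes differ")


def build_bath(N: Union[int, Tuple[int, int]], omega_bar: float,
               gamma: float, m: float, kT: float,
               mode: BathMode, rng: np.random.Generator) -> OscillatorBath:
    """Draw a bath of N oscillators (a pair (N1, N2) for two_bath/split).

    two_bath / split: group i has k = m*omega^2 and
    alpha^2 = 2*gamma*omega_bar/(N_i*m*pi*omega^2), so
    m*sum(alpha^2*omega^2) = 2*gamma*omega_bar/pi per group exactly.
    shared: every oscillator couples to both monomers with
    k_j = m*omega_j^2/2 and alpha_j^2 = gamma*omega_bar/(N*pi*k_j), so
    sum(k_j*alpha_j^2) = gamma*omega_bar/pi exactly.
    """
    if omega_bar <= 0 or m <= 0 or kT <= 0:
        raise ConfigurationError("omega_bar, m and kT must be positive")
    if mode in ("two_bath", "split"):
        if isinstance(N, (tuple, list)):
            N1, N2 = int(N[0]), int(N[1])
        else:
            N1 = N2 = int(N)
        Ntot = N1 + N2
        omega = rng.exponential(omega_bar, size=Ntot)
        k = m * omega ** 2
        k1 = np.where(np.arange(Ntot) < N1, k, 0.0)
        k2 = np.where(np.arange(Ntot) >= N1, k, 0.0)
        a1 = np.zeros(Ntot)
        a2 = np.zeros(Ntot)
        if N1 > 0:
            a1[:N1] = np.sqrt(2.0 * gamma * omega_bar
                              / (N1 * m * math.pi * omega[:N1] ** 2))
        if N2 > 0:
            a2[N1:] = np.sqrt(2.0 * gamma * omega_bar
                              / (N2 * m * math.pi * omega[N1:] ** 2))
        return OscillatorBath(omega=omega, k1=k1, k2=k2, alpha1=a1, alpha2=a2,
                              m=m, omega_bar=omega_bar, kT=kT, mode=mode,
                              N1=N1, N2=N2)
    if mode != "shared":
        raise ConfigurationError(f"unknown bath mode {mode!r}")
    Ntot = int(N)
    omega = rng.exponential(omega_bar, size=Ntot)
    kj = 0.5 * m * omega ** 2
    aj = np.sqrt(gamma * omega_bar / (Ntot * math.pi * kj))
    return OscillatorBath(omega=omega, k1=kj, k2=kj.copy(), alpha1=aj,
                          alpha2=aj.copy(), m=m, omega_bar=omega_bar, kT=kT,
                          mode="shared", N1=Ntot, N2=Ntot)


def friction_kernel(tau, gamma: float, omega_bar: float):
    """Limiting Lorentzian friction kernel
    kappa(tau) = (2 gamma/pi) omega_bar / (omega_bar^2 tau^2 + 1);
    kappa(0) = 2 gamma omega_bar / pi and its integral over [0, inf) is
    gamma."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    out = (2.0 * gamma / math.pi) * omega_bar / (omega_bar ** 2 * tau ** 2 + 1.0)
    return float(out) if out.ndim == 0 else out


def empirical_friction_kernel(bath: OscillatorBath, tau,
                              monomer: int = 1):
    """Finite-N kernel m * sum_j alpha_j^2 omega_j^2 cos(omega_j tau) for the
    oscillators coupled to the given monomer."""
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    a = bath.alpha1 if monomer == 1 else bath.alpha2
    w = bath.omega
    coef = bath.m * a ** 2 * w ** 2
    return (coef[None, :] * np.cos(np.outer(tau, w))).sum(axis=1)


def bath_forces(dimer: DimerState, bath: OscillatorBath,
                state: OscillatorState, spring: Optional[SpringParams] = None):
    """Forces of the oscillator bath (plus the spring when given).

    Returns (F1, F2, a_osc): the force on each monomer,
    sum_j k_{i,j} alpha_{i,j} (x_j - alpha_{i,j} X_i), and the oscillator
    accelerations (-k1_j (x_j - a1_j X1) - k2_j (x_j - a2_j X2))/m.
    """
    x = state.positions
    d1 = x - bath.alpha1[:, None] * dimer.X1
    d2 = x - bath.alpha2[:, None] * dimer.X2
    F1 = ((bath.k1 * bath.alpha1)[:, None] * d1).sum(axis=0)
    F2 = ((bath.k2 * bath.alpha2)[:, None] * d2).sum(axis=0)
    ao = (-(bath.k1[:, None] * d1) - bath.k2[:, None] * d2) / bath.m
    if spring is not None:
        from .model_core import spring_force

        f1, f2 = spring_force(dimer, spring)
        F1 = F1 + f1
        F2 = F2 + f2
    return F1, F2, ao


def initialize_oscillators(dimer: DimerState, bath: OscillatorBath,
                           rng: np.random.Generator) -> OscillatorState:
    """Thermal-equilibrium initialisation of the oscillators.

    Velocities are Gaussian(0, kT/m) per component. Positions are Gaussian
    about each oscillator's instantaneous potential minimum — the
    k-weighted mean of alpha1*X1 and alpha2*X2 — with per-component variance
    kT / (k1 + k2). This makes the bath-force fluctuations satisfy the
    fluctuation-dissipation relation with the friction kernel from t = 0.
    """
    K = bath.k1 + bath.k2
    centre = (bath.k1[:, None] * bath.alpha1[:, None] * dimer.X1
              + bath.k2[:, None] * bath.alpha2[:, None] * dimer.X2) / K[:, None]
    sd = np.sqrt(bath.kT / K)
    pos = centre + rng.normal(size=(bath.N, 3)) * sd[:, None]
    vel = rng.normal(0.0, math.sqrt(bath.kT / bath.m), size=(bath.N, 3))
    return OscillatorState(positions=pos, velocities=vel)


def _check_step(dt: float, bath: OscillatorBath) -> None:
    wmax = bath.omega_max
    if dt * wmax > 1.0:
        j = int(np.argmax(bath.omega))
        raise ConfigurationError(
            f"dt*omega_max = {dt * wmax:.3g} > 1 (oscillator {j}, "
            f"omega = {bath.omega[j]:.3g}): the Verlet step is unstable")


def suggest_timestep(bath: OscillatorBath, spring: Optional[SpringParams] = None,
                     M: float = 1.0) -> float:
    """Conservative default step: min(1e-3/omega_bar, 0.1/omega_max), also
    bounded by the spring period when a spring is given."""
    dt = min(1e-3 / bath.omega_bar, 0.1 / bath.omega_max)
    if spring is not None:
        dt = min(dt, 0.1 / math.sqrt(2.0 * spring.k / M))
    return dt


def total_energy(dimer: DimerState, bath: OscillatorBath,
                 state: OscillatorState, spring: Optional[SpringParams],
                 M: float) -> float:
    """Total energy of the isolated dimer + oscillator system."""
    kin = 0.5 * M * (np.sum(dimer.V1 ** 2) + np.sum(dimer.V2 ** 2))
    kin += 0.5 * bath.m * np.sum(state.velocities ** 2)
    pot = 0.0
    if spring is not None:
        pot += float(spring.potential(dimer.R))
    d1 = state.positions - bath.alpha1[:, None] * dimer.X1
    d2 = state.positions - bath.alpha2[:, None] * dimer.X2
    pot += 0.5 * float(np.sum(bath.k1[:, None] * d1 ** 2))
    pot += 0.5 * float(np.sum(bath.k2[:, None] * d2 ** 2))
    return kin + pot


# ---------------------------------------------------------------------------
# steppers
# ---------------------------------------------------------------------------

def step_verlet_full(dimer: DimerState, bath: OscillatorBath,
                     state: OscillatorState, spring: Optional[SpringParams],
                     dt: float, M: float = 1.0, n_steps: int = 1):
    """Synchronized velocity-Verlet step(s) of the full deterministic
    dimer + oscillator system (time-reversible)."""
    _check_step(dt, bath)
    X = np.stack([dimer.X1, dimer.X2]).astype(float)
    V = np.stack([dimer.V1, dimer.V2]).astype(float)
    xo = state.positions.copy()
    vo = state.velocities.copy()
    rec, err = _kernels.run_long_range_full(
        X, V, xo, vo, bath.k1, bath.k2, bath.alpha1, bath.alpha2, bath.m, M,
        spring.k if spring is not None else 0.0,
        spring.ell0 if spring is not None else 0.0,
        dt, n_steps, max(n_steps, 1))
    if err == _kernels.ERR_DEGENERATE:
        raise DegenerateSeparationError("monomer separation collapsed to zero")
    new_dimer = DimerState(X1=X[0], X2=X[1], V1=V[0], V2=V[1],
                           t=dimer.t + n_steps * dt)
    return new_dimer, OscillatorState(positions=xo, velocities=vo)


def step_mixed_long_range(dimer: DimerState, bath: OscillatorBath,
                          state: OscillatorState,
                          spring: Optional[SpringParams],
                          langevin: LangevinParams, dt: float,
                          rng: np.random.Generator, n_steps: int = 1):
    """Mixed-resolution step(s): monomer 1 and its oscillators by velocity
    Verlet, monomer 2 by BBK with acceleration
    -Phi'(R)/M R_hat - gamma V2 + gamma sqrt(2D/dt) xi (fresh xi per step)."""
    _check_step(dt, bath)
    X = np.stack([dimer.X1, dimer.X2]).astype(float)
    V = np.stack([dimer.V1, dimer.V2]).astype(float)
    xo = state.positions.copy()
    vo = state.velocities.copy()
    seed = int(rng.integers(1 << 31))
    rec, err = _kernels.run_long_range_mixed(
        X, V, xo, vo, bath.k1, bath.alpha1, bath.m, langevin.M,
        spring.k if spring is not None else 0.0,
        spring.ell0 if spring is not None else 0.0,
        langevin.D, langevin.gamma, dt, n_steps, max(n_steps, 1), seed)
    if err == _kernels.ERR_DEGENERATE:
        raise DegenerateSeparationError("monomer separation collapsed to zero")
    new_dimer = DimerState(X1=X[0], X2=X[1], V1=V[0], V2=V[1],
                           t=dimer.t + n_steps * dt)
    return new_dimer, OscillatorState(positions=xo, velocities=vo)


# ---------------------------------------------------------------------------
# full simulations
# ---------------------------------------------------------------------------

def simulate_long_range(
    spring: SpringParams,
    p: LangevinParams,
    omega_bar: float,
    N: Union[int, Tuple[int, int]],
    m: float,
    mode: Literal["two_bath", "shared", "split", "mixed"],
    T: float,
    dt: Optional[float] = None,
    seed: int = 0,
    sample_interval: Optional[float] = None,
) -> Trajectory:
    """Long-range heat-bath run in one of the bath arrangements.

    The dimer starts at separation ell0 with thermal velocities; oscillators
    are initialised at thermal equilibrium about their potential minima.
    The trajectory metadata records the post-burn-in (second half) mean
    dimer length with a 99% batch-means confidence interval.
    """
    s_init, s_kernel = _derive_seeds(seed)
    rng = np.random.default_rng(s_init)
    bath_mode = "two_bath" if mode == "mixed" else mode
    if mode == "mixed" and isinstance(N, (tuple, list)):
        N = int(N[0])
    bath = build_bath(N if mode != "mixed" else (int(N), 0), omega_bar,
                      p.gamma, m, p.kT, bath_mode, rng)
    if dt is None:
        dt = suggest_timestep(bath, spring, p.M)
    _check_step(dt, bath)
    if sample_interval is None:
        sample_interval = max(dt, 1e-3)
    record_every = max(1, int(round(sample_interval / dt)))
    n_steps = int(round(T / dt))

    dimer = thermal_dimer_state(spring, p, rng)
    state = initialize_oscillators(dimer, bath, rng)
    X = np.stack([dimer.X1, dimer.X2]).astype(float)
    V = np.stack([dimer.V1, dimer.V2]).astype(float)
    xo = state.positions
    vo = state.velocities
    if mode == "mixed":
        rec, err = _kernels.run_long_range_mixed(
            X, V, xo, vo, bath.k1, bath.alpha1, bath.m, p.M,
            spring.k, spring.ell0, p.D, p.gamma, dt, n_steps, record_every,
            s_kernel)
    else:
        rec, err = _kernels.run_long_range_full(
            X, V, xo, vo, bath.k1, bath.k2, bath.alpha1, bath.alpha2,
            bath.m, p.M, spring.k, spring.ell0, dt, n_steps, record_every)
    if err == _kernels.ERR_DEGENERATE:
        raise DegenerateSeparationError("monomer separation collapsed to zero")

    meta = {
        "model": "long_range", "mode": mode, "seed": int(seed), "dt": dt,
        "T": T, "sample_interval": record_every * dt,
        "params": {"M": p.M, "D": p.D, "gamma": p.gamma, "k": spring.k,
                   "ell0": spring.ell0, "omega_bar": omega_bar,
                   "m": m, "N1": bath.N1, "N2": bath.N2},
    }
    traj = _records_to_trajectory(rec, meta)
    from .estimators import estimate_mean_length

    res = estimate_mean_length(traj, burn_in=0.5 * T)
    meta["L_d"] = {"value": res.value, "ci_low": res.ci_low,
                   "ci_high": res.ci_high, "confidence": res.confidence}
    return traj
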