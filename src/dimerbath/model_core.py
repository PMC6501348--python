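"""Dimer definition, macroscopic Langevin reference model and closed-form
equilibrium statistics.

The solute is a dimer: two beads ("monomers") of mass ``M`` joined by a
harmonic spring with stiffness ``k`` and rest length ``ell0``,

    Phi(R) = k (R - ell0)^2 / 2 ,

where ``R`` is the separation of the beads. At the macroscopic level the
solvent enters only through a friction coefficient ``gamma`` and a diffusion
coefficient ``D``; each monomer then obeys the Langevin equations

    dX_i = V_i dt,
    dV_i = +/- Phi'(R)/M * R_hat dt - gamma V_i dt + gamma sqrt(2 D) dW_i .

The thermal energy is fixed by the Einstein-Smoluchowski relation
``k_B T = M D gamma``. Everything is in dimensionless units.

This macroscopic description is the benchmark against which the explicit
heat-bath models of :mod:`dimerbath.short_range_bath` and
:mod:`dimerbath.long_range_bath` are validated: at equilibrium the dimer's
centre-of-mass velocity autocorrelation is ``(D*gamma/2) exp(-gamma tau)``,
its diffusion constant is ``D/2`` and its mean length exceeds ``ell0`` by a
factor ``1 + 2 M D gamma / (k ell0^2)`` to first order.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from scipy import integrate

from . import _kernels
from .errors import ConfigurationError, DegenerateSeparationError

__all__ = [
    "SpringParams",
    "LangevinParams",
    "DimerState",
    "Trajectory",
    "spring_force",
    "analytic_vacf",
    "analytic_dimer_diffusion",
    "stationary_length_density",
    "analytic_mean_length",
    "effective_rest_length_one_bath",
    "simulate_langevin_dimer",
]


@dataclasses.dataclass(frozen=True)
class SpringParams:
    """Harmonic dimer spring: Phi(R) = k (R - ell0)^2 / 2."""

    k: float
    ell0: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("spring constant k must be positive")
        if self.ell0 < 0:
            raise ValueError("rest length ell0 must be non-negative")

    def potential(self, R):
        return 0.5 * self.k * (np.asarray(R) - self.ell0) ** 2

    def dpotential(self, R):
        """Phi'(R) = k (R - ell0)."""
        return self.k * (np.asarray(R) - self.ell0)


@dataclasses.dataclass(frozen=True)
class LangevinParams:
    """Macroscopic solvent parameters: monomer mass M, diffusion D,
    friction gamma.  k_B T = M*D*gamma (Einstein-Smoluchowski)."""

    M: float
    D: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.M > 0 and self.D > 0 and self.gamma > 0):
            raise ValueError("M, D and gamma must all be positive")

    @property
    def kT(self) -> float:
        return self.M * self.D * self.gamma


@dataclasses.dataclass
class DimerState:
    """Positions and velocities of both monomers at time t."""

    X1: np.ndarray
    X2: np.ndarray
    V1: np.ndarray
    V2: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("X1", "X2", "V1", "V2"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} has non-finite components")
            setattr(self, name, v)

    @property
    def Rvec(self) -> np.ndarray:
        return self.X2 - self.X1

    @property
    def R(self) -> float:
        return float(np.linalg.norm(self.Rvec))

    @property
    def Xbar(self) -> np.ndarray:
        return 0.5 * (self.X1 + self.X2)

    @property
    def Vbar(self) -> np.ndarray:
        return 0.5 * (self.V1 + self.V2)


@dataclasses.dataclass
class Trajectory:
    """Sampled centre-of-mass kinematics of a dimer run.

    times are strictly increasing and uniformly spaced by construction of
    the simulators; ``V1`` (the first monomer's velocity) is retained
    because single-monomer statistics are needed to validate the explicit
    heat baths.
    """

    times: np.ndarray
    Xbar: np.ndarray
    Vbar: np.ndarray
    R: np.ndarray
    V1: Optional[np.ndarray] = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.Xbar = np.asarray(self.Xbar, dtype=float)
        self.Vbar = np.asarray(self.Vbar, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        n = len(self.times)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.Xbar.shape != (n, 3) or self.Vbar.shape != (n, 3) \
                or self.R.shape != (n,):
            raise ValueError("series lengths are inconsistent")
        if self.V1 is not None:
            self.V1 = np.asarray(self.V1, dtype=float)
            if self.V1.shape != (n, 3):
                raise ValueError("V1 length inconsistent")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_frame(self):
        import pandas as pd

        cols = {
            "t": self.times,
            "Xbar_x": self.Xbar[:, 0], "Xbar_y": self.Xbar[:, 1],
            "Xbar_z": self.Xbar[:, 2],
            "Vbar_x": self.Vbar[:, 0], "Vbar_y": self.Vbar[:, 1],
            "Vbar_z": self.Vbar[:, 2],
            "R": self.R,
        }
        if self.V1 is not None:
            cols.update({"V1_x": self.V1[:, 0], "V1_y": self.V1[:, 1],
                         "V1_z": self.V1[:, 2]})
        return pd.DataFrame(cols)

    def save(self, path) -> None:
        """Write the trajectory table; CSV (with a .json metadata sidecar)
        or HDF5 depending on the suffix."""
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            import h5py

            with h5py.File(path, "w") as f:
                f.create_dataset("times", data=self.times)
                f.create_dataset("Xbar", data=self.Xbar)
                f.create_dataset("Vbar", data=self.Vbar)
                f.create_dataset("R", data=self.R)
                if self.V1 is not None:
                    f.create_dataset("V1", data=self.V1)
                f.attrs["metadata"] = json.dumps(self.metadata)
        else:
            self.to_frame().to_csv(path, index=False)
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(self.metadata, indent=2))

    @classmethod
    def load(cls, path) -> "Trajectory":
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            import h5py

            with h5py.File(path, "r") as f:
                v1 = f["V1"][...] if "V1" in f else None
                return cls(times=f["times"][...], Xbar=f["Xbar"][...],
                           Vbar=f["Vbar"][...], R=f["R"][...], V1=v1,
                           metadata=json.loads(f.attrs.get("metadata", "{}")))
        import pandas as pd

        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        v1 = None
        if "V1_x" in df.columns:
            v1 = df[["V1_x", "V1_y", "V1_z"]].to_numpy()
        return cls(
            times=df["t"].to_numpy(),
            Xbar=df[["Xbar_x", "Xbar_y", "Xbar_z"]].to_numpy(),
            Vbar=df[["Vbar_x", "Vbar_y", "Vbar_z"]].to_numpy(),
            R=df["R"].to_numpy(), V1=v1, metadata=meta)


def _records_to_trajectory(rec: np.ndarray, metadata: dict) -> Trajectory:
    return Trajectory(times=rec[:, 0], Xbar=rec[:, 1:4], Vbar=rec[:, 4:7],
                      R=rec[:, 7], V1=rec[:, 8:11], metadata=metadata)


# ---------------------------------------------------------------------------
# forces and closed-form statistics
# ---------------------------------------------------------------------------

def spring_force(state: DimerState, spring: SpringParams):
    """Spring forces on the two monomers.

    Force on monomer 1 is Phi'(R) * R_hat with R_hat pointing from monomer 1
    to monomer 2 (so an extended spring, R > ell0, pulls the monomers
    together); monomer 2 takes the opposite force.
    """
    rvec = state.Rvec
    r = float(np.linalg.norm(rvec))
    if r == 0.0:
        raise DegenerateSeparationError(
            "monomer separation is zero: the force direction is undefined")
    f1 = spring.dpotential(r) * rvec / r
    return f1, -f1


def analytic_vacf(tau, p: LangevinParams):
    """Centre-of-mass velocity autocorrelation (D*gamma/2) exp(-gamma tau)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    out = 0.5 * p.D * p.gamma * np.exp(-p.gamma * tau)
    return float(out) if out.ndim == 0 else out


def analytic_dimer_diffusion(p: LangevinParams) -> float:
    """Green-Kubo integral of the analytic VACF: D/2."""
    return 0.5 * p.D


def _length_normalizer(spring: SpringParams, p: LangevinParams) -> float:
    """4 pi * integral_0^inf r^2 exp(-Phi(r)/(M D gamma)) dr."""
    theta = p.kT
    width = math.sqrt(theta / spring.k)
    lo = max(0.0, spring.ell0 - 25.0 * width)
    hi = spring.ell0 + 25.0 * width

    def integrand(r):
        return r * r * math.exp(-spring.potential(r) / theta)

    val, _ = integrate.quad(integrand, lo, hi,
                            points=[spring.ell0], limit=200)
    return 4.0 * math.pi * val


def stationary_length_density(R, spring: SpringParams, p: LangevinParams):
    """Stationary density rho(R) of the separation vector (overdamped limit).

    rho(R) = exp(-Phi(R)/(M D gamma)) / (4 pi int r^2 exp(-Phi/(M D gamma)) dr);
    the induced radial density is 4 pi R^2 rho(R).
    """
    R = np.asarray(R, dtype=float)
    norm = _length_normalizer(spring, p)
    out = np.exp(-spring.potential(R) / p.kT) / norm
    out = np.where(R < 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def analytic_mean_length(spring: SpringParams, p: LangevinParams) -> float:
    """First-order stiff-spring mean dimer length
    L_d = ell0 (1 + 2 M D gamma / (k ell0^2))."""
    if spring.ell0 == 0:
        raise ValueError("analytic mean length requires ell0 > 0")
    eps = p.kT / (spring.k * spring.ell0 ** 2)
    if eps > 0.1:
        warnings.warn(
            f"stiff-spring expansion parameter eps={eps:.3g} > 0.1; the "
            "first-order mean length may be inaccurate", stacklevel=2)
    return spring.ell0 * (1.0 + 2.0 * eps)


def effective_rest_length_one_bath(spring: SpringParams, gamma: float,
                                   omega_bar: float) -> float:
    """Mean dimer length when both monomers share one oscillator bath with
    identical couplings: L_d = 2 k pi ell0 / (2 k pi + gamma omega_bar).

    The shared bath contributes a net restoring force -(gamma*omega_bar/pi) R
    on the separation vector, shortening the effective rest length.
    """
    return 2.0 * spring.k * math.pi * spring.ell0 / (
        2.0 * spring.k * math.pi + gamma * omega_bar)


# ---------------------------------------------------------------------------
# Langevin simulator
# ---------------------------------------------------------------------------

def _derive_seeds(seed, n: int = 2):
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def thermal_dimer_state(spring: Optional[SpringParams], p: LangevinParams,
                        rng: np.random.Generator,
                        separation: Optional[float] = None) -> DimerState:
    """Monomers separated by the rest length along x, thermal velocities
    (per-component variance D*gamma = kT/M)."""
    if separation is None:
        separation = spring.ell0 if spring is not None else 1.0
    sd = math.sqrt(p.D * p.gamma)
    return DimerState(
        X1=np.zeros(3), X2=np.array([separation, 0.0, 0.0]),
        V1=rng.normal(0.0, sd, 3), V2=rng.normal(0.0, sd, 3))


def simulate_langevin_dimer(
    spring: Optional[SpringParams],
    p: LangevinParams,
    T: float,
    dt: float,
    seed: int = 0,
    integrator: Literal["euler_maruyama", "bbk"] = "euler_maruyama",
    sample_interval: Optional[float] = None,
    initial_state: Optional[DimerState] = None,
) -> Trajectory:
    """Simulate the macroscopic Langevin dimer.

    ``spring=None`` switches the spring off (two independent
    Ornstein-Uhlenbeck monomers). The noise increment per component is
    gamma*sqrt(2 D dt) * xi, so the stationary velocity variance is D*gamma
    per component.
    """
    if T <= 0:
        raise ConfigurationError("T must be positive")
    if dt * p.gamma >= 1.0:
        raise ConfigurationError(
            f"dt*gamma = {dt * p.gamma:.3g} >= 1: the step is unstable")
    if spring is not None and integrator == "euler_maruyama":
        # the stiff relative mode of the dimer is amplified by explicit
        # Euler-Maruyama unless dt < gamma*M/(2k)
        if 2.0 * spring.k * dt / (p.M * p.gamma) > 1.0:
            warnings.warn(
                "Euler-Maruyama amplifies the spring mode at this dt; "
                "use the bbk integrator or a smaller step", stacklevel=2)
    if sample_interval is None:
        sample_interval = dt
    record_every = max(1, int(round(sample_interval / dt)))
    n_steps = int(round(T / dt))

    s_init, s_kernel = _derive_seeds(seed)
    rng = np.random.default_rng(s_init)
    state = initial_state or thermal_dimer_state(spring, p, rng)
    X = np.stack([state.X1, state.X2]).astype(float)
    V = np.stack([state.V1, state.V2]).astype(float)
    k = spring.k if spring is not None else 0.0
    ell0 = spring.ell0 if spring is not None else 0.0

    rec, err = _kernels.run_langevin(
        X, V, k, ell0, p.M, p.D, p.gamma, dt, n_steps, record_every,
        integrator == "bbk", s_kernel)
    if err == _kernels.ERR_DEGENERATE:
        raise DegenerateSeparationError("monomer separation collapsed to zero")
    meta = {
        "model": "langevin", "integrator": integrator, "seed": int(seed),
        "dt": dt, "T": T, "sample_interval": record_every * dt,
        "params": {"M": p.M, "D": p.D, "gamma": p.gamma,
                   "k": k, "ell0": ell0},
    }
    return _records_to_trajectory(rec, meta)
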