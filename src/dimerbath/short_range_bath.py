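"""Collision MD of the dimer in a point-particle bath, inside co-moving
frames with open (stochastically replenished) boundaries.

Solvent is explicit only inside a cubic frame of side ``L`` that moves with
the dimer (or with a single monomer). Each fixed step consists of free
flight, exact rewind-and-exchange resolution of monomer-solvent overlaps,
a forward-Euler spring kick, frame recentring with deletion of particles
that left, and a stochastic boundary insertion whose position/velocity are
drawn from the flux of an ideal gas across the moving face. Insertions are
thinned near edges and corners, where summing the six per-face fluxes
over-counts, by an acceptance factor 1/j when the particle back-propagates
to a region with j coordinates outside the frame.

Three arrangements are supported: a single shared bath in one frame around
the dimer's centre of mass; two independent baths in frames centred on each
monomer; and a mixed-resolution variant where monomer 1 is simulated with
explicit solvent while monomer 2 follows the Langevin description.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal, Optional, Sequence, Tuple, Union

import numpy as np

from . import _kernels
from .errors import (CapacityError, ConfigurationError, IntegrityError,
                     MultipleCollisionError, StepSizeError)
from .model_core import (DimerState, LangevinParams, SpringParams, Trajectory,
                         _derive_seeds, _records_to_trajectory,
                         thermal_dimer_state)
from .samplers import ShortRangeBathParams

__all__ = [
    "SolventSet",
    "Frame",
    "elastic_collision",
    "resolve_collision",
    "influx_probability",
    "sample_incoming_particle",
    "overcount_acceptance",
    "initialize_short_range",
    "step_comoving",
    "step_mixed_resolution",
    "simulate_short_range",
    "run_empty_frame",
]

_MODE_CODES = {"one_bath": _kernels.MODE_ONE_BATH,
               "two_bath": _kernels.MODE_TWO_BATH,
               "mixed": _kernels.MODE_MIXED}

_ERRORS = {
    _kernels.ERR_INSIDE: (IntegrityError,
                          "a solvent particle was inside a monomer at the "
                          "start of a step; reduce dt"),
    _kernels.ERR_CAPACITY: (CapacityError, "solvent capacity exhausted"),
    _kernels.ERR_STEPSIZE: (StepSizeError,
                            "6*p_in exceeded 0.5; reduce dt"),
    _kernels.ERR_DEGENERATE: (IntegrityError,
                              "monomer separation collapsed to zero"),
    _kernels.ERR_INSERT: (IntegrityError,
                          "inserted particle back-propagated to the frame "
                          "interior"),
    _kernels.ERR_COLLISION: (MultipleCollisionError,
                             "collision resolution did not terminate; "
                             "reduce dt"),
}


def _raise_kernel_error(err: int) -> None:
    if err != _kernels.ERR_OK:
        exc, msg = _ERRORS[err]
        raise exc(msg)


@dataclasses.dataclass
class SolventSet:
    """Explicit bath particles: positions, velocities and a bath tag.

    bath_id is "shared" when particles collide with both monomers, or
    "bath1"/"bath2" when they belong to a single monomer's frame.
    """

    positions: np.ndarray
    velocities: np.ndarray
    bath_id: str = "shared"

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        if self.positions.size == 0:
            self.positions = np.empty((0, 3))
            self.velocities = np.empty((0, 3))
        if self.positions.shape != self.velocities.shape \
                or self.positions.shape[1:] != (3,):
            raise ValueError("positions/velocities must both be (N, 3)")
        if self.bath_id not in ("shared", "bath1", "bath2"):
            raise ValueError("bath_id must be shared, bath1 or bath2")

    @property
    def count(self) -> int:
        return self.positions.shape[0]


@dataclasses.dataclass
class Frame:
    """Co-moving cubic simulation window."""

    centre: np.ndarray
    L: float
    velocity: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float)
        if self.velocity is None:
            self.velocity = np.zeros(3)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.centre.shape != (3,) or self.velocity.shape != (3,):
            raise ValueError("centre and velocity must be 3-vectors")
        if not self.L > 0:
            raise ValueError("frame side L must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points) - self.centre
        return np.all(np.abs(rel) <= 0.5 * self.L, axis=1)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def elastic_collision(V_mono, v_solv, n_hat, mu: float):
    """Post-collision velocities of a monomer (mass M) and a point particle
    (mass m = M/mu) after a frictionless elastic collision with contact
    normal ``n_hat``. Tangential components are unchanged; the normal
    components undergo the mu-weighted exchange that conserves momentum and
    kinetic energy exactly."""
    n_hat = np.asarray(n_hat, dtype=float)
    if abs(np.linalg.norm(n_hat) - 1.0) > 1e-9:
        raise ValueError("n_hat must be a unit vector")
    V = np.array(V_mono, dtype=float)
    v = np.array(v_solv, dtype=float)
    _kernels._elastic_collision_inplace(V, v, n_hat, mu)
    return V, v


def resolve_collision(mono_pos, mono_vel, solv_pos, solv_vel, r0: float,
                      dt: float) -> Optional[Tuple[float, np.ndarray]]:
    """Rewind time and contact normal for an overlapping free-flight pair.

    Inputs are positions at the *end* of the free flight (time t + dt) and
    the constant velocities used for it. Returns None when the pair does not
    overlap; otherwise (tau, n_hat) with tau in (0, dt] such that rewinding
    both trajectories by tau leaves them just touching, and n_hat the
    outward unit normal at the contact point.
    """
    rel = np.asarray(solv_pos, dtype=float) - np.asarray(mono_pos, dtype=float)
    if np.dot(rel, rel) >= r0 * r0:
        return None
    w = np.asarray(solv_vel, dtype=float) - np.asarray(mono_vel, dtype=float)
    tau = _kernels._contact_rewind_tau(rel[0], rel[1], rel[2],
                                       w[0], w[1], w[2], r0)
    if tau < 0.0:
        raise IntegrityError("overlapping pair with no contact solution")
    if tau > dt * (1.0 + 1e-9):
        raise IntegrityError(
            "contact time precedes the step: the particle started inside "
            "the monomer")
    n_hat = (rel - w * tau)
    n_hat /= np.linalg.norm(n_hat)
    return float(tau), n_hat


def influx_probability(lambda_mu: float, sigma_mu: float, L: float,
                       dt: float, Vf_normal: float) -> float:
    """Per-step probability that a bath particle enters one face of the
    frame; ``Vf_normal`` is the frame velocity along that face's inward
    normal.

    The stepping scheme inserts at most one particle per frame per step, so
    it needs 6*p_in small: values above 0.1 draw a warning (multiple entries
    are being ignored a few percent of the time) and above 0.5 an error.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    p = _kernels._influx_probability(lambda_mu, sigma_mu, L, dt, Vf_normal)
    if 6.0 * p > 0.5:
        raise StepSizeError(
            f"6*p_in = {6 * p:.3g} > 0.5: reduce dt so that insertions stay "
            "rare within a step")
    if 6.0 * p > 0.1:
        warnings.warn(
            f"6*p_in = {6 * p:.3g} > 0.1: simultaneous boundary entries are "
            "being neglected a few percent of the time", stacklevel=2)
    return float(p)


def sample_incoming_particle(face: int, frame: Frame,
                             bath: ShortRangeBathParams, dt: float,
                             rng: np.random.Generator):
    """Position and velocity (lab coordinates) of one particle entering
    through ``face`` (0..5 = axis*2 + side, side 0 the low face).

    The depth past the face is sigma_mu*dt*sqrt(2) times an erfc-tail draw
    with beta = Vf_normal/(sigma_mu*sqrt(2)); transverse coordinates are
    uniform on the face; the inward-normal velocity component is a Gaussian
    conditioned to carry the particle to its depth within dt.
    """
    if face not in range(6):
        raise ValueError("face must be in 0..5")
    pos = np.empty(3)
    vel = np.empty(3)
    seed = int(rng.integers(1 << 31))
    _kernels._seed_and_sample_incoming(
        seed, frame.centre, frame.velocity, face // 2, face % 2,
        frame.L, bath.sigma_mu, dt, pos, vel)
    return pos, vel


def overcount_acceptance(y_rel, L: float) -> float:
    """Edge/corner thinning factor 1/j, with j the number of coordinates of
    the back-propagated position (relative to the frame centre) outside
    [-L/2, L/2]."""
    y_rel = np.asarray(y_rel, dtype=float)
    j = int(np.sum(np.abs(y_rel) > 0.5 * L))
    if j == 0:
        raise IntegrityError(
            "entering particle back-propagates to the frame interior")
    return 1.0 / j


# ---------------------------------------------------------------------------
# initialisation and stepping
# ---------------------------------------------------------------------------

def initialize_short_range(
    dimer: DimerState,
    frames: Union[Frame, Sequence[Frame]],
    bath: ShortRangeBathParams,
    rng: np.random.Generator,
    mode: Literal["one_bath", "two_bath", "mixed"] = "one_bath",
):
    """Populate frame(s) with a Poisson(lambda_mu * L^3) number of particles,
    uniform positions and Maxwell-Boltzmann velocities; particles overlapping
    a monomer they can collide with are removed."""
    if mode == "two_bath":
        if not (isinstance(frames, Sequence) and len(frames) == 2):
            raise ConfigurationError("two_bath mode needs two frames")
        out = []
        for i, fr in enumerate(frames):
            mono = dimer.X1 if i == 0 else dimer.X2
            out.append(_fill_frame(fr, bath, rng, [mono], f"bath{i + 1}"))
        return out
    fr = frames[0] if isinstance(frames, Sequence) else frames
    monomers = [dimer.X1, dimer.X2] if mode == "one_bath" else [dimer.X1]
    tag = "shared" if mode == "one_bath" else "bath1"
    return _fill_frame(fr, bath, rng, monomers, tag)


def _fill_frame(frame: Frame, bath: ShortRangeBathParams,
                rng: np.random.Generator, monomers, tag: str) -> SolventSet:
    n = rng.poisson(bath.lambda_mu * frame.L ** 3)
    pos = frame.centre + rng.uniform(-0.5, 0.5, size=(n, 3)) * frame.L
    vel = rng.normal(0.0, bath.sigma_mu, size=(n, 3))
    keep = np.ones(n, dtype=bool)
    for mono in monomers:
        keep &= np.linalg.norm(pos - mono, axis=1) >= bath.r0
    return SolventSet(positions=pos[keep], velocities=vel[keep], bath_id=tag)


def _pack_solvent(solvent, mode: str, extra: int = 64):
    if mode == "two_bath":
        sets = list(solvent)
        n = sum(s.count for s in sets)
        cap = 2 * n + extra
        sol = np.zeros((cap, 3))
        svel = np.zeros((cap, 3))
        stag = np.zeros(cap, dtype=np.int64)
        ofs = 0
        for i, s in enumerate(sets):
            sol[ofs:ofs + s.count] = s.positions
            svel[ofs:ofs + s.count] = s.velocities
            stag[ofs:ofs + s.count] = i
            ofs += s.count
        return sol, svel, stag, n
    s = solvent
    cap = 2 * s.count + extra
    sol = np.zeros((cap, 3))
    svel = np.zeros((cap, 3))
    stag = np.zeros(cap, dtype=np.int64)
    sol[:s.count] = s.positions
    svel[:s.count] = s.velocities
    return sol, svel, stag, s.count


def _unpack_solvent(sol, svel, stag, n, mode: str):
    if mode == "two_bath":
        out = []
        for i in range(2):
            m = stag[:n] == i
            out.append(SolventSet(positions=sol[:n][m].copy(),
                                  velocities=svel[:n][m].copy(),
                                  bath_id=f"bath{i + 1}"))
        return out
    tag = "shared" if mode == "one_bath" else "bath1"
    return SolventSet(positions=sol[:n].copy(), velocities=svel[:n].copy(),
                      bath_id=tag)


def _run(dimer, solvent, frames, spring, bath, p, dt, n_steps, record_every,
         mode, seed):
    X = np.stack([dimer.X1, dimer.X2]).astype(float)
    V = np.stack([dimer.V1, dimer.V2]).astype(float)
    sol, svel, stag, n0 = _pack_solvent(solvent, mode)
    frame_list = frames if isinstance(frames, Sequence) else [frames]
    fc = np.stack([fr.centre for fr in frame_list]).astype(float)
    L = frame_list[0].L
    rec, nser, vsamp, counters, n, err = _kernels.run_short_range(
        X, V, sol, svel, stag, n0, fc, _MODE_CODES[mode], np.zeros(3),
        bath.r0, bath.mu, bath.lambda_mu, bath.sigma_mu, L,
        spring.k if spring is not None else 0.0,
        spring.ell0 if spring is not None else 0.0,
        p.M, p.D, p.gamma, dt, n_steps, record_every, seed)
    _raise_kernel_error(err)
    new_dimer = DimerState(X1=X[0], X2=X[1], V1=V[0], V2=V[1],
                           t=dimer.t + n_steps * dt)
    new_solvent = _unpack_solvent(sol, svel, stag, n, mode)
    new_frames = []
    for g, fr in enumerate(frame_list):
        vfr = (fc[g] - frame_list[g].centre) / (n_steps * dt) if n_steps else fr.velocity
        new_frames.append(Frame(centre=fc[g].copy(), L=L, velocity=vfr))
    counter_dict = dict(zip(
        ["collisions", "insertions", "deletions", "insertion_attempts",
         "hacc_rejects", "overlap_rejects", "max_N"],
        (int(c) for c in counters)))
    return new_dimer, new_solvent, new_frames, rec, nser, vsamp, counter_dict


def _check_frame_geometry(L: float, bath: ShortRangeBathParams, mode: str,
                          ell0: float) -> None:
    if L <= 2.0 * bath.r0:
        raise ConfigurationError("frame side L must exceed the monomer "
                                 "diameter 2*r0")
    if mode == "one_bath" and L < ell0 + 2.0 * bath.r0:
        raise ConfigurationError(
            "one-bath frame must enclose the whole dimer: need "
            "L >= ell0 + 2*r0")


def step_comoving(dimer: DimerState, solvent, frame, spring: SpringParams,
                  bath: ShortRangeBathParams, dt: float,
                  rng: np.random.Generator,
                  frame_anchor: Literal["com", "monomer1", "monomer2"] = "com"):
    """One iteration of the co-moving-frame algorithm.

    With ``frame_anchor="com"`` a single shared bath (one frame around the
    centre of mass) is stepped; passing two frames and two solvent sets
    steps the two-bath arrangement, where each frame is anchored on its
    monomer. Returns the updated (dimer, solvent, frame(s)).
    """
    p = LangevinParams(M=1.0, D=bath.D, gamma=bath.gamma)
    two = isinstance(solvent, (list, tuple))
    mode = "two_bath" if two else "one_bath"
    if not two and frame_anchor != "com":
        raise ConfigurationError(
            "single-frame stepping is anchored on the centre of mass; "
            "monomer anchoring applies to the two-bath arrangement")
    L = (frame[0].L if two else frame.L)
    _check_frame_geometry(L, bath, mode, spring.ell0)
    seed = int(rng.integers(1 << 31))
    new_dimer, new_solvent, new_frames, *_ = _run(
        dimer, solvent, frame, spring, bath, p, dt, 1, 1, mode, seed)
    return new_dimer, new_solvent, (new_frames if two else new_frames[0])


def step_mixed_resolution(dimer: DimerState, solvent: SolventSet,
                          frame: Frame, spring: SpringParams,
                          bath: ShortRangeBathParams,
                          langevin: LangevinParams, dt: float,
                          rng: np.random.Generator):
    """One mixed-resolution iteration: monomer 1 by collision MD inside its
    co-moving frame, monomer 2 by an Euler-Maruyama Langevin step."""
    _check_frame_geometry(frame.L, bath, "mixed", spring.ell0)
    seed = int(rng.integers(1 << 31))
    new_dimer, new_solvent, new_frames, *_ = _run(
        dimer, solvent, frame, spring, bath, langevin, dt, 1, 1, "mixed",
        seed)
    return new_dimer, new_solvent, new_frames[0]


def simulate_short_range(
    mode: Literal["one_bath", "two_bath", "mixed"],
    spring: SpringParams,
    bath: ShortRangeBathParams,
    T: float,
    dt: float,
    L: float,
    seed: int = 0,
    M: float = 1.0,
    sample_interval: Optional[float] = None,
) -> Trajectory:
    """Full run of the short-range heat-bath model.

    The dimer starts at separation ell0 with thermal velocities; frames are
    populated from the bath's equilibrium statistics. Event counters are
    stored in the trajectory metadata.
    """
    _check_frame_geometry(L, bath, mode, spring.ell0)
    p = LangevinParams(M=M, D=bath.D, gamma=bath.gamma)
    influx_probability(bath.lambda_mu, bath.sigma_mu, L, dt, 0.0)
    if sample_interval is None:
        sample_interval = max(dt, 1e-3)
    record_every = max(1, int(round(sample_interval / dt)))
    n_steps = int(round(T / dt))

    s_init, s_kernel = _derive_seeds(seed)
    rng = np.random.default_rng(s_init)
    dimer = thermal_dimer_state(spring, p, rng)
    if mode == "one_bath":
        # centre the dimer on the frame origin
        shift = dimer.Xbar
        dimer = DimerState(X1=dimer.X1 - shift, X2=dimer.X2 - shift,
                           V1=dimer.V1, V2=dimer.V2)
        frames: Union[Frame, list] = Frame(centre=np.zeros(3), L=L)
    elif mode == "two_bath":
        frames = [Frame(centre=dimer.X1.copy(), L=L),
                  Frame(centre=dimer.X2.copy(), L=L)]
    else:
        frames = Frame(centre=dimer.X1.copy(), L=L)
    solvent = initialize_short_range(dimer, frames, bath, rng, mode=mode)

    _, _, _, rec, nser, _, counters = _run(
        dimer, solvent, frames, spring, bath, p, dt, n_steps, record_every,
        mode, s_kernel)
    meta = {
        "model": "short_range", "mode": mode, "seed": int(seed), "dt": dt,
        "T": T, "sample_interval": record_every * dt,
        "params": {"M": M, "D": bath.D, "gamma": bath.gamma, "k": spring.k,
                   "ell0": spring.ell0, "r0": bath.r0, "mu": bath.mu,
                   "L": L, "lambda_mu": bath.lambda_mu,
                   "sigma_mu": bath.sigma_mu},
        "counters": counters,
        "mean_N": float(np.mean(nser)),
    }
    return _records_to_trajectory(rec, meta)


def run_empty_frame(bath: ShortRangeBathParams, L: float, dt: float,
                    n_steps: int, drag_velocity, seed: int = 0,
                    record_every: int = 1000):
    """Diagnostic run of the frame machinery with no monomers.

    A frame is filled from the bath's equilibrium state and dragged at a
    constant velocity; deletion and boundary insertion then have to hold the
    particle count Poisson(lambda_mu*L^3) and the velocities
    Maxwell-Boltzmann. Returns (times, N_series, velocity_samples) where
    velocity_samples holds one randomly chosen particle velocity per record.
    """
    s_init, s_kernel = _derive_seeds(seed)
    rng = np.random.default_rng(s_init)
    frame = Frame(centre=np.zeros(3), L=L)
    solvent = _fill_frame(frame, bath, rng, [], "shared")
    sol, svel, stag, n0 = _pack_solvent(solvent, "one_bath")
    X = np.zeros((2, 3))
    V = np.zeros((2, 3))
    fc = np.zeros((1, 3))
    rec, nser, vsamp, counters, n, err = _kernels.run_short_range(
        X, V, sol, svel, stag, n0, fc, _kernels.MODE_EMPTY,
        np.asarray(drag_velocity, dtype=float),
        bath.r0, bath.mu, bath.lambda_mu, bath.sigma_mu, L,
        0.0, 0.0, 1.0, bath.D, bath.gamma, dt, n_steps, record_every,
        s_kernel)
    _raise_kernel_error(err)
    return rec[:, 0], nser, vsamp
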