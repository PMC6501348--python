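"""Compiled inner loops for the samplers and the three simulation engines.

Everything in this module operates on plain float64 arrays so that numba can
compile it; the public modules wrap these kernels with validated dataclasses.

Randomness: kernels draw from numba's internal ``np.random`` state, which is
separate from the interpreter's. Every stochastic kernel takes an explicit
integer ``seed`` and seeds that state on entry, so a kernel call is a pure
function of its arguments.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SQRT_PI = math.sqrt(math.pi)
SQRT_2 = math.sqrt(2.0)

# error codes shared by the simulation kernels
ERR_OK = 0
ERR_INSIDE = 1      # particle overlapped a monomer already at step start
ERR_CAPACITY = 2    # solvent array capacity exhausted
ERR_STEPSIZE = 3    # 6*p_in exceeded 0.5
ERR_DEGENERATE = 4  # monomer separation collapsed to zero
ERR_INSERT = 5      # inserted particle back-propagates to inside the frame
ERR_COLLISION = 6   # collision resolution failed to terminate


# ---------------------------------------------------------------------------
# special functions
# ---------------------------------------------------------------------------

@njit(cache=True)
def _erfcx_pos(x):
    # scaled complementary error function exp(x^2)*erfc(x) for x >= 0
    if x < 20.0:
        return math.exp(x * x) * math.erfc(x)
    # asymptotic series; truncation error below 1e-14 for x >= 20
    inv = 1.0 / (2.0 * x * x)
    s = 1.0
    term = 1.0
    for k in range(1, 13):
        term *= -(2 * k - 1) * inv
        s += term
    return s / (x * SQRT_PI)


@njit(cache=True)
def _erfcx(x):
    # valid for x > -26 (the reflection term overflows beyond that)
    if x >= 0.0:
        return _erfcx_pos(x)
    return 2.0 * math.exp(x * x) - _erfcx_pos(-x)


@njit(cache=True)
def _log_erfc(x):
    if x < -6.0:
        # erfc(x) = 2 - erfc(-x) with erfc(-x) < 1e-17
        return math.log(2.0)
    return math.log(_erfcx(x)) - x * x


# ---------------------------------------------------------------------------
# acceptance-rejection sampler for densities proportional to erfc(z + beta)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ar_log_constants(beta):
    """Envelope constants (a1, log a2) of the erfc-tail sampler."""
    if beta >= 0.0:
        a1 = 0.5 * SQRT_PI * _erfcx_pos(beta)
        log_a2 = beta * beta - math.log(_erfcx_pos(beta))
    else:
        a1 = 0.5 * SQRT_PI
        log_a2 = 2.0 * beta / SQRT_PI
    return a1, log_a2


@njit(cache=True)
def _erfc_tail_draw(beta, a1, log_a2):
    """One exact draw from p(z) ∝ erfc(z+beta), z >= 0.

    Exponential proposal of mean a1; acceptance test evaluated in log space
    so that large |beta| cannot overflow. Returns (sample, n_proposals);
    sample is -1.0 if the rejection loop failed to accept (internal
    inconsistency guard).
    """
    n = 0
    while n < 1000000:
        n += 1
        e1 = np.random.random()
        e2 = np.random.random()
        z = -a1 * math.log(e1)
        if math.log(e1) + math.log(e2) < log_a2 + _log_erfc(z + beta):
            return z, n
    return -1.0, n


@njit(cache=True)
def _erfc_tail_batch(beta, a1, log_a2, n, seed):
    np.random.seed(seed)
    out = np.empty(n)
    proposals = 0
    for i in range(n):
        z, m = _erfc_tail_draw(beta, a1, log_a2)
        proposals += m
        if z < 0.0:
            out[i] = np.nan
        else:
            out[i] = z
    return out, proposals


@njit(cache=True)
def _truncnorm_tail(a):
    """Standard normal conditioned on X >= a (a may be -inf)."""
    if a < 0.3:
        while True:
            x = np.random.normal()
            if x >= a:
                return x
    # Robert's translated-exponential acceptance-rejection for the far tail
    alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        x = a - math.log(np.random.random()) / alpha
        d = x - alpha
        if math.log(np.random.random()) < -0.5 * d * d:
            return x


@njit(cache=True)
def _truncnorm_tail_batch(a, n, seed):
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _truncnorm_tail(a)
    return out


# ---------------------------------------------------------------------------
# short-range (collisional) heat bath primitives
# ---------------------------------------------------------------------------

@njit(cache=True)
def _influx_probability(lam, sigma, L, dt, v):
    """Mean number of bath particles entering one frame face in dt.

    v is the frame velocity component along the face's inward normal.
    """
    p = lam * L * L * dt * (
        sigma / math.sqrt(2.0 * math.pi) * math.exp(-v * v / (2.0 * sigma * sigma))
        - 0.5 * v * math.erfc(v / (sigma * SQRT_2))
    )
    if p < 0.0:  # cancellation guard for v >> sigma
        return 0.0
    return p


@njit(cache=True)
def _elastic_collision_inplace(V, v, n, mu):
    """Frictionless elastic collision, applied in place.

    V: monomer velocity (3,), v: point-particle velocity (3,), n: unit
    normal at the contact point, mu: mass ratio M/m. Only the components
    along n are exchanged (mu-weighted); tangential parts are untouched.
    """
    Vn = V[0] * n[0] + V[1] * n[1] + V[2] * n[2]
    vn = v[0] * n[0] + v[1] * n[1] + v[2] * n[2]
    c = (mu - 1.0) / (mu + 1.0)
    Vn_new = c * Vn + 2.0 / (mu + 1.0) * vn
    vn_new = -c * vn + 2.0 * mu / (mu + 1.0) * Vn
    for d in range(3):
        V[d] += (Vn_new - Vn) * n[d]
        v[d] += (vn_new - vn) * n[d]


@njit(cache=True)
def _contact_rewind_tau(rx, ry, rz, wx, wy, wz, r0):
    """Rewind time tau at which |r - w*tau| = r0.

    r, w are the solvent-minus-monomer relative position and velocity at the
    end of the free flight (overlapping: |r| < r0). The unique positive root
    of the contact quadratic is returned; -1.0 signals no solution.
    """
    w2 = wx * wx + wy * wy + wz * wz
    if w2 <= 0.0:
        return -1.0
    rw = rx * wx + ry * wy + rz * wz
    r2 = rx * rx + ry * ry + rz * rz
    disc = rw * rw - w2 * (r2 - r0 * r0)
    if disc < 0.0:
        return -1.0
    return (rw + math.sqrt(disc)) / w2


@njit(cache=True)
def _sample_incoming(fc, vf, axis, side, L, sigma, dt, pos, vel):
    """Sample position/velocity of one entering particle (lab coordinates).

    fc: frame centre at the end of the step; vf: frame velocity over the
    step; face = (axis, side) with side 0 the low face. Fills pos, vel.
    """
    sgn = 1.0 if side == 0 else -1.0
    vin = sgn * vf[axis]  # frame velocity along the inward normal
    beta = vin / (sigma * SQRT_2)
    a1, log_a2 = _ar_log_constants(beta)
    z, _ = _erfc_tail_draw(beta, a1, log_a2)
    z1 = sigma * dt * SQRT_2 * z
    # inward-normal lab velocity component, conditioned so the particle can
    # reach depth z1 within dt
    thr = z1 / dt + vin
    wn = sigma * _truncnorm_tail(thr / sigma)
    for d in range(3):
        if d == axis:
            pos[d] = fc[d] + sgn * (z1 - 0.5 * L)
            vel[d] = sgn * wn
        else:
            pos[d] = fc[d] - 0.5 * L + L * np.random.random()
            vel[d] = sigma * np.random.normal()
    return z1


@njit(cache=True)
def _seed_and_sample_incoming(seed, fc, vf, axis, side, L, sigma, dt,
                              pos, vel):
    np.random.seed(seed)
    return _sample_incoming(fc, vf, axis, side, L, sigma, dt, pos, vel)


# ---------------------------------------------------------------------------
# Langevin reference integrators
# ---------------------------------------------------------------------------

@njit(cache=True)
def _spring_coeff(X, k, ell0):
    """Returns (f, r, err): force on monomer 0 is f*(X1-X0), i.e.
    f = k(r-ell0)/r so that f*(X1-X0) = Phi'(r) * unit vector."""
    rx = X[1, 0] - X[0, 0]
    ry = X[1, 1] - X[0, 1]
    rz = X[1, 2] - X[0, 2]
    r = math.sqrt(rx * rx + ry * ry + rz * rz)
    if k == 0.0:
        return 0.0, r, ERR_OK
    if r <= 0.0:
        return 0.0, r, ERR_DEGENERATE
    return k * (r - ell0) / r, r, ERR_OK


@njit(cache=True)
def _record(rec, irec, t, X, V):
    rec[irec, 0] = t
    rx = X[1, 0] - X[0, 0]
    ry = X[1, 1] - X[0, 1]
    rz = X[1, 2] - X[0, 2]
    for d in range(3):
        rec[irec, 1 + d] = 0.5 * (X[0, d] + X[1, d])
        rec[irec, 4 + d] = 0.5 * (V[0, d] + V[1, d])
        rec[irec, 8 + d] = V[0, d]
    rec[irec, 7] = math.sqrt(rx * rx + ry * ry + rz * rz)


@njit(cache=True)
def run_langevin(X, V, k, ell0, M, D, gamma, dt, n_steps, record_every,
                 use_bbk, seed):
    """Macroscopic Langevin dimer, Euler-Maruyama or BBK.

    X, V: (2,3) initial state, updated in place. Records columns
    [t, Xbar(3), Vbar(3), R, V1(3)] every record_every steps.
    """
    np.random.seed(seed)
    n_rec = n_steps // record_every + 1
    rec = np.empty((n_rec, 11))
    _record(rec, 0, 0.0, X, V)
    irec = 1
    err = ERR_OK

    if use_bbk:
        amp = gamma * math.sqrt(2.0 * D / dt)
        A = np.empty((2, 3))
        f, r, err = _spring_coeff(X, k, ell0)
        if err == ERR_OK:
            for d in range(3):
                fd = f * (X[1, d] - X[0, d])
                A[0, d] = fd / M - gamma * V[0, d] + amp * np.random.normal()
                A[1, d] = -fd / M - gamma * V[1, d] + amp * np.random.normal()
            denom = 1.0 + 0.5 * gamma * dt
            for step in range(1, n_steps + 1):
                for i in range(2):
                    for d in range(3):
                        V[i, d] += 0.5 * dt * A[i, d]
                        X[i, d] += dt * V[i, d]
                f, r, err = _spring_coeff(X, k, ell0)
                if err != ERR_OK:
                    break
                for i in range(2):
                    s = 1.0 if i == 0 else -1.0
                    for d in range(3):
                        fd = s * f * (X[1, d] - X[0, d]) / M
                        xi = np.random.normal()
                        V[i, d] = (V[i, d] + 0.5 * dt * (fd + amp * xi)) / denom
                        A[i, d] = fd - gamma * V[i, d] + amp * xi
                if step % record_every == 0:
                    _record(rec, irec, step * dt, X, V)
                    irec += 1
    else:
        amp = gamma * math.sqrt(2.0 * D * dt)
        for step in range(1, n_steps + 1):
            f, r, err = _spring_coeff(X, k, ell0)
            if err != ERR_OK:
                break
            for i in range(2):
                s = 1.0 if i == 0 else -1.0
                for d in range(3):
                    fd = s * f * (X[1, d] - X[0, d]) / M
                    vnew = (V[i, d] + (fd - gamma * V[i, d]) * dt
                            + amp * np.random.normal())
                    X[i, d] += V[i, d] * dt
                    V[i, d] = vnew
            if step % record_every == 0:
                _record(rec, irec, step * dt, X, V)
                irec += 1
    return rec[:irec], err


# ---------------------------------------------------------------------------
# short-range heat bath: event-handling collision MD in a co-moving frame
# ---------------------------------------------------------------------------

# modes of run_short_range
MODE_ONE_BATH = 0   # shared solvent, frame centred on the dimer's COM
MODE_TWO_BATH = 1   # independent solvent per monomer, frames on the monomers
MODE_MIXED = 2      # monomer 0 in explicit solvent, monomer 1 Langevin (EM)
MODE_EMPTY = 3      # no monomers; frame dragged at a prescribed velocity


@njit(cache=True)
def run_short_range(X, V, sol, svel, stag, n0, fc, mode, vdrag,
                    r0, mu, lam, sigma, L,
                    k, ell0, M, D, gamma,
                    dt, n_steps, record_every, seed):
    """Fixed-step collision MD of the dimer in the co-moving frame(s).

    One iteration: free flight; pairwise rewind/elastic exchange for any
    solvent particle whose free-flight position overlaps a monomer it can
    collide with; forward-Euler spring kick on monomer velocities (the
    coarse monomer takes an Euler-Maruyama Langevin step in MODE_MIXED);
    frame recentring and culling; stochastic boundary insertion thinned by
    the edge/corner overcount factor.

    Returns (records, N_series, velocity_samples, counters, n_final, err).
    records columns: [t, Xbar(3), Vbar(3), R, V1(3)].
    counters: [collisions, insertions, deletions, insertion_attempts,
               hacc_rejects, overlap_rejects, max_N].
    """
    np.random.seed(seed)
    cap = sol.shape[0]
    n = n0
    n_frames = 2 if mode == MODE_TWO_BATH else 1
    has_monomers = mode != MODE_EMPTY

    n_rec = n_steps // record_every + 1
    rec = np.zeros((n_rec, 11))
    nser = np.zeros(n_rec, dtype=np.int64)
    vsamp = np.full((n_rec, 3), np.nan)
    counters = np.zeros(7, dtype=np.int64)

    fc_old = fc.copy()
    vf = np.zeros((n_frames, 3))
    pos_new = np.empty(3)
    vel_new = np.empty(3)
    nhat = np.empty(3)

    if has_monomers:
        _record(rec, 0, 0.0, X, V)
    nser[0] = n
    if n > 0:
        jj = int(np.random.random() * n)
        for d in range(3):
            vsamp[0, d] = svel[jj, d]
    irec = 1
    err = ERR_OK
    amp_em = gamma * math.sqrt(2.0 * D * dt)
    half = 0.5 * L

    for step in range(1, n_steps + 1):
        # [S1] free flight
        if has_monomers:
            for i in range(2):
                for d in range(3):
                    X[i, d] += V[i, d] * dt
        for j in range(n):
            for d in range(3):
                sol[j, d] += svel[j, d] * dt

        # [S2] collisions: resolve overlapping pairs in contact-time order
        if has_monomers:
            n_pass = 0
            while True:
                n_pass += 1
                if n_pass > 100:
                    err = ERR_COLLISION
                    break
                best_j = -1
                best_i = -1
                best_tau = -1.0
                for j in range(n):
                    if mode == MODE_ONE_BATH:
                        i_lo, i_hi = 0, 2
                    elif mode == MODE_TWO_BATH:
                        i_lo, i_hi = stag[j], stag[j] + 1
                    else:
                        i_lo, i_hi = 0, 1
                    for i in range(i_lo, i_hi):
                        rx = sol[j, 0] - X[i, 0]
                        ry = sol[j, 1] - X[i, 1]
                        rz = sol[j, 2] - X[i, 2]
                        if rx * rx + ry * ry + rz * rz < r0 * r0:
                            tau = _contact_rewind_tau(
                                rx, ry, rz,
                                svel[j, 0] - V[i, 0],
                                svel[j, 1] - V[i, 1],
                                svel[j, 2] - V[i, 2], r0)
                            if tau < 0.0:
                                err = ERR_COLLISION
                                break
                            # earliest forward contact = largest rewind
                            if tau > best_tau:
                                best_tau = tau
                                best_j = j
                                best_i = i
                    if err != ERR_OK:
                        break
                if err != ERR_OK or best_j < 0:
                    break
                if best_tau > dt * (1.0 + 1e-9):
                    err = ERR_INSIDE
                    break
                j = best_j
                i = best_i
                tau = best_tau
                for d in range(3):
                    sol[j, d] -= svel[j, d] * tau
                    X[i, d] -= V[i, d] * tau
                nrm = 0.0
                for d in range(3):
                    nhat[d] = sol[j, d] - X[i, d]
                    nrm += nhat[d] * nhat[d]
                nrm = math.sqrt(nrm)
                for d in range(3):
                    nhat[d] /= nrm
                _elastic_collision_inplace(V[i], svel[j], nhat, mu)
                for d in range(3):
                    sol[j, d] += svel[j, d] * tau
                    X[i, d] += V[i, d] * tau
                counters[0] += 1
            if err != ERR_OK:
                break

            # [S3] monomer velocity updates
            f, r, serr = _spring_coeff(X, k, ell0)
            if serr != ERR_OK:
                err = serr
                break
            if mode == MODE_MIXED:
                for d in range(3):
                    fd = f * (X[1, d] - X[0, d]) / M
                    V[0, d] += fd * dt
                    V[1, d] += (-fd - gamma * V[1, d]) * dt \
                        + amp_em * np.random.normal()
            else:
                for d in range(3):
                    fd = f * (X[1, d] - X[0, d]) / M
                    V[0, d] += fd * dt
                    V[1, d] -= fd * dt

        # [S4]-[S5] recentre frame(s), cull leavers, frame velocity
        if mode == MODE_ONE_BATH:
            for d in range(3):
                fc[0, d] = 0.5 * (X[0, d] + X[1, d])
        elif mode == MODE_TWO_BATH:
            for i in range(2):
                for d in range(3):
                    fc[i, d] = X[i, d]
        elif mode == MODE_MIXED:
            for d in range(3):
                fc[0, d] = X[0, d]
        else:
            for d in range(3):
                fc[0, d] = fc_old[0, d] + vdrag[d] * dt
        for g in range(n_frames):
            for d in range(3):
                vf[g, d] = (fc[g, d] - fc_old[g, d]) / dt
        j = 0
        while j < n:
            g = stag[j] if mode == MODE_TWO_BATH else 0
            out = False
            for d in range(3):
                if abs(sol[j, d] - fc[g, d]) > half:
                    out = True
                    break
            if out:
                n -= 1
                for d in range(3):
                    sol[j, d] = sol[n, d]
                    svel[j, d] = svel[n, d]
                stag[j] = stag[n]
                counters[2] += 1
            else:
                j += 1

        # [S6] boundary insertion, one attempt per frame per step
        for g in range(n_frames):
            r1 = np.random.random()
            face = int(np.random.random() * 6.0)
            if face > 5:
                face = 5
            axis = face // 2
            side = face - 2 * axis
            sgn = 1.0 if side == 0 else -1.0
            vin = sgn * vf[g, axis]
            p_in = _influx_probability(lam, sigma, L, dt, vin)
            if 6.0 * p_in > 0.5:
                err = ERR_STEPSIZE
                break
            if r1 < 6.0 * p_in:
                counters[3] += 1
                _sample_incoming(fc[g], vf[g], axis, side, L, sigma, dt,
                                 pos_new, vel_new)
                # overcount correction: back-propagate to the start of the
                # step and count coordinates outside the old frame
                j_out = 0
                for d in range(3):
                    y = pos_new[d] - vel_new[d] * dt - fc_old[g, d]
                    if abs(y) > half:
                        j_out += 1
                if j_out == 0:
                    err = ERR_INSERT
                    break
                if np.random.random() * j_out < 1.0:
                    overlap = False
                    if has_monomers:
                        if mode == MODE_ONE_BATH:
                            i_lo, i_hi = 0, 2
                        elif mode == MODE_TWO_BATH:
                            i_lo, i_hi = g, g + 1
                        else:
                            i_lo, i_hi = 0, 1
                        for i in range(i_lo, i_hi):
                            d2 = 0.0
                            for d in range(3):
                                dd = pos_new[d] - X[i, d]
                                d2 += dd * dd
                            if d2 < r0 * r0:
                                overlap = True
                                break
                    if overlap:
                        counters[5] += 1
                    else:
                        if n >= cap:
                            err = ERR_CAPACITY
                            break
                        for d in range(3):
                            sol[n, d] = pos_new[d]
                            svel[n, d] = vel_new[d]
                        stag[n] = g
                        n += 1
                        counters[1] += 1
                else:
                    counters[4] += 1
        if err != ERR_OK:
            break

        if n > counters[6]:
            counters[6] = n
        for g in range(n_frames):
            for d in range(3):
                fc_old[g, d] = fc[g, d]

        if step % record_every == 0:
            if has_monomers:
                _record(rec, irec, step * dt, X, V)
            else:
                rec[irec, 0] = step * dt
            nser[irec] = n
            if n > 0:
                jj = int(np.random.random() * n)
                if jj >= n:
                    jj = n - 1
                for d in range(3):
                    vsamp[irec, d] = svel[jj, d]
            irec += 1

    return rec[:irec], nser[:irec], vsamp[:irec], counters, n, err


# ---------------------------------------------------------------------------
# long-range (harmonic-oscillator) heat bath
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lr_accels(X, xo, kk1, kk2, aa1, aa2, m, M, k, ell0, A, ao):
    """Monomer and oscillator accelerations for the oscillator bath.

    Monomer i: spring force plus sum_j k_{i,j} alpha_{i,j} (x_j - alpha_{i,j} X_i).
    Oscillator j: -k_{1,j}(x_j - a_{1,j}X_1) - k_{2,j}(x_j - a_{2,j}X_2), over m.
    """
    f, r, err = _spring_coeff(X, k, ell0)
    if err != ERR_OK:
        return err
    for d in range(3):
        fd = f * (X[1, d] - X[0, d])
        A[0, d] = fd / M
        A[1, d] = -fd / M
    N = xo.shape[0]
    for j in range(N):
        for d in range(3):
            d1 = xo[j, d] - aa1[j] * X[0, d]
            d2 = xo[j, d] - aa2[j] * X[1, d]
            A[0, d] += kk1[j] * aa1[j] * d1 / M
            A[1, d] += kk2[j] * aa2[j] * d2 / M
            ao[j, d] = (-kk1[j] * d1 - kk2[j] * d2) / m
    return ERR_OK


@njit(cache=True)
def run_long_range_full(X, V, xo, vo, kk1, kk2, aa1, aa2, m, M, k, ell0,
                        dt, n_steps, record_every):
    """Deterministic velocity-Verlet run of dimer + oscillator bath."""
    n_rec = n_steps // record_every + 1
    rec = np.empty((n_rec, 11))
    _record(rec, 0, 0.0, X, V)
    irec = 1
    N = xo.shape[0]
    A = np.empty((2, 3))
    ao = np.empty((N, 3))
    err = _lr_accels(X, xo, kk1, kk2, aa1, aa2, m, M, k, ell0, A, ao)
    if err != ERR_OK:
        return rec[:1], err
    for step in range(1, n_steps + 1):
        for i in range(2):
            for d in range(3):
                V[i, d] += 0.5 * dt * A[i, d]
                X[i, d] += dt * V[i, d]
        for j in range(N):
            for d in range(3):
                vo[j, d] += 0.5 * dt * ao[j, d]
                xo[j, d] += dt * vo[j, d]
        err = _lr_accels(X, xo, kk1, kk2, aa1, aa2, m, M, k, ell0, A, ao)
        if err != ERR_OK:
            break
        for i in range(2):
            for d in range(3):
                V[i, d] += 0.5 * dt * A[i, d]
        for j in range(N):
            for d in range(3):
                vo[j, d] += 0.5 * dt * ao[j, d]
        if step % record_every == 0:
            _record(rec, irec, step * dt, X, V)
            irec += 1
    return rec[:irec], err


@njit(cache=True)
def run_long_range_mixed(X, V, xo, vo, kk, aa, m, M, k, ell0, D, gamma,
                         dt, n_steps, record_every, seed):
    """Mixed resolution: monomer 0 + its oscillators by velocity Verlet,
    monomer 1 by BBK inside the same half-kick structure."""
    np.random.seed(seed)
    n_rec = n_steps // record_every + 1
    rec = np.empty((n_rec, 11))
    _record(rec, 0, 0.0, X, V)
    irec = 1
    N = xo.shape[0]
    zeros = np.zeros(N)
    A = np.empty((2, 3))
    ao = np.empty((N, 3))
    amp = gamma * math.sqrt(2.0 * D / dt)
    denom = 1.0 + 0.5 * gamma * dt
    err = _lr_accels(X, xo, kk, zeros, aa, zeros, m, M, k, ell0, A, ao)
    if err != ERR_OK:
        return rec[:1], err
    for d in range(3):
        A[1, d] += -gamma * V[1, d] + amp * np.random.normal()
    for step in range(1, n_steps + 1):
        for i in range(2):
            for d in range(3):
                V[i, d] += 0.5 * dt * A[i, d]
                X[i, d] += dt * V[i, d]
        for j in range(N):
            for d in range(3):
                vo[j, d] += 0.5 * dt * ao[j, d]
                xo[j, d] += dt * vo[j, d]
        err = _lr_accels(X, xo, kk, zeros, aa, zeros, m, M, k, ell0, A, ao)
        if err != ERR_OK:
            break
        for d in range(3):
            V[0, d] += 0.5 * dt * A[0, d]
            xi = np.random.normal()
            V[1, d] = (V[1, d] + 0.5 * dt * (A[1, d] + amp * xi)) / denom
            A[1, d] += -gamma * V[1, d] + amp * xi
        for j in range(N):
            for d in range(3):
                vo[j, d] += 0.5 * dt * ao[j, d]
        if step % record_every == 0:
            _record(rec, irec, step * dt, X, V)
            irec += 1
    return rec[:irec], err
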