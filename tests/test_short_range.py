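import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import dimerbath as db
from dimerbath.errors import IntegrityError, StepSizeError
from dimerbath.short_range_bath import (Frame, SolventSet, run_empty_frame,
                                        simulate_short_range, step_comoving,
                                        step_mixed_resolution)

BATH = db.ShortRangeBathParams(r0=0.08, mu=1e3, gamma=10.0, D=1.0)
SIGMA = BATH.sigma_mu


class TestElasticCollision:
    def test_equal_masses_exchange_normal_components(self):
        n = np.array([1.0, 0.0, 0.0])
        V, v = db.elastic_collision([1.0, 2.0, 0.0], [-3.0, 5.0, 1.0], n, 1.0)
        assert np.allclose(V, [-3.0, 2.0, 0.0])
        assert np.allclose(v, [1.0, 5.0, 1.0])

    def test_heavy_monomer_reflects_solvent(self):
        n = np.array([0.0, 1.0, 0.0])
        V0 = np.array([0.5, -1.0, 0.0])
        v0 = np.array([0.0, 4.0, 2.0])
        V, v = db.elastic_collision(V0, v0, n, 1e12)
        assert np.allclose(V, V0, atol=1e-9)
        # normal component reflected about the monomer's: v' = 2V - v
        assert v[1] == pytest.approx(2 * V0[1] - v0[1], rel=1e-9)
        assert v[0] == pytest.approx(v0[0]) and v[2] == pytest.approx(v0[2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_momentum_and_energy_conserved(self, seed):
        rng = np.random.default_rng(seed)
        mu = 1e3
        M, m = 1.0, 1.0 / mu
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        V0 = rng.normal(0, 3, 3)
        v0 = rng.normal(0, 100, 3)
        V, v = db.elastic_collision(V0, v0, n, mu)
        P0 = M * V0 + m * v0
        P1 = M * V + m * v
        E0 = 0.5 * M * V0 @ V0 + 0.5 * m * v0 @ v0
        E1 = 0.5 * M * V @ V + 0.5 * m * v @ v
        assert np.max(np.abs(P1 - P0)) < 1e-12
        assert abs(E1 - E0) / E0 < 1e-10

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError):
            db.elastic_collision([0, 0, 0], [1, 0, 0], [2.0, 0, 0], 10.0)


class TestResolveCollision:
    def test_head_on_kinematics(self):
        # solvent at distance r0 + d approaching at closing speed u overlaps
        # after dt; contact happened at dt - d/u before the step end
        r0, d, u, dt = 0.08, 0.001, 50.0, 1e-4
        mono_pos = np.zeros(3)
        solv_start = np.array([r0 + d, 0.0, 0.0])
        solv_vel = np.array([-u, 0.0, 0.0])
        end = solv_start + solv_vel * dt
        out = db.resolve_collision(mono_pos, np.zeros(3), end, solv_vel,
                                   r0, dt)
        assert out is not None
        tau, n_hat = out
        assert tau == pytest.approx(dt - d / u, rel=1e-12)
        assert np.allclose(n_hat, [1.0, 0.0, 0.0])

    def test_grazing_without_overlap_returns_none(self):
        r0, dt = 0.08, 1e-4
        end = np.array([0.0, r0 * 1.001, 0.0])
        assert db.resolve_collision(np.zeros(3), np.zeros(3), end,
                                    np.array([100.0, 0, 0]), r0, dt) is None

    def test_started_inside_detected(self):
        r0, dt = 0.08, 1e-6
        end = np.array([0.5 * r0, 0, 0])  # barely moving: inside all along
        with pytest.raises(IntegrityError):
            db.resolve_collision(np.zeros(3), np.zeros(3), end,
                                 np.array([-1e-3, 0, 0]), r0, dt)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rewound_pair_is_just_touching(self, seed):
        rng = np.random.default_rng(seed)
        r0, dt = 0.08, 1e-6
        mono_vel = rng.normal(0, 3, 3)
        # aim a fast particle at the monomer so the free flight overlaps
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        start = r0 * 1.2 * direction
        impact = rng.uniform(0, 0.7 * r0)
        perp = np.cross(direction, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        aim = impact * perp
        speed = rng.uniform(0.3, 0.6) * r0 / dt
        solv_vel = (aim - start) / np.linalg.norm(aim - start) * speed
        end_solv = start + solv_vel * dt
        end_mono = mono_vel * dt
        if np.linalg.norm(end_solv - end_mono) >= r0:
            return  # no overlap produced; nothing to resolve
        tau, n_hat = db.resolve_collision(end_mono, mono_vel, end_solv,
                                          solv_vel, r0, dt)
        sep = np.linalg.norm((end_solv - solv_vel * tau)
                             - (end_mono - mono_vel * tau))
        assert abs(sep - r0) < 1e-10


class TestInfluxProbability:
    def test_static_frame_kinetic_flux(self):
        lam, L, dt = BATH.lambda_mu, 0.32, 1e-6
        expect = lam * L * L * dt * SIGMA / math.sqrt(2 * math.pi)
        assert db.influx_probability(lam, SIGMA, L, dt, 0.0) \
            == pytest.approx(expect, rel=1e-12)

    def test_decreasing_in_frame_velocity(self):
        lam, L, dt = BATH.lambda_mu, 0.32, 1e-6
        vals = [db.influx_probability(lam, SIGMA, L, dt, v)
                for v in (-50.0, 0.0, 50.0, 200.0)]
        assert vals[0] > vals[1] > vals[2] > vals[3] >= 0.0
        assert db.influx_probability(lam, SIGMA, L, dt, 20 * SIGMA) \
            == pytest.approx(0.0, abs=1e-30)

    def test_step_size_guard(self):
        with pytest.raises(StepSizeError):
            db.influx_probability(BATH.lambda_mu, SIGMA, 0.32, 1e-4, 0.0)

    @pytest.mark.parametrize("vf", [0.0, -SIGMA])
    def test_matches_free_streaming_monte_carlo(self, vf):
        # independent oracle: count ideal-gas particles crossing the moving
        # face within dt
        lam, L, dt = BATH.lambda_mu, 0.32, 1e-6
        n_rep = 40000
        rng = np.random.default_rng(17)
        depth = 12 * SIGMA * dt + abs(vf) * dt
        mean_n = lam * depth * L * L * n_rep
        n_part = rng.poisson(mean_n)
        x = rng.uniform(-depth, 0.0, n_part)
        v1 = rng.normal(0.0, SIGMA, n_part)
        crossed = np.sum(x + (v1 - vf) * dt > 0.0)
        p = db.influx_probability(lam, SIGMA, L, dt, vf)
        expect = p * n_rep
        assert abs(crossed - expect) < 3.0 * math.sqrt(expect)


class TestOvercountAcceptance:
    def test_region_factors(self):
        L = 1.0
        assert db.overcount_acceptance([0.6, 0.0, 0.0], L) == 1.0
        assert db.overcount_acceptance([0.6, 0.6, 0.0], L) == 0.5
        assert db.overcount_acceptance([0.6, 0.6, -0.6], L) \
            == pytest.approx(1 / 3)

    def test_interior_point_is_integrity_error(self):
        with pytest.raises(IntegrityError):
            db.overcount_acceptance([0.1, 0.2, -0.3], 1.0)


class TestSampleIncomingParticle:
    def test_depth_marginal_static_frame(self):
        frame = Frame(centre=np.zeros(3), L=0.32)
        dt = 1e-6
        rng = np.random.default_rng(23)
        scale = SIGMA * dt * math.sqrt(2)
        depths = []
        for _ in range(4000):
            pos, vel = db.sample_incoming_particle(0, frame, BATH, dt, rng)
            depths.append((pos[0] + 0.16) / scale)
            # constructive constraint: the particle can reach its depth in dt
            assert vel[0] * dt >= (pos[0] + 0.16) - 1e-15
            assert abs(pos[1]) <= 0.16 and abs(pos[2]) <= 0.16
        from scipy import integrate

        zs = np.linspace(0, 8, 1601)
        pdf = db.erfc_tail_density(zs, 0.0)
        cdf = integrate.cumulative_trapezoid(pdf, zs, initial=0.0)
        cdf /= cdf[-1]
        res = stats.ks_1samp(depths, lambda x: np.interp(x, zs, cdf))
        assert res.pvalue > 0.01

    def test_opposite_faces_mirror(self):
        frame = Frame(centre=np.zeros(3), L=0.32)
        dt = 1e-6
        rng = np.random.default_rng(29)
        lo = np.array([db.sample_incoming_particle(0, frame, BATH, dt, rng)[0]
                       for _ in range(1500)])
        hi = np.array([db.sample_incoming_particle(1, frame, BATH, dt, rng)[0]
                       for _ in range(1500)])
        res = stats.ks_2samp(lo[:, 0] + 0.16, 0.16 - hi[:, 0])
        assert res.pvalue > 0.01


class TestInitialization:
    def test_count_statistics_with_overlap_culling(self):
        spring = db.SpringParams(k=1e6, ell0=0.32)
        p = db.LangevinParams(M=1.0, D=1.0, gamma=10.0)
        L = 0.32
        frame = Frame(centre=np.zeros(3), L=L)
        counts = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            dimer = db.DimerState(X1=np.zeros(3), X2=[0.32, 0, 0],
                                  V1=np.zeros(3), V2=np.zeros(3))
            s = db.initialize_short_range(dimer, frame, BATH, rng,
                                          mode="mixed")
            counts.append(s.count)
            assert np.all(np.linalg.norm(s.positions - dimer.X1, axis=1)
                          >= BATH.r0)
            assert np.all(np.abs(s.positions) <= L / 2)
        vol_frac = (4 / 3) * math.pi * BATH.r0 ** 3 / L ** 3
        expect = BATH.lambda_mu * L ** 3 * (1 - vol_frac)
        mean = np.mean(counts)
        assert abs(mean - expect) < 3 * math.sqrt(expect / len(counts))

    def test_two_bath_mode_returns_tagged_sets(self):
        rng = np.random.default_rng(1)
        dimer = db.DimerState(X1=np.zeros(3), X2=[0.32, 0, 0],
                              V1=np.zeros(3), V2=np.zeros(3))
        frames = [Frame(centre=dimer.X1, L=0.32),
                  Frame(centre=dimer.X2, L=0.32)]
        s1, s2 = db.initialize_short_range(dimer, frames, BATH, rng,
                                           mode="two_bath")
        assert s1.bath_id == "bath1" and s2.bath_id == "bath2"

    def test_same_seed_identical(self):
        dimer = db.DimerState(X1=np.zeros(3), X2=[0.32, 0, 0],
                              V1=np.zeros(3), V2=np.zeros(3))
        frame = Frame(centre=np.zeros(3), L=0.32)
        a = db.initialize_short_range(dimer, frame, BATH,
                                      np.random.default_rng(5), "one_bath")
        b = db.initialize_short_range(dimer, frame, BATH,
                                      np.random.default_rng(5), "one_bath")
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)


class TestSteppers:
    def test_empty_bath_reduces_to_symplectic_euler(self):
        # a bath with vanishing friction has essentially zero density, so
        # stepping is free flight plus the spring kick
        thin = db.ShortRangeBathParams(r0=0.01, mu=1.0, gamma=1e-12, D=1.0)
        spring = db.SpringParams(k=100.0, ell0=0.3)
        dt = 1e-4
        dimer = db.DimerState(X1=np.zeros(3), X2=[0.35, 0, 0],
                              V1=np.zeros(3), V2=np.zeros(3))
        solvent = SolventSet(positions=np.empty((0, 3)),
                             velocities=np.empty((0, 3)))
        frame = Frame(centre=dimer.Xbar, L=1.0)
        rng = np.random.default_rng(0)
        d = dimer
        s, f = solvent, frame
        for _ in range(100):
            d, s, f = step_comoving(d, s, f, spring, thin, dt, rng)
        # reference symplectic Euler (positions first, then velocity kick)
        X = np.stack([dimer.X1, dimer.X2])
        V = np.zeros((2, 3))
        for _ in range(100):
            X += V * dt
            rvec = X[1] - X[0]
            r = np.linalg.norm(rvec)
            fvec = spring.k * (r - spring.ell0) * rvec / r
            V[0] += fvec * dt
            V[1] -= fvec * dt
        assert np.allclose(d.X1, X[0], atol=1e-12)
        assert np.allclose(d.X2, X[1], atol=1e-12)
        assert np.allclose(d.V2, V[1], atol=1e-10)

    def test_step_mixed_resolution_deterministic(self):
        spring = db.SpringParams(k=1e6, ell0=0.32)
        p = db.LangevinParams(M=1.0, D=1.0, gamma=10.0)
        dimer = db.DimerState(X1=np.zeros(3), X2=[0.32, 0, 0],
                              V1=[1.0, 0, 0], V2=np.zeros(3))
        frame = Frame(centre=np.zeros(3), L=0.32)
        sol = db.initialize_short_range(dimer, frame, BATH,
                                        np.random.default_rng(2), "mixed")
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            d, s, f = dimer, sol, frame
            for _ in range(50):
                d, s, f = step_mixed_resolution(d, s, f, spring, BATH, p,
                                                1e-6, rng)
            outs.append((d.X1.copy(), d.V2.copy(), s.positions.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])
        assert np.array_equal(outs[0][2], outs[1][2])


class TestEquilibriumMaintenance:
    def test_static_frame_holds_density(self):
        L = 0.32
        times, nser, _ = run_empty_frame(BATH, L, 1e-6, 100000, [0.0, 0, 0],
                                         seed=13, record_every=2000)
        m = nser[5:]
        expect = BATH.lambda_mu * L ** 3
        assert abs(m.mean() - expect) < 3 * math.sqrt(expect / len(m))
        # Poisson: variance comparable to the mean
        assert 0.6 * expect < m.var() < 1.5 * expect


class TestTwoBathStatistics:
    def test_mean_length_consistent_with_langevin(self):
        # softer spring so the thermal extension is resolvable in a short run
        spring = db.SpringParams(k=1e4, ell0=0.32)
        p = db.LangevinParams(M=1.0, D=1.0, gamma=10.0)
        traj = simulate_short_range("two_bath", spring, BATH, T=6.0,
                                    dt=1e-6, L=0.32, seed=9)
        from dimerbath.estimators import estimate_mean_length

        res = estimate_mean_length(traj, burn_in=1.5)
        pred = db.analytic_mean_length(spring, p)
        assert res.ci_low <= pred <= res.ci_high
        # the heat bath extends the dimer beyond its rest length
        assert res.ci_low > spring.ell0


class TestMixedResolutionStatistics:
    def test_vacf_matches_langevin_form(self, short_mixed_traj):
        from dimerbath.estimators import estimate_vacf, fit_exponential_vacf

        vacf = estimate_vacf(short_mixed_traj, max_lag=1.0, burn_in=5.0)
        assert vacf.values[0] == pytest.approx(5.0, rel=0.15)
        d_hat, g_hat = fit_exponential_vacf(vacf, max_lag=0.5)
        assert d_hat == pytest.approx(1.0, rel=0.2)
        assert g_hat == pytest.approx(10.0, rel=0.15)
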