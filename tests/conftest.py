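import pytest

import dimerbath as db
from dimerbath.short_range_bath import simulate_short_range
from dimerbath.long_range_bath import simulate_long_range

# Reference parameter set: heavy dimer (mu = 1e3) with a stiff spring in a
# bath realising gamma = 10, D = 1 (thermal energy kT = M*D*gamma = 10).
GAMMA = 10.0
DIFF = 1.0
SPRING = db.SpringParams(k=1e6, ell0=0.32)
LANGEVIN = db.LangevinParams(M=1.0, D=DIFF, gamma=GAMMA)
BATH = db.ShortRangeBathParams(r0=0.08, mu=1e3, gamma=GAMMA, D=DIFF)


@pytest.fixture(scope="session")
def langevin_traj():
    """Macroscopic Langevin benchmark run (BBK handles the stiff spring at
    dt = 1e-4); 200 time units, recorded every 1e-3."""
    return db.simulate_langevin_dimer(
        SPRING, LANGEVIN, T=200.0, dt=1e-4, seed=42, integrator="bbk",
        sample_interval=1e-3)


@pytest.fixture(scope="session")
def short_mixed_traj():
    """Mixed-resolution collisional run (explicit solvent around monomer 1,
    Langevin monomer 2) at the reference parameters, scaled to 20 time
    units."""
    return simulate_short_range("mixed", SPRING, BATH, T=20.0, dt=1e-6,
                                L=0.32, seed=7)


@pytest.fixture(scope="session")
def shared_bath_run():
    """Shared oscillator bath with a soft spring, where the effective
    rest-length contraction is large enough to resolve in a short run."""
    spring = db.SpringParams(k=1000.0, ell0=1.0)
    traj = simulate_long_range(spring, LANGEVIN, omega_bar=100.0, N=1000,
                               m=1e-3, mode="shared", T=10.0, dt=5e-5,
                               seed=3)
    pred = db.effective_rest_length_one_bath(spring, GAMMA, 100.0)
    return traj, spring, pred


@pytest.fixture(scope="session")
def split_bath_run():
    """Split oscillator bath (one group per monomer) with a soft spring, so
    the thermal extension of the dimer is resolvable in a short run."""
    spring = db.SpringParams(k=1000.0, ell0=0.5)
    traj = simulate_long_range(spring, LANGEVIN, omega_bar=100.0,
                               N=(1000, 1000), m=1e-3, mode="split", T=16.0,
                               dt=5e-5, seed=4)
    pred = db.analytic_mean_length(spring, LANGEVIN)
    return traj, spring, pred


@pytest.fixture(scope="session")
def long_mixed_trajs():
    """Three independent mixed-resolution oscillator-bath runs (N1 = 1000,
    omega_bar = 100, 20 time units each). Averaging over runs also averages
    over bath draws, whose low-frequency discreteness dominates the
    Green-Kubo noise at this bath size."""
    return [
        simulate_long_range(SPRING, LANGEVIN, omega_bar=100.0, N=1000,
                            m=1e-3, mode="mixed", T=20.0, dt=2e-5, seed=s)
        for s in (101, 102, 103)
    ]
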