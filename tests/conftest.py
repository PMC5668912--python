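"""Shared fixtures.

Expensive simulations (the NVE conservation run, the double-well
crossing ensembles, the Monte-Carlo estimator-recovery draws) are
session-scoped so unit tests and the acceptance checks assert on one
computation each.
"""

import numpy as np
import pytest

import lowmassmd as lm
from lowmassmd.kinetics import FoldingRecord, exponential_fit
from lowmassmd.synthetic import CROSSING_TEMPERATURE, ensemble_first_crossing


def make_lj_cluster(seed: int = 2, n: int = 10) -> tuple[lm.ToySystem, lm.ForceField]:
    """A seeded, loosely bound Lennard-Jones cluster (ε=0.2, σ=3.0)."""
    rng = np.random.default_rng(seed)
    positions = rng.normal(0.0, 1.0, (n, 3)) * 2.5
    velocities = rng.normal(0.0, 0.005, (n, 3))
    system = lm.ToySystem(np.full(n, 12.0), positions, velocities)
    ff = lm.ForceField(
        lj_pairs=[(i, j, 0.2, 3.0) for i in range(n) for j in range(i + 1, n)]
    )
    return system, ff


@pytest.fixture(scope="session")
def lj_cluster():
    return make_lj_cluster()


@pytest.fixture(scope="session")
def nve_lj_trajectory(lj_cluster):
    """10-particle LJ cluster, NVE, dt = 1 fs, 10^5 steps, energies saved."""
    system, ff = lj_cluster
    cfg = lm.IntegratorConfig(dt=1.0, n_steps=100_000, save_interval=1000)
    return lm.run_simulation(system, ff, cfg)


@pytest.fixture(scope="session")
def crossing_ensembles():
    """First-passage step counts over the double-well barrier.

    24 replicas per mass factor at the pilot-calibrated bath
    temperature, identical seed so the λ = 0.1 and λ = 1.0 batches share
    their initial velocity draws (paired comparison).
    """
    well = lm.build_double_well()
    common = dict(n_replicas=24, seed=2024, max_steps=12_000)
    standard = ensemble_first_crossing(
        well, CROSSING_TEMPERATURE, lam=1.0, **common
    )
    low_mass = ensemble_first_crossing(
        well, CROSSING_TEMPERATURE, lam=0.1, **common
    )
    return {"standard": standard, "low_mass": low_mass}


@pytest.fixture(scope="session")
def exponential_recovery():
    """500 synthetic draws of 20 exponential(τ=100 ns) folding times."""
    estimates, covered = [], 0
    for s in range(500):
        rng = np.random.default_rng(10_000 + s)
        records = [FoldingRecord(t, True) for t in rng.exponential(100.0, 20)]
        fit = exponential_fit(records)
        estimates.append(fit.tau_f)
        covered += fit.lcl <= 100.0 <= fit.ucl
    return {"estimates": np.array(estimates), "coverage": covered / 500}


@pytest.fixture(scope="session")
def shake_chain_run():
    """A thermostatted run of a fully bond-constrained bead chain,
    returning the trajectory and the constraint set for residual checks."""
    r0 = 1.53
    theta0 = np.deg2rad(109.5)
    well = lm.build_double_well()
    system = well.system.copy()
    constraints = lm.ConstraintSet(
        pairs=[(0, 1, r0), (1, 2, r0), (2, 3, r0)]
    )
    ff = lm.ForceField(
        angles=[(0, 1, 2, 25.0, theta0), (1, 2, 3, 35.0, theta0)],
        torsions=[(0, 1, 2, 3, 2.0, 2.0, 0.0)],
    )
    cfg = lm.IntegratorConfig(
        dt=1.0,
        n_steps=5000,
        save_interval=10,
        thermostat=lm.Thermostat(300.0, 100.0),
        seed=7,
        initialize_velocities=True,
    )
    traj = lm.run_simulation(system, ff, cfg, constraints=constraints)
    return traj, constraints
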