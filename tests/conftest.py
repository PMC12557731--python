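import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ringseg.engine import PhaseSchedule, default_schedule, run_protocol, step_brownian
from ringseg.fixtures import make_mixed_compact_init
from ringseg.metrics import segregation_efficiency
from ringseg.model import Configuration, SimulationParameters, ring_bonds

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ENSEMBLE_SEEDS = tuple(range(401, 411))  # ten replicas, common across modes


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def segregation_cells():
    """Lazily computed (mode, phi, n_beads) ensembles on common seeds.

    Returns a getter: get(mode, phi, nb) -> (initial_efficiencies,
    final_efficiencies) over the ten fixed replica seeds, using the default
    desk-scale schedule for that mode and system size.  Cached so criteria
    sharing a cell do not recompute it.
    """
    cache = {}

    def get(mode, phi=0.10, nb=100):
        key = (mode, float(phi), nb)
        if key not in cache:
            schedule = default_schedule(mode, nb)
            params = SimulationParameters.for_volume_fraction(phi, n_beads_per_ring=nb)
            inits, finals = [], []
            for seed in ENSEMBLE_SEEDS:
                config = make_mixed_compact_init(params, phi, seed)
                inits.append(segregation_efficiency(config))
                result = run_protocol(params, schedule, config, seed)
                finals.append(segregation_efficiency(result.final))
            cache[key] = (np.array(inits), np.array(finals))
        return cache[key]

    return get


@pytest.fixture(scope="session")
def einstein_msd_ratio():
    """MSD(t)/(6 D t) for 10^4 free Brownian walkers after 200 steps."""
    params = SimulationParameters()
    n = 10_000
    config = Configuration(
        np.zeros((n, 3)), np.repeat([0, 1], n // 2), ring_bonds(n // 2, n // 2)
    )
    stream = np.random.default_rng(1234)
    steps = 200
    for _ in range(steps):
        config = step_brownian(config, np.zeros((n, 3)), params, stream)
    msd = np.mean(np.sum(config.positions**2, axis=1))
    return msd / (steps * params.dt) / (6.0 * params.kT / params.gamma)


@pytest.fixture(scope="session")
def bond_ks_statistic():
    """KS distance between sampled bond lengths and the Boltzmann density.

    One small two-ring system in a large vesicle, attraction off, run at
    reduced dt so the Euler-Maruyama discretization bias is negligible;
    samples spaced 1 tau (bond relaxation time is gamma/(2 k_bond) ~ 0.005
    tau, so they are independent).
    """
    from scipy.integrate import cumulative_trapezoid
    from scipy.stats import kstest

    params = SimulationParameters.for_volume_fraction(
        0.01, n_beads_per_ring=16, dt=5e-4
    )
    config = make_mixed_compact_init(params, 0.01, seed=1)
    schedule = PhaseSchedule(
        t_relax=330.0, compaction_mode="none", t_membrane_on=330.0,
        t_total=330.0, snapshot_interval=1.0,
    )
    result = run_protocol(params, schedule, config, seed=21)
    samples = []
    for snap in result.snapshots[10:]:  # discard equilibration
        d = np.linalg.norm(
            snap.positions[snap.bonds[:, 1]] - snap.positions[snap.bonds[:, 0]], axis=1
        )
        samples.extend(d.tolist())
    samples = np.asarray(samples)
    assert len(samples) >= 10_000

    grid = np.linspace(0.5, 1.5, 4001)
    dens = grid**2 * np.exp(-params.k_bond * (grid - params.r0_bond) ** 2 / 2)
    cdf = cumulative_trapezoid(dens, grid, initial=0.0)
    cdf /= cdf[-1]
    return kstest(samples, lambda x: np.interp(x, grid, cdf)).statistic
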