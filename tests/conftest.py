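import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "dtekit",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("dtekit")

from dtekit import (  # noqa: E402
    AnnulusFlowConfig,
    SeedConfig,
    Trajectory,
    TrajectoryEnsemble,
    advect,
    seed_particles,
)


def pure_shear_trajectory(sigmas, times, particle_id="p0", exited=True):
    """Trajectory whose scalar stress at sample i equals sigmas[i].

    Uses a pure-shear tensor (tau12 = sigma, rest 0), for which the
    von-Mises invariant returns sigma exactly.  Positions march along z.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    times = np.asarray(times, dtype=float)
    n = len(times)
    tau = np.zeros((n, 6))
    tau[:, 3] = sigmas
    pos = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(0, 1, n)])
    return Trajectory(particle_id, times, pos, tau, exited=exited)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_ensemble(rng):
    """A 5-particle random ensemble in Pa with zone labels."""
    trajectories = []
    for i in range(5):
        n = int(rng.integers(3, 8))
        t = np.sort(rng.uniform(0, 1, n))
        t += np.arange(n) * 1e-6  # enforce strict increase
        pos = rng.normal(0, 0.01, (n, 3))
        tau = rng.normal(0, 5, (n, 6))
        zone = np.array(
            [rng.choice(["blade", "stator", ""]) for _ in range(n)],
            dtype=object,
        )
        trajectories.append(
            Trajectory(f"p{i}", t, pos, tau, zone=zone, exited=bool(i % 2))
        )
    return TrajectoryEnsemble(
        trajectories, stress_unit="Pa", label="toy",
        meta={"rpm": 10600, "n_seeded": 6},
    )


@pytest.fixture(scope="session")
def annulus_cfg():
    return AnnulusFlowConfig()


@pytest.fixture(scope="session")
def advected(annulus_cfg):
    """A modest advected ensemble shared across tests (300 particles)."""
    seed_cfg = SeedConfig(n_particles=300, seed=7, max_duration=0.3)
    seeds = seed_particles(annulus_cfg, seed_cfg)
    return advect(annulus_cfg, seeds, seed_cfg)
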