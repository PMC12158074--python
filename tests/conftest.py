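import numpy as np
import pytest

from magstep.simulate import (
    GaitParams,
    NoiseParams,
    simulate_magnetic_distances,
    simulate_walk,
)

EXACT_NOISE = NoiseParams(sigma0=0.0, impact_sigma=0.0, marker_sigma=0.0, bandwidth=None)


def calibrated_run(seed: int):
    """One seeded walk with the default calibrated noise model."""
    walk_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    p = GaitParams(seed=seed)
    traj, truth = simulate_walk(p, rng=np.random.default_rng(walk_ss))
    ds = simulate_magnetic_distances(
        traj, NoiseParams(), da=p.geometry.da, ic_times=truth.ic_times,
        rng=np.random.default_rng(noise_ss),
    )
    return p, traj, truth, ds


@pytest.fixture(scope="session")
def noise_free_walk():
    """Default 120 s walk with exact (unfiltered, noiseless) distance channels."""
    p = GaitParams(seed=42)
    traj, truth = simulate_walk(p)
    ds = simulate_magnetic_distances(traj, EXACT_NOISE, da=p.geometry.da)
    return p, traj, truth, ds


@pytest.fixture(scope="session")
def calibrated_walk():
    return calibrated_run(7)
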