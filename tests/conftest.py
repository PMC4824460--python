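import numpy as np
import pytest

import micropotts as mp


def rasterized_disc_grid(radius_sites: float, pad: int = 6):
    """Binary disc indicator with site centers at (i+0.5, j+0.5)."""
    n = 2 * int(np.ceil(radius_sites)) + 2 * pad
    ii = np.arange(n)
    dx = ii[:, None] + 0.5 - n / 2
    dy = ii[None, :] + 0.5 - n / 2
    return (dx * dx + dy * dy <= radius_sites ** 2), n / 2


@pytest.fixture(scope="session")
def disc56():
    """Reference rasterized disc of radius 56 sites (~1e4 sites)."""
    grid, center = rasterized_disc_grid(56.0)
    return grid, center, 56.0


@pytest.fixture(scope="session")
def generic_params():
    return mp.get_preset("generic")


@pytest.fixture(scope="session")
def mcf_params():
    return mp.get_preset("MCF10A")


@pytest.fixture(scope="session")
def division_batches():
    """Shared spread-and-divide batches on bar and L (scaled-down counts).

    Generic-cell preset at lattice scale 0.5 um; 100 replicates per pattern.
    """
    out = {}
    for pat, seed0 in (("bar", 1000), ("L", 5000)):
        _, angles = mp.batch_divisions(
            mp.get_preset("generic"), mp.PatternSpec(pat, beta=0.5),
            n_reps=100, base_seed=seed0)
        out[pat] = angles
    return out


@pytest.fixture(scope="session")
def square_division_batch():
    """Divisions on the four-fold symmetric square (for symmetry checks)."""
    _, angles = mp.batch_divisions(
        mp.get_preset("generic"),
        mp.PatternSpec("square", dims={"width": 30.0}, beta=0.5),
        n_reps=64, base_seed=9000)
    return angles


@pytest.fixture(scope="session")
def free_migration_runs():
    """MCF10A single-cell trajectories on an unbounded adhesive plane."""
    trajs = []
    for seed in (101, 102, 103):
        params = mp.get_preset("MCF10A")
        mask = mp.make_pattern(mp.PatternSpec("uniform", dims={"width": 120.0},
                                              beta=params.beta))
        sim = mp.Simulation(params, mask, seed=seed)
        trajs.append(sim.free_migration_trajectory(50000, relax_mcs=2000))
    return trajs
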