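import numpy as np
import pytest

from planbio.dvh import DVH, DoseGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def two_bin_dvh():
    """Half the volume at ~60 Gy, half at ~70 Gy (narrow bins)."""
    return DVH("x", np.array([59.95, 60.05, 69.95, 70.05]),
               np.array([0.5, 0.0, 0.5]))


def random_dvh(rng, n_bins=None, name="rand"):
    """Random valid differential DVH on an irregular grid."""
    n = n_bins or int(rng.integers(2, 40))
    edges = np.sort(rng.uniform(0.0, 80.0, size=n + 1))
    edges += np.arange(n + 1) * 1e-6  # enforce strict increase
    v = rng.dirichlet(np.ones(n))
    return DVH(name, edges, v)


def matched_grid(dvh, counts_per_bin=7):
    """DoseGrid whose voxel doses sit exactly at the DVH bin midpoints.

    Voxel counts are proportional to integer multiples of the relative
    volumes so the grid's empirical distribution matches the DVH exactly;
    returns (grid, exact_dvh) where exact_dvh has the matching rational
    weights.
    """
    d = dvh.as_differential()
    mids = d.midpoints
    counts = np.maximum((d.volume * 1000).round().astype(int), 0)
    counts[d.volume > 0] = np.maximum(counts[d.volume > 0], 1)
    doses = np.repeat(mids, counts)
    grid = DoseGrid(doses.reshape(1, 1, -1), np.ones((1, 1, doses.size), bool))
    v = counts / counts.sum()
    exact = DVH(d.structure_name, d.bin_edges, v)
    return grid, exact
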