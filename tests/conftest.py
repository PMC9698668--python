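import numpy as np
import pytest

import topochron as tc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_raster(rng, n_regions, n_bins, p=0.1):
    """Sample-resolution raster with random occupancy."""
    occ = rng.random((n_regions, n_bins)) < p
    prev = np.zeros_like(occ)
    prev[:, 1:] = occ[:, :-1]
    return tc.BinnedRaster(
        occupancy=occ,
        onsets=occ & ~prev,
        bin_width=1,
        fs=512.0,
        threshold=3.0,
        region_labels=tuple(f"R{i}" for i in range(n_regions)),
    )


def make_avalanche(frames, n_regions=None):
    """Avalanche from a list of iterables of region indices."""
    fr = tuple(frozenset(f) for f in frames)
    if n_regions is None:
        n_regions = 1 + max((r for f in fr for r in f), default=0)
    return tc.Avalanche(start_bin=1, frames=fr, n_regions=n_regions)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny end-to-end synthetic cohort shared across tests."""
    params = tc.CascadeParams(
        n_regions=12, edge_density=0.4, transmission_p=0.3,
        n_avalanches=40, horizon_bins=400, seed=77,
    )
    return tc.make_cohort(params, n_controls=2, n_patients=2,
                          lesion_fraction=0.25, lesion_slowdown=2.0)
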