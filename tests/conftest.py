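"""Shared fixtures: fitted phantoms are expensive, so they are session-scoped."""

import numpy as np
import pytest

from topofield import confield, phantoms
from topofield.volumes_io import remove_region_mean


@pytest.fixture(scope="session")
def topo_phantom():
    """Topographic phantom: 5x5x5 seed mapped onto a 9x9x9 region, high SNR."""
    spec = phantoms.PhantomSpec(
        seed_shape=(5, 5, 5),
        map_shape=(9, 9, 9),
        scheme="topographic",
        sigma_true=2.0,
        n_timepoints=300,
        snr=10.0,
        seed_rng=1,
    )
    return spec, *phantoms.generate_phantom(spec)


@pytest.fixture(scope="session")
def topo_fit(topo_phantom):
    _, seed_ts, map_ts, truth = topo_phantom
    seed_d, map_d = remove_region_mean(seed_ts), remove_region_mean(map_ts)
    cfm = confield.fit_connective_field_map(seed_d, map_d)
    return cfm, seed_d, map_d, truth


@pytest.fixture(scope="session")
def conv_fit():
    """Convergent phantom fit: all fields cluster on one mapping locus."""
    spec = phantoms.PhantomSpec(
        seed_shape=(5, 5, 5),
        map_shape=(9, 9, 9),
        scheme="convergent",
        sigma_true=2.0,
        n_timepoints=300,
        snr=10.0,
        seed_rng=2,
    )
    seed_ts, map_ts, truth = phantoms.generate_phantom(spec)
    cfm = confield.fit_connective_field_map(
        remove_region_mean(seed_ts), remove_region_mean(map_ts)
    )
    return cfm, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
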