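import numpy as np
import pytest

import sporemap as sm
from sporemap.core import MarkerMap, TetradSet


@pytest.fixture(scope="session")
def small_layout():
    return sm.GenomeLayout.from_lengths({"I": 600_000, "II": 500_000})


@pytest.fixture(scope="session")
def analyzed_layout():
    return sm.analyzed_layout()


@pytest.fixture(scope="session")
def clean_sim(analyzed_layout):
    """Noise-free study-scale-ish simulation shared across tests."""
    params = sm.SimParams(seed=202, missing_rate=0.0, error_rate=0.0)
    tetrads, truth = sm.simulate_tetrads(analyzed_layout, params, 24)
    return tetrads, truth, params


@pytest.fixture(scope="session")
def clean_catalog(clean_sim):
    tetrads, truth, _ = clean_sim
    return sm.call_events(tetrads, params=sm.CallerParams(min_tract_markers=1))


def tetrad_from_matrix(positions, genotypes, chrom="I", name="T001"):
    """Build a one-tetrad TetradSet from an explicit (4, M) genotype matrix."""
    positions = np.asarray(positions, dtype=np.int64)
    g = np.asarray(genotypes, dtype=np.int8)
    assert g.shape == (4, len(positions))
    markers = MarkerMap({chrom: positions})
    return TetradSet(markers, [name], {chrom: g[None, :, :]})
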