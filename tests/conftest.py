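import warnings

import pytest

import depth_tcr as d
from depth_tcr.simulate import simulate


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 80 individuals, 300 TCRs, 30 planted pairs."""
    return d.SimulationConfig(n_individuals=80, n_public_tcrs=300,
                              n_planted_pairs=30, seed=7)


@pytest.fixture(scope="session")
def small_world(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_labeled(small_world):
    """Discovery output on the small cohort: labeled + split pair table."""
    universe, cohort, truth = small_world
    occ = d.OccurrenceMatrix.from_cohort(cohort).public_filter()
    tested = d.select_positive_pairs(occ, cohort.genotypes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labeled = d.sample_negative_pairs(tested, seed=3)
    split = d.split_pairs(labeled, seed=3)
    return d.attach_tcr_sequences(split, cohort.tcr_catalog)
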