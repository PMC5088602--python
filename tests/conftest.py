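"""Shared fixtures: small synthetic reference sets and read samples."""

import numpy as np
import pytest

from strainscope.simulate import simulate_species_set


@pytest.fixture(scope="session")
def small_species_set():
    """Four species, three strains each — enough for every pipeline stage."""
    return simulate_species_set(11, n_species=4, n_strains_per_species=3)


@pytest.fixture(scope="session")
def single_species_set():
    """One species, two strains: a community strain and a representative."""
    return simulate_species_set(23, n_species=1, n_strains_per_species=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
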