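"""Shared fixtures: synthetic bundles are generated once per session."""

import pytest

from famscan.cis_elements import default_catalog
from famscan.synthetic_data import SimConfig, generate_family_genome, generate_genome_pair


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic genome bundle (seed 1, 20 members + 20 decoys)."""
    return generate_family_genome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def genome_pair():
    """Two-genome bundle with planted collinear blocks (seed 1)."""
    return generate_genome_pair(SimConfig(seed=1))


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()
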