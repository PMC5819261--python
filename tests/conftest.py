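"""Shared fixtures: a small end-to-end reference set built once per session."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from virsig.annotation import annotate_references
from virsig.profiles import build_database
from virsig.simulate import SimulationConfig, simulate_reference_set


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_families=3, genomes_per_family=3, genes_per_genome=4, seed=7
    )


@pytest.fixture(scope="session")
def small_ref(small_config):
    """3 families x 3 genomes with disjoint repertoires."""
    return simulate_reference_set(small_config)


@pytest.fixture(scope="session")
def small_db(small_ref):
    return build_database(small_ref.genomes)


@pytest.fixture(scope="session")
def small_annotation(small_ref, small_db):
    """(SignatureTable, GOMs) of the small reference set against itself."""
    return annotate_references(small_ref.genomes, small_db)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
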