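import numpy as np
import pytest

from ecocoalesce.community import (
    CommunityState,
    FunctionalGroup,
    Species,
    SpeciesTable,
    default_species_table,
)


@pytest.fixture(scope="session")
def species() -> SpeciesTable:
    return default_species_table()


@pytest.fixture
def two_species() -> SpeciesTable:
    P = FunctionalGroup.PRODUCER
    return SpeciesTable(
        (Species("A", "alpha", P, 1.0), Species("B", "beta", P, 1.0))
    )


def make_state(counts, species=None, **meta) -> CommunityState:
    """State over the full pool axis with the given counts, rest zero."""
    if species is None:
        species = default_species_table()
    full = {sid: 0.0 for sid in species.ids}
    full.update(counts)
    return CommunityState(counts=full, **meta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
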