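import numpy as np
import pandas as pd
import pytest

from ciliaprofile import (
    OrthologueMatrix,
    ProfileGenerationConfig,
    SpeciesPanel,
    SpeciesRecord,
    generate_panel,
)


@pytest.fixture(scope="session")
def default_panel() -> SpeciesPanel:
    """The 45-genome panel: 29 ciliated, 16 non-ciliated (3 plants, 5 fungi)."""
    return generate_panel(ProfileGenerationConfig())


@pytest.fixture
def tiny_panel() -> SpeciesPanel:
    """A hand-built 6-species panel covering all flag combinations."""
    return SpeciesPanel(
        species=[
            SpeciesRecord("q", ciliated=True, supergroup="Archaeplastida"),
            SpeciesRecord("c1", ciliated=True, supergroup="Holozoa"),
            SpeciesRecord("c2", ciliated=True, supergroup="Excavata"),
            SpeciesRecord("p1", ciliated=False, supergroup="Archaeplastida", nonciliated_plant=True),
            SpeciesRecord("f1", ciliated=False, supergroup="Fungi", fungus=True),
            SpeciesRecord("n1", ciliated=False, supergroup="Amoebozoa"),
        ],
        query_species_id="q",
    )


def make_matrix(panel: SpeciesPanel, rows: dict[str, list[int]]) -> OrthologueMatrix:
    """Build an OrthologueMatrix from {protein: 0/1 vector in panel order}."""
    values = np.array(list(rows.values()), dtype=bool).reshape(len(rows), len(panel.species_ids))
    presence = pd.DataFrame(
        values,
        index=pd.Index(list(rows), name="protein_id"),
        columns=panel.species_ids,
    )
    return OrthologueMatrix(presence=presence, query_species_id=panel.query_species_id)
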