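import numpy as np
import pytest

from biofilmgeo.core import SpatialCountTable
from biofilmgeo.synthetic import environment_preset, generate_biofilm


@pytest.fixture
def tiny_table() -> SpatialCountTable:
    return SpatialCountTable(
        ["taxA", "taxB", "taxC"],
        ["s1", "s2"],
        np.array([[3, 0], [1, 2], [0, 5]]),
    )


@pytest.fixture(scope="session")
def small_survey():
    """A small uncontrolled-style survey shared across tests (fixed seed)."""
    cfg = environment_preset("uncontrolled", n_taxa=120, n_sections=60,
                             depth=2000, seed=42)
    return generate_biofilm(cfg)
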