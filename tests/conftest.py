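import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from chemevol.simulate import DEFAULT_SPECIES_TREE, simulate_gene_family


@pytest.fixture(scope="session")
def nine_species_truth():
    """Event-free gene family on the nine-species default tree."""
    return simulate_gene_family(DEFAULT_SPECIES_TREE, 0.0, 0.0, 0.0, seed=5)
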