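import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from logoplot import Alignment, PositionCharacterMatrix


@pytest.fixture
def dna_counts():
    """Counts row (3, 1, 0, 0): the hand-checked transform example."""
    return PositionCharacterMatrix.from_values(
        [[3, 1, 0, 0]], "ACGT", matrix_type="counts"
    )


@pytest.fixture
def toy_alignment():
    return Alignment([("a", "ACGT"), ("b", "ACGA")])


@pytest.fixture
def uniform_prob():
    return PositionCharacterMatrix.from_values(
        np.full((3, 4), 0.25), "ACGT", matrix_type="probability"
    )
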