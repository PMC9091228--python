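import numpy as np
import pandas as pd
import pytest

from sparccnet import AbundanceTable


@pytest.fixture
def toy_counts() -> AbundanceTable:
    """5 samples x 4 taxa integer counts, strictly positive."""
    data = pd.DataFrame(
        [
            [10, 20, 5, 65],
            [12, 18, 7, 63],
            [8, 25, 4, 63],
            [15, 15, 9, 61],
            [11, 22, 6, 61],
        ],
        index=[f"S{i}" for i in range(1, 6)],
        columns=["A", "B", "C", "D"],
    )
    return AbundanceTable(data, kind="counts")


@pytest.fixture
def toy_relative(toy_counts) -> AbundanceTable:
    from sparccnet import to_relative

    return to_relative(toy_counts, pseudocount=0.0)
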