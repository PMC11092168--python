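import numpy as np
import pandas as pd
import pytest

from mvboost.data_model import ViewTable, assemble_dataset


@pytest.fixture
def two_view_ds():
    """Views over {a,b,c} and {b,d}: the canonical incomplete pair."""
    v1 = ViewTable(
        "v1",
        pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
            index=["a", "b", "c"],
            columns=["f1", "f2"],
        ),
    )
    v2 = ViewTable(
        "v2",
        pd.DataFrame(
            [[7.0], [8.0]],
            index=["b", "d"],
            columns=["g1"],
        ),
    )
    labels = {"a": "case", "b": "ctrl", "c": "case", "d": "ctrl"}
    return assemble_dataset([v1, v2], labels)


@pytest.fixture
def count_table():
    """5 samples x 4 features of small counts with known presence pattern."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        {
            "otu_everywhere": [3, 1, 2, 5, 1],   # present in 5
            "otu_two": [4, 0, 0, 9, 0],          # present in 2
            "otu_one": [0, 0, 7, 0, 0],          # present in 1
            "otu_three": [1, 2, 0, 0, 3],        # present in 3
        },
        index=[f"s{i}" for i in range(5)],
    ).astype(float)
    return ViewTable("otus", data)
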