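import numpy as np
import pandas as pd
import pytest

from keystonetaxa import SyntheticSpec, generate_dataset
from keystonetaxa.table_io import CountTable, TraitTable


@pytest.fixture(scope="session")
def small_spec():
    """Small but structured community: 3 planted modules, 1 connector,
    4 differential taxa, 8 + 8 samples."""
    return SyntheticSpec(
        n_taxa=40,
        n_samples_per_group=8,
        n_blocks=3,
        block_size=8,
        n_connectors=1,
        n_differential=4,
        delta=1.2,
        sequencing_depth=20_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture()
def toy_counts():
    return CountTable(
        counts=pd.DataFrame(
            [[4, 0, 1, 3], [2, 2, 2, 2], [0, 0, 5, 0]],
            index=["tA", "tB", "tC"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture()
def toy_traits():
    return TraitTable(
        data=pd.DataFrame(
            {
                "group": ["H", "H", "L", "L"],
                "ADG": [120.0, 130.0, 90.0, 85.0],
                "IgG": [5.0, np.nan, 8.0, 9.0],
            },
            index=["s1", "s2", "s3", "s4"],
        )
    )
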