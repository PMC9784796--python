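from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
import pytest

from milkscc import load_reference_counts


@pytest.fixture(scope="session")
def reference_table() -> pd.DataFrame:
    """The packaged 20-cow study: nine counts per cow plus the published CV."""
    ref = importlib.resources.files("milkscc.data") / "table1_counts.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


@pytest.fixture(scope="session")
def reference_groups():
    return load_reference_counts()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20173)
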