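import numpy as np
import pandas as pd
import pytest

from ifnscore.panel import DEFAULT_PANEL
from ifnscore.simulate import DEFAULT_SPEC


@pytest.fixture
def panel():
    return DEFAULT_PANEL


@pytest.fixture
def spec():
    return DEFAULT_SPEC


@pytest.fixture
def ct_csv(tmp_path):
    """Write a Ct CSV from a dict of column lists; returns the path."""

    def _write(rows: dict, name: str = "ct.csv"):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write


@pytest.fixture
def small_ct_frame(panel):
    """Two samples with all 8 default genes measured."""
    rng = np.random.default_rng(11)
    data = {"sample_id": ["s1", "s2"]}
    for gene in panel.all_genes:
        data[gene] = np.round(rng.uniform(18, 30, 2), 2)
    return pd.DataFrame(data)
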