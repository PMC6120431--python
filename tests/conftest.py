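import numpy as np
import pandas as pd
import pytest

from tidalplast.data_model import CountMatrix, SampleDesign
from tidalplast.normalization import filter_low_expression, rlog_transform, size_factors
from tidalplast.synthetic_data import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def default_dataset():
    """One study-condition synthetic dataset shared across read-only tests."""
    counts, design, truth = simulate_counts(SimConfig(seed=20240817, n_genes=1000))
    return counts, design, truth


@pytest.fixture(scope="session")
def default_expr(default_dataset):
    counts, design, truth = default_dataset
    filt = filter_low_expression(counts)
    sf = size_factors(filt)
    return filt, design, truth, rlog_transform(filt, sf, design=design)


@pytest.fixture()
def tiny_counts():
    return CountMatrix(
        ["g1", "g2", "g3"], ["s1", "s2"], np.array([[5, 0], [10, 2], [0, 7]])
    )


def full_design_frame(sites=("BYQ", "LT"), drop=()):
    rows = [
        (f"{site}-{tide}_{t}h_{r}", site, tide, t, r)
        for site in sites
        for tide in ("I", "S")
        for t in (0, 6, 24)
        for r in (1, 2, 3)
        if f"{site}-{tide}_{t}h_{r}" not in drop
    ]
    return pd.DataFrame(rows, columns=["sample_id", "site", "tide", "time_h", "replicate"])


@pytest.fixture()
def full_design():
    return SampleDesign(full_design_frame())
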