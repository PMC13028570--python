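import numpy as np
import pandas as pd
import pytest

from fungalnet.datamodel import OtuTable


def make_table(counts, altitudes=None, zones=None, belts=None):
    counts = np.asarray(counts)
    n_plots, n_otus = counts.shape
    plot_ids = [f"P{i + 1:02d}" for i in range(n_plots)]
    otu_ids = [f"OTU{j + 1:02d}" for j in range(n_otus)]
    meta = pd.DataFrame(index=plot_ids)
    meta["altitude"] = altitudes if altitudes is not None else np.linspace(1020, 1770, n_plots)
    meta["zone"] = zones if zones is not None else ["LA"] * n_plots
    if belts is not None:
        meta["belt"] = belts
    return OtuTable(counts, otu_ids, plot_ids, meta)


@pytest.fixture
def tiny_table():
    """3 OTUs x 4 plots with simple structure."""
    return make_table([[0, 5, 1], [2, 0, 1], [1, 1, 0], [3, 2, 2]])


@pytest.fixture
def spearman_fixture():
    """20-OTU table with exactly 3 planted monotone pairs among iid noise.

    Verified to yield exactly the 3 planted edges at |rho| >= 0.65 and
    BH-adjusted p <= 0.01.
    """
    rng = np.random.default_rng(2024)
    n_plots = 40
    cols = {}
    for k in range(3):
        order = rng.permutation(n_plots)
        cols[f"OTU{2 * k + 1:02d}"] = 50 + 2 * order
        cols[f"OTU{2 * k + 2:02d}"] = 40 + (order + 1) ** 2 // 12
    for k in range(7, 21):
        cols[f"OTU{k:02d}"] = rng.poisson(60, n_plots) + 1
    counts = np.column_stack([cols[k] for k in sorted(cols)])
    ids = sorted(cols)
    plots = [f"P{i:02d}" for i in range(n_plots)]
    meta = pd.DataFrame(
        {"altitude": np.linspace(1000, 1500, n_plots), "zone": ["LA"] * n_plots},
        index=plots,
    )
    return OtuTable(counts, ids, plots, meta)
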