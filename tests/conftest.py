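import numpy as np
import pandas as pd
import pytest

from anhydronet import prep, synthio


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts():
    """Two-condition, 3-timepoint, 2-replicate count matrix with 4 genes."""
    genes = ["g1", "g2", "g3", "g4"]
    rows = []
    for cond, prefix in (("trehalose", "T"), ("rehydration", "R")):
        for t in range(3):
            for r in (1, 2):
                rows.append({"sample": f"{prefix}{t}_{r}", "condition": cond,
                             "time_h": float(t), "replicate": r})
    design = prep.TimeSeriesDesign(pd.DataFrame(rows).set_index("sample"))
    rng = np.random.default_rng(0)
    values = pd.DataFrame(rng.poisson(100, size=(4, 12)),
                          index=genes, columns=design.samples)
    lengths = pd.Series([500.0, 1000.0, 2000.0, 1500.0], index=genes)
    return prep.CountMatrix(values, lengths), design


@pytest.fixture
def chain_network():
    """A -> B -> C chain with unit weights, A the root."""
    return synthio.PlantedNetwork(
        tf_ids=["A", "B", "C"],
        edges=[("A", "B", 1, 1.0), ("B", "C", -1, 0.8)],
    )
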