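import numpy as np
import pandas as pd
import pytest

from citrullinome.proteome_core import AbundanceTable
from citrullinome.synthetic_data import LfqSimConfig, gen_lfq_dataset, gen_toy_structure


@pytest.fixture(scope="session")
def small_lfq():
    """Small planted LFQ dataset shared across read-only tests."""
    cfg = LfqSimConfig(n_proteins=60, n_per_group=8, module_sizes=(10, 8),
                       n_de=4, n_de_down=1, seed=11)
    return gen_lfq_dataset(cfg)


@pytest.fixture()
def tiny_table():
    """Hand-sized 4-protein, 6-sample table with known holes."""
    values = pd.DataFrame(
        [[10.0, 11.0, 12.0, 20.0, 21.0, 22.0],
         [10.0, np.nan, 12.0, 20.0, 21.0, np.nan],
         [30.0, 31.0, 32.0, 40.0, 41.0, 42.0],
         [np.nan, np.nan, np.nan, 40.0, 41.0, 42.0]],
        index=["p1", "p2", "p3", "p4"],
        columns=[f"s{i}" for i in range(1, 7)],
    )
    groups = pd.Series(["case"] * 3 + ["control"] * 3, index=values.columns)
    return AbundanceTable(values, groups)


@pytest.fixture(scope="session")
def helix12():
    return gen_toy_structure("helix", 12, seed=3)


@pytest.fixture(scope="session")
def strand8():
    return gen_toy_structure("strand", 8, seed=4)
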