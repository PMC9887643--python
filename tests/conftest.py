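import numpy as np
import pandas as pd
import pytest

from attnmpi import synthdata
from attnmpi.featurize import MetaboliteFeatureTable


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small cohort reused across tests (cheap, deterministic)."""
    cfg = synthdata.SynthConfig(
        n_proteins=24, n_metabolites=24, n_protein_families=8,
        n_metabolite_families=8, seq_len_range=(30, 80), n_pairs=400, seed=7)
    return synthdata.generate_cohort(cfg)


@pytest.fixture
def raw_met_frame():
    rng = np.random.default_rng(42)
    n = 50
    frame = pd.DataFrame({
        "mass": rng.uniform(100, 900, n),
        "xlogp": rng.normal(2, 1, n),
        "count_a": rng.integers(0, 8, n).astype(float),
        "constant": np.ones(n),
        "bit_0": rng.integers(0, 2, n).astype(float),
    }, index=[f"M{i}" for i in range(n)])
    frame.loc[frame.index[:5], "xlogp"] = np.nan
    return frame


@pytest.fixture
def raw_met_table(raw_met_frame):
    return MetaboliteFeatureTable.from_dataframe(raw_met_frame)
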