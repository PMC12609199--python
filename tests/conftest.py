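import numpy as np
import pandas as pd
import pytest

from masldscreen.config import PipelineConfig
from masldscreen.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """An 80-compound, 10-target synthetic screen with ground truth."""
    return generate_dataset(SyntheticSpec(n_compounds=80, seed=7))


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig().validate()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def toy_records():
    """Hand-built bioactivity records covering replicates, salts, and an
    invalid structure."""
    rows = []

    def add(ref, smiles, target, ic50s, ts=0):
        for i, v in enumerate(ic50s):
            rows.append({"compound_ref": ref, "smiles": smiles,
                         "target_id": target, "ic50_nM": v,
                         "replicate_group": f"{ref}:{target}",
                         "timestamp": ts})

    add("ethanol", "CCO", "T0", [100, 200, 900])
    add("ethanol_salt", "CCO.[Na+]", "T0", [150])
    add("flat", "c1ccccc1O", "T0", [100, 100, 100])
    add("noisy", "c1ccccc1N", "T0", [100, 400, 1600])
    add("bad", "not_a_smiles", "T0", [50])
    add("inactive", "c1ccccc1C", "T1", [5000])
    return pd.DataFrame(rows)
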