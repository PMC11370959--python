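import numpy as np
import pandas as pd
import pytest

import ewas_hypogen as eh


@pytest.fixture(scope="session")
def table1():
    return eh.table1_fixture()


@pytest.fixture(scope="session")
def dys_fixture():
    return eh.dysmenorrhea_catalog_fixture()


@pytest.fixture(scope="session")
def hmb_fixture():
    return eh.hmb_catalog_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset with all three planted probe roles."""
    config = eh.SimulationConfig(
        n_samples=200,
        n_probes=400,
        n_direct_probes=5,
        n_confounded_probes=10,
        n_batch_probes=40,
        seed=11,
    )
    return eh.generate_dataset(config)


def status_from_condition(pheno: pd.DataFrame, column: str = "condition") -> pd.DataFrame:
    status = pd.Series("excluded", index=pheno.index, dtype=object)
    status[pheno[column] == 1] = "case"
    status[pheno[column] == 0] = "control"
    return pd.DataFrame({"status": status, "first_report_wave": np.nan, "reason": ""})
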