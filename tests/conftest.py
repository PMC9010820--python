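import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stromacomp import QuantTable, SampleSheet, default_cohort_config, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_table() -> QuantTable:
    """3 proteins x 2 samples with one missing cell, linear scale."""
    data = pd.DataFrame(
        {"S1": [8.0, 1.0, 4.0], "S2": [2.0, np.nan, 16.0]},
        index=["PA", "PB", "PC"],
    )
    return QuantTable(data, scale="linear")


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    meta = pd.DataFrame(
        {
            "patient_id": ["PT1", "PT1"],
            "preparation": ["LCM", "LCM"],
            "compartment": ["epithelium", "stroma"],
            "stage": ["adjacent", "adjacent"],
        },
        index=pd.Index(["S1", "S2"], name="sample_id"),
    )
    return SampleSheet(meta)


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down default cohort shared across tests (read-only)."""
    cfg = default_cohort_config(seed=11, n_patients=8, n_proteins=900)
    return generate_cohort(cfg)
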