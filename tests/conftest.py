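import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_recording():
    """A 5-hour artifact-free nocturnal recording with RMSSD target 40 ms."""
    from resthrv import IbiGenConfig, generate_ibi_recording

    return generate_ibi_recording(IbiGenConfig(duration=18000.0, seed=11))


@pytest.fixture()
def identity_panel():
    """Panel where y duplicates x exactly at both levels."""
    from resthrv.synthetic_data import PanelDataset

    rng = np.random.default_rng(0)
    rows = []
    for i in range(20):
        for d in range(5):
            v = float(rng.normal(i * 0.5, 1.0))
            rows.append((f"p{i:02d}", d, "x", v))
            rows.append((f"p{i:02d}", d, "y", v))
    data = pd.DataFrame(rows, columns=["person_id", "day_index",
                                       "variable", "value"])
    persons = pd.DataFrame({"person_id": data["person_id"].unique()})
    return PanelDataset(data=data, persons=persons)
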