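import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def tiny_pheno() -> pd.DataFrame:
    """Four hybrids, two traits, two years of injury indices."""
    rng = np.random.default_rng(0)
    rows = []
    for hid in ["H1", "H2", "H3", "H4"]:
        base = rng.uniform(0.2, 0.8)
        for year in (2015, 2016):
            for trait in ("SID", "AID"):
                rows.append({"hybrid_id": hid, "year": year, "trait": trait,
                             "value": float(np.clip(base + rng.normal(0, 0.05), 0, 1))})
    return pd.DataFrame(rows)
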