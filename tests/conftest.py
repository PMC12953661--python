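import numpy as np
import pandas as pd
import pytest

from lesionnet.synthetic import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_hc=140, n_aoms=80, n_loms=60, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def hc_reference_frame() -> pd.DataFrame:
    """Healthy-control rows generated from a known linear model."""
    rng = np.random.default_rng(42)
    n_per_center = 200
    centers = ["C1", "C2", "C3"]
    sigmas = {"C1": 1.0, "C2": 2.0, "C3": 0.5}
    rows = []
    for c in centers:
        age = rng.uniform(20, 70, n_per_center)
        male = rng.integers(0, 2, n_per_center)
        y = (
            10.0
            + 1.5 * male
            - 0.1 * (age - 45.0)
            + 0.05 * male * (age - 45.0)
            + {"C1": 0.0, "C2": 3.0, "C3": -2.0}[c]
            + rng.normal(0, sigmas[c], n_per_center)
        )
        rows.append(
            pd.DataFrame(
                {
                    "center_id": c,
                    "sex": np.where(male == 1, "M", "F"),
                    "age_at_mri": age,
                    "value": y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
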