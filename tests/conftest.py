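import numpy as np
import pandas as pd
import pytest

from multibatch import SimConfig, simulate_experiment


def rates_frame(batch_rates: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    """Build a rate table from {batch: {group: [rates]}} literals."""
    rows = []
    for batch, groups in batch_rates.items():
        for group, values in groups.items():
            for i, r in enumerate(values):
                rows.append((f"{batch}{group[0].upper()}{i}", batch, group, r))
    return pd.DataFrame(rows, columns=["animal_id", "batch_id", "group", "rate"])


@pytest.fixture(scope="session")
def mc38_base() -> SimConfig:
    """Baseline growth-rate characteristics of the MC38 calibration dataset."""
    return SimConfig(baseline_mean=0.105, baseline_sd=0.026)


@pytest.fixture(scope="session")
def effect_dataset() -> pd.DataFrame:
    """One simulated 3-batch experiment with a 30% inhibition (seeded)."""
    cfg = SimConfig(baseline_mean=0.105, baseline_sd=0.026, gri=0.3, seed=7)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def null_dataset() -> pd.DataFrame:
    """One simulated null 3-batch experiment with strong batch effects."""
    cfg = SimConfig(baseline_mean=0.105, baseline_sd=0.026, batch_sd_prop=0.2,
                    seed=12345)
    return simulate_experiment(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
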