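import numpy as np
import pandas as pd
import pytest

import marchphys as mp


@pytest.fixture(scope="session")
def clean_dataset():
    """Small noise-free cohort: generator truth must be exactly recoverable."""
    return mp.generate_dataset(
        n_soldiers=9,
        seed=42,
        hr_noise_sd=0.0,
        intake_noise_frac=0.0,
        dropout_hazard_per_pain_point=0.0,
        bct_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default study conditions (sensor noise, dropouts) at full cohort size."""
    return mp.generate_dataset(seed=7)


def make_minutes(step_freq, hr=130.0, bct=37.5, hacc=None, start="2020-03-05 15:11"):
    """Minute-grid frame from a step-frequency sequence and scalar/array channels."""
    step = np.asarray(step_freq, dtype=float)
    n = len(step)
    if hacc is None:
        hacc = np.where(step > 1.0, 6000.0, 300.0)
    return pd.DataFrame({
        "minute_index": np.arange(n),
        "clock": pd.Timestamp(start) + pd.to_timedelta(np.arange(n), unit="min"),
        "hr": np.broadcast_to(np.asarray(hr, dtype=float), (n,)).copy(),
        "bct": np.broadcast_to(np.asarray(bct, dtype=float), (n,)).copy(),
        "hacc": np.broadcast_to(np.asarray(hacc, dtype=float), (n,)).copy(),
        "step_freq": step,
    })
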