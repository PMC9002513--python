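import numpy as np
import pandas as pd
import pytest

from paqc.simulate import SynthConfig, make_fixture_dataset


def make_paired(a, b, t0="2021-01-01", step_s=120, algorithm="ALT_CF3"):
    """Paired-observation frame straight from channel value arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(total > 0, np.abs(a - b) / total, np.nan)
    return pd.DataFrame(
        {
            "timestamp": pd.date_range(t0, periods=a.size, freq=f"{step_s}s", tz="UTC"),
            "a_value": a,
            "b_value": b,
            "mu": (a + b) / 2,
            "sigma": np.abs(a - b) / np.sqrt(2),
            "precision": precision,
            "algorithm": algorithm,
        }
    )


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A deterministic 2-day indoor+outdoor synthetic dataset on disk."""
    out = tmp_path_factory.mktemp("fixture")
    cfg = SynthConfig(duration_hours=48, seed=11)
    paths = make_fixture_dataset(cfg, out)
    return cfg, paths
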