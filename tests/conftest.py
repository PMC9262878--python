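import numpy as np
import pandas as pd
import pytest

from ltdsm.detection import DetectionConfig, fit_detection


@pytest.fixture(scope="session")
def halfnormal_sample():
    """500 one-sided distances from a half-normal (sigma = 600 m), w = 1750 m."""
    rng = np.random.default_rng(42)
    x = np.abs(rng.normal(0.0, 600.0, 4000))
    x = x[x <= 1750.0][:500]
    return pd.DataFrame({"perp_distance": x})


@pytest.fixture(scope="session")
def halfnormal_fit(halfnormal_sample):
    return fit_detection(
        halfnormal_sample, DetectionConfig("half-normal", "none", (), 1750.0)
    )


@pytest.fixture(scope="session")
def straight_track():
    """A single straight 12-km on-effort transect with fixes every 0.5 km."""
    d = np.arange(0.0, 12.0001, 0.5)
    return pd.DataFrame(
        {
            "transect_id": "T1",
            "timestamp": pd.Timestamp("2018-04-01T10:00:00")
            + pd.to_timedelta(d / 160.0, unit="h"),
            "x": d,
            "y": np.zeros_like(d),
            "on_effort": True,
        }
    )
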