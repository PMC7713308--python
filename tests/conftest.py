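import numpy as np
import pandas as pd
import pytest

from arstrack import SimConfig, simulate_tracks
from arstrack.argos_io import segment_all


def make_obs(times_h, tag="W1", lc="3", lon=140.0, lat=-38.0, t0="2015-01-21"):
    """Observation frame with fixes at the given hours from t0."""
    t0 = pd.Timestamp(t0, tz="UTC")
    n = len(times_h)
    return pd.DataFrame(
        {
            "tag_id": tag,
            "timestamp": [t0 + pd.Timedelta(hours=float(h)) for h in times_h],
            "lc": lc,
            "lon": np.full(n, lon, dtype=float),
            "lat": np.full(n, lat, dtype=float),
        }
    )


@pytest.fixture(scope="session")
def small_sim():
    """Two whales, 200 regular steps, default stated-world parameters."""
    cfg = SimConfig(n_whales=2, n_steps=200, seed=7)
    obs, truth = simulate_tracks(cfg)
    return cfg, obs, truth


@pytest.fixture(scope="session")
def small_segments(small_sim):
    _, obs, _ = small_sim
    return segment_all(obs)
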