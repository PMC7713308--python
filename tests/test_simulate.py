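"""The synthetic-data generator: track process, observation process, rasters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arstrack import SimConfig, simulate_tracks, simulate_seascape
from arstrack.argos_io import LC_CLASSES, mean_interval
from arstrack.simulate import ArgosErrorModel, SstLink


def tiny_error_model():
    eps = 1e-9
    return ArgosErrorModel(
        scales={c: (eps, eps) for c in LC_CLASSES},
        df={c: 50.0 for c in LC_CLASSES},
    )


class TestSimulateTracks:
    def test_zero_noise_limit_observations_on_path(self):
        # near-zero error and equal persistence: fixes fall on the
        # interpolated true path
        cfg = SimConfig(
            n_whales=1,
            n_steps=50,
            seed=3,
            gamma_transit=0.500001,
            gamma_ars=0.5,
            error_model=tiny_error_model(),
        )
        obs, truth = simulate_tracks(cfg)
        tag = obs["tag_id"].iloc[0]
        h = (
            (obs["timestamp"] - truth.tracks[tag]["t0"]) / pd.Timedelta(hours=1)
        ).to_numpy()
        pos = truth.positions_at(tag, h)
        np.testing.assert_allclose(obs["lon"].to_numpy(), pos[:, 0], atol=1e-6)
        np.testing.assert_allclose(obs["lat"].to_numpy(), pos[:, 1], atol=1e-6)

    def test_absorbing_chain_stays_in_ars(self):
        cfg = SimConfig(
            n_whales=1,
            n_steps=100,
            seed=4,
            switch_prob=np.eye(2),
            initial_state=2,
        )
        _, truth = simulate_tracks(cfg)
        assert (truth.tracks["SIM00"]["b"] == 2).all()

    def test_transit_more_autocorrelated_than_ars(self):
        cfg = SimConfig(n_whales=1, n_steps=2000, seed=1)
        _, truth = simulate_tracks(cfg)
        tr = truth.tracks["SIM00"]
        d = np.diff(np.column_stack([tr["lon"], tr["lat"]]), axis=0)
        b = tr["b"][1:]

        def lag1_within(state):
            # lag-1 correlation of step vectors over pairs inside one state run
            idx = np.where((b[:-1] == state) & (b[1:] == state))[0]
            a, c = d[idx].ravel(), d[idx + 1].ravel()
            return np.corrcoef(a, c)[0, 1]

        assert lag1_within(1) > lag1_within(2)

    def test_bit_reproducible_under_seed(self):
        cfg = SimConfig(n_whales=2, n_steps=100, seed=9)
        obs1, truth1 = simulate_tracks(cfg)
        obs2, truth2 = simulate_tracks(SimConfig(n_whales=2, n_steps=100, seed=9))
        pd.testing.assert_frame_equal(obs1, obs2)
        for tag in truth1.tracks:
            np.testing.assert_array_equal(
                truth1.tracks[tag]["lon"], truth2.tracks[tag]["lon"]
            )
            np.testing.assert_array_equal(truth1.tracks[tag]["b"], truth2.tracks[tag]["b"])

    def test_interval_and_class_mix_converge(self):
        # one long track: ~1e4 fixes
        cfg = SimConfig(n_whales=1, n_steps=10_000, seed=2)
        obs, _ = simulate_tracks(cfg)
        assert len(obs) > 8000
        est = mean_interval(obs)
        assert est == pytest.approx(cfg.mean_obs_interval, rel=0.05)
        counts = obs["lc"].value_counts()
        observed = np.array([counts.get(c, 0) for c in LC_CLASSES])
        expected = np.array([cfg.class_mix[c] for c in LC_CLASSES]) * len(obs)
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01

    def test_explicit_gap_schedule_creates_gap(self):
        cfg = SimConfig(
            n_whales=1, n_steps=200, seed=5, gap_schedule={0: [(100.0, 60.0)]}
        )
        obs, _ = simulate_tracks(cfg)
        h = (
            (obs["timestamp"] - obs["timestamp"].iloc[0]) / pd.Timedelta(hours=1)
        ).to_numpy()
        assert not ((h > 100.0) & (h < 160.0)).any()
        assert np.max(np.diff(h)) >= 55.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_steps=2)
        with pytest.raises(ValueError):
            SimConfig(gamma_transit=1.2)
        with pytest.raises(ValueError):
            SimConfig(gamma_transit=0.2, gamma_ars=0.8)
        with pytest.raises(ValueError):
            SimConfig(switch_prob=np.array([[0.7, 0.2], [0.5, 0.5]]))

    def test_error_scale_ordering_enforced(self):
        scales = dict(ArgosErrorModel().scales)
        scales["2"] = (1e-4, 1e-4)  # better than class 3: invalid
        with pytest.raises(ValueError):
            ArgosErrorModel(scales=scales)


class TestSimulateSeascape:
    BBOX = (130.0, -42.0, 145.0, -32.0)

    def test_constant_field_option(self):
        fields = simulate_seascape(self.BBOX, constants={"sst": 15.0}, seed=1)
        assert float(fields.data["sst"].min()) == 15.0 == float(fields.data["sst"].max())

    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError):
            simulate_seascape((140.0, -38.0, 140.0, -30.0))

    def test_unlinked_sst_uncorrelated_with_states(self):
        cfg = SimConfig(n_whales=2, n_steps=1000, seed=8)
        _, truth = simulate_tracks(cfg)
        fields = simulate_seascape(self.BBOX, seed=80)
        ds = fields.data
        lon, lat, b, when = [], [], [], []
        for tr in truth.tracks.values():
            lon.extend(tr["lon"])
            lat.extend(tr["lat"])
            b.extend(tr["b"])
            when.extend(tr["t0"].tz_localize(None) + pd.to_timedelta(tr["times_h"], unit="h"))
        lon, lat, b = np.array(lon), np.array(lat), np.array(b)
        ix = np.clip(np.searchsorted(ds.lon.values, lon), 0, len(ds.lon) - 1)
        iy = np.clip(np.searchsorted(ds.lat.values, lat), 0, len(ds.lat) - 1)
        it = np.clip(pd.DatetimeIndex(ds.time.values).searchsorted(pd.DatetimeIndex(when)), 0, len(ds.time) - 1)
        sst = ds["sst"].values[it, iy, ix][:2000]
        rho = np.corrcoef(sst, (b == 2)[:2000])[0, 1]
        assert abs(rho) < 0.1

    def test_link_pulls_ars_into_band(self):
        from arstrack.simulate import nearest_cell_index, nearest_time_index

        cfg = SimConfig(n_whales=2, n_steps=800, seed=8)
        _, truth = simulate_tracks(cfg)
        fields = simulate_seascape(
            self.BBOX, link=SstLink(truth, band=(14.0, 17.0)), seed=81
        )
        ds = fields.data
        frac = {}
        for state in (1, 2):
            vals = []
            for tr in truth.tracks.values():
                sel = tr["b"] == state
                ix = nearest_cell_index(ds.lon.values, tr["lon"][sel])
                iy = nearest_cell_index(ds.lat.values, tr["lat"][sel])
                when = pd.DatetimeIndex(
                    tr["t0"].tz_localize(None)
                    + pd.to_timedelta(tr["times_h"][sel], unit="h")
                )
                it = nearest_time_index(pd.DatetimeIndex(ds.time.values), when)
                vals.extend(ds["sst"].values[it, iy, ix])
            vals = np.array(vals)
            frac[state] = np.mean((vals >= 14.0) & (vals <= 17.0))
        assert frac[2] > frac[1] + 0.3  # the link concentrates ARS in band

    def test_netcdf_roundtrip(self, tmp_path):
        from arstrack.simulate import SeascapeFieldSet

        fields = simulate_seascape(self.BBOX, seed=3)
        p = tmp_path / "fields.nc"
        fields.to_netcdf(p)
        back = SeascapeFieldSet.from_netcdf(p)
        np.testing.assert_allclose(
            back.data["sst"].values, fields.data["sst"].values, rtol=1e-6
        )
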