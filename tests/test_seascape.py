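"""Covariate extraction (lags, windows, transforms) and collinearity screen."""

import numpy as np
import pandas as pd
import pytest

from arstrack import ExtractionSpec, extract, screen_collinearity, simulate_seascape
from arstrack.simulate import SeascapeFieldSet

BBOX = (138.0, -40.0, 142.0, -36.0)


def make_fields(sst=None, chla=None, seed=0, **kwargs):
    constants = {}
    if sst is not None:
        constants["sst"] = sst
    if chla is not None:
        constants["chla"] = chla
    return simulate_seascape(BBOX, constants=constants or None, seed=seed, **kwargs)


def make_locations(n=10, lon=140.0, lat=-38.0, t0="2015-03-01"):
    t0 = pd.Timestamp(t0, tz="UTC")
    return pd.DataFrame(
        {
            "tag_id": "W1",
            "timestamp": [t0 + pd.Timedelta(hours=3 * i) for i in range(n)],
            "lon": lon,
            "lat": lat,
            "mode_state": 1,
        }
    )


SPEC = ExtractionSpec(wind_point=(140.0, -38.0))


class TestExtract:
    def test_constant_field_extracts_constant(self):
        fields = make_fields(sst=15.0)
        mat, meta = extract(make_locations(), fields, SPEC)
        assert (mat["sst"] == 15.0).all()
        assert meta["n_missing"] == 0

    def test_sd_of_uniform_field_is_zero(self):
        fields = make_fields(sst=15.0)
        mat, _ = extract(make_locations(), fields, SPEC)
        assert (mat["sst_sd"] == 0.0).all()

    def test_lagged_mean_tracks_window_overlap(self):
        # chla = 1 before the switch date, 0 after: the 30-day prior mean
        # equals the fraction of the window before the switch
        fields = make_fields(seed=1)
        ds = fields.data
        switch = pd.Timestamp("2015-04-01")
        chla = np.where(
            (pd.DatetimeIndex(ds.time.values) < switch)[:, None, None], 1.0, 0.0
        ) * np.ones_like(ds["chla"].values)
        ds["chla"] = (("time", "lat", "lon"), chla)
        spec = ExtractionSpec(wind_point=(140.0, -38.0), log_chla=False)
        times = pd.DatetimeIndex(ds.time.values)

        for when, expected in [
            ("2015-03-20", 1.0),  # window fully before the switch
            ("2015-06-20", 0.0),  # window fully after
        ]:
            loc = make_locations(n=1, t0=when)
            mat, _ = extract(loc, fields, spec)
            assert mat["chla"].iloc[0] == pytest.approx(expected)

        # partial overlap: oracle = mean over slices inside the window
        when = pd.Timestamp("2015-04-15", tz="UTC")
        loc = make_locations(n=1, t0=str(when.date()))
        mat, _ = extract(loc, fields, spec)
        naive = when.tz_localize(None)
        in_win = (times >= naive - pd.Timedelta(days=30)) & (times <= naive)
        oracle = float((times[in_win] < switch).mean())
        assert mat["chla"].iloc[0] == pytest.approx(oracle)
        assert 0.0 < oracle < 1.0

    def test_lag_window_before_raster_start_is_missing(self):
        fields = make_fields(seed=2)
        loc = make_locations(n=1, t0="2015-01-05")  # 30-day window precedes start
        mat, meta = extract(loc, fields, SPEC)
        assert np.isnan(mat["chla"].iloc[0])
        assert meta["n_missing"] == 1

    def test_location_outside_raster_is_missing_row(self):
        fields = make_fields(seed=3)
        loc = make_locations(n=2, lon=150.0)  # east of bbox
        mat, meta = extract(loc, fields, SPEC)
        assert mat["sst"].isna().all()
        assert meta["n_missing"] == 2

    def test_wind_sampled_at_point_not_at_whale(self):
        fields = make_fields(seed=4)
        far = make_locations(n=3, lon=141.5, lat=-39.5, t0="2015-03-01")
        near = make_locations(n=3, lon=138.5, lat=-36.5, t0="2015-03-01")
        m1, _ = extract(far, fields, SPEC)
        m2, _ = extract(near, fields, SPEC)
        np.testing.assert_allclose(m1["wind_speed"], m2["wind_speed"])
        with pytest.raises(ValueError):
            extract(far, fields, ExtractionSpec(wind_point=None))

    def test_transforms_applied_once_and_flagged(self):
        fields = make_fields(chla=np.e, seed=5)
        mat, meta = extract(make_locations(), fields, SPEC)
        assert mat["chla"].iloc[0] == pytest.approx(1.0)  # log(e)
        assert (mat["depth"] > 0).all()  # log of positive depth magnitude
        assert meta["transforms"]["chla"] == "log"

    def test_deterministic_and_time_shift_commutes(self):
        fields = make_fields(seed=6)
        loc = make_locations(n=5, t0="2015-03-10")
        m1, _ = extract(loc, fields, SPEC)
        m2, _ = extract(loc, fields, SPEC)
        pd.testing.assert_frame_equal(m1, m2)
        # shift both raster times and locations by 16 days: lagged values match
        shift = pd.Timedelta(days=16)
        ds2 = fields.data.copy()
        ds2 = ds2.assign_coords(time=pd.DatetimeIndex(ds2.time.values) + shift)
        loc2 = loc.copy()
        loc2["timestamp"] = loc2["timestamp"] + shift
        m3, _ = extract(loc2, SeascapeFieldSet(ds2), SPEC)
        np.testing.assert_allclose(m1["chla"], m3["chla"])
        np.testing.assert_allclose(m1["wind_speed"], m3["wind_speed"])


class TestScreenCollinearity:
    def make_matrix(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, 4)), columns=["v1", "v2", "v3", "v4"])

    def test_duplicated_column_dropped(self):
        m = self.make_matrix()
        m["v1_copy"] = m["v1"]
        rep = screen_collinearity(m)
        assert ("v1_copy", "v1") in [(d, r.split()[-1]) for d, r in rep.dropped]
        assert "v1" in rep.kept and "v1_copy" not in rep.kept

    def test_orthogonal_columns_none_dropped(self):
        rep = screen_collinearity(self.make_matrix(seed=1))
        assert rep.dropped == []
        # VIF of orthogonal standardised columns is 1 (+- eps)
        assert np.allclose(rep.vif.to_numpy(), 1.0, atol=0.05)

    def test_chla_lag_family_keeps_30day(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=800)
        m = pd.DataFrame(
            {
                "chla_14d": base + rng.normal(0, 0.05, 800),
                "chla_30d": base,
                "sst": rng.normal(size=800),
            }
        )
        rep = screen_collinearity(m)
        assert "chla_30d" in rep.kept and "chla_14d" not in rep.kept

    def test_sd_scale_family_keeps_100km(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=800)
        m = pd.DataFrame(
            {
                "sst_sd_50km": base + rng.normal(0, 0.05, 800),
                "sst_sd_100km": base,
                "depth": rng.normal(size=800),
            }
        )
        rep = screen_collinearity(m)
        assert "sst_sd_100km" in rep.kept and "sst_sd_50km" not in rep.kept

    def test_high_vif_variable_dropped(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=1000)
        b = rng.normal(size=1000)
        m = pd.DataFrame({"v1": a, "v2": b, "v3": a + b + rng.normal(0, 0.3, 1000)})
        rep = screen_collinearity(m)
        assert any("VIF" in reason for _, reason in rep.dropped)

    def test_constant_column_flagged(self):
        m = self.make_matrix()
        m["const"] = 1.0
        rep = screen_collinearity(m)
        assert any(d == "const" and "constant" in r for d, r in rep.dropped)

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            screen_collinearity(pd.DataFrame({"v1": [1.0, 2.0, 3.0]}))
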