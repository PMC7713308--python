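"""Synthetic Argos tracks and seascape rasters with known ground truth.

The generator emulates the observation process of a satellite-tagged
whale: the animal moves on a regular time grid according to a two-state
switching first-difference correlated random walk (transit vs.
area-restricted search, ARS), while the Argos system returns fixes at
irregular times, with multi-day transmission gaps, a realistic mix of
quality classes, and heavy-tailed class-dependent location error.

Defaults mirror a summer deployment of ~13 whales in the Bonney Upwelling
region (January–March deployments, transmissions averaging one per
2.3 h), with state-specific move persistence 0.8 (transit) vs 0.2 (ARS)
and multi-day behavioural dwell times.

Seascape rasters are smooth random fields — statistical stand-ins with no
ocean physics.  An optional *link* warps sea-surface temperature so that
cells visited during true ARS preferentially carry values inside a
configured thermal band (default 14–17 °C), giving downstream habitat
models a positive control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from arstrack.argos_io import LC_CLASSES, OBS_COLUMNS

# Per-class t-error scales (degrees lon, degrees lat) and degrees of
# freedom.  The tracking literature gives Argos class errors from a few
# hundred metres (class 3) to tens of km (B/Z) with heavy tails; these
# defaults follow published Argos calibrations and are fully configurable.
_DEFAULT_SCALES = {
    "3": (0.0025, 0.0020),
    "2": (0.0050, 0.0040),
    "1": (0.0120, 0.0090),
    "0": (0.0350, 0.0280),
    "A": (0.0350, 0.0280),
    "B": (0.0700, 0.0550),
    "Z": (0.1500, 0.1200),
}
_DEFAULT_DF = {"3": 8.0, "2": 6.0, "1": 4.0, "0": 3.0, "A": 3.0, "B": 2.5, "Z": 2.0}

# Argos class mix typical of whale surface behaviour: dominated by the
# low-quality A/B classes, with a small fraction of invalid-grade Z.
_DEFAULT_CLASS_MIX = {
    "3": 0.04,
    "2": 0.07,
    "1": 0.11,
    "0": 0.14,
    "A": 0.21,
    "B": 0.37,
    "Z": 0.06,
}


@dataclass(frozen=True)
class ArgosErrorModel:
    """Heavy-tailed (Student-t) Argos location error, per quality class.

    ``scales`` maps each class to (lon, lat) scale in degrees; ``df`` maps
    each class to the t degrees of freedom.  Scales must be strictly
    positive and non-decreasing from class 3 through class B.
    """

    scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SCALES)
    )
    df: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DF))

    def __post_init__(self) -> None:
        for lc in LC_CLASSES:
            if lc not in self.scales or lc not in self.df:
                raise ValueError(f"error model missing class {lc!r}")
            if min(self.scales[lc]) <= 0:
                raise ValueError(f"error scales must be positive (class {lc!r})")
        order = ("3", "2", "1", "0", "A", "B")
        for axis in (0, 1):
            s = [self.scales[lc][axis] for lc in order]
            if any(a > b for a, b in zip(s, s[1:])):
                raise ValueError("error scales must be non-decreasing from 3 to B")

    def scale_arrays(self, lc: np.ndarray) -> np.ndarray:
        """(n, 2) array of per-observation (lon, lat) scales."""
        return np.array([self.scales[c] for c in lc])

    def df_array(self, lc: np.ndarray) -> np.ndarray:
        return np.array([self.df[c] for c in lc])

    def scaled(self, factor: float) -> "ArgosErrorModel":
        """Error model with every scale multiplied by ``factor``."""
        return ArgosErrorModel(
            scales={k: (a * factor, b * factor) for k, (a, b) in self.scales.items()},
            df=dict(self.df),
        )


@dataclass
class SimConfig:
    """Stated world for the track generator.

    States are coded 1 = transit, 2 = ARS.  ``switch_prob[i, j]`` is the
    probability of moving from state i+1 to state j+1 per 3-h step; the
    default gives multi-day mean dwell in both states.  ``gap_schedule``
    maps a whale index to explicit transmission gaps as (start_h,
    duration_h) pairs measured from that whale's deployment, so
    segmentation tests are deterministic.
    """

    n_whales: int = 13
    n_steps: int = 800
    dt_hours: float = 3.0
    deploy_start: str = "2015-01-21"
    deploy_end: str = "2015-03-13"
    deploy_bbox: tuple[float, float, float, float] = (139.6, -39.6, 140.9, -38.4)
    mean_obs_interval: float = 2.3
    gap_schedule: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_MIX)
    )
    gamma_transit: float = 0.8
    gamma_ars: float = 0.2
    Sigma: np.ndarray = field(
        default_factory=lambda: np.array([[1.6e-3, 0.0], [0.0, 1.6e-3]])
    )
    switch_prob: np.ndarray = field(
        default_factory=lambda: np.array([[0.95, 0.05], [0.05, 0.95]])
    )
    initial_state: int | None = None  # 1, 2, or None for the stationary draw
    error_model: ArgosErrorModel = field(default_factory=ArgosErrorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.switch_prob = np.asarray(self.switch_prob, dtype=float)
        if self.n_steps < 3:
            raise ValueError("need at least 3 regular steps (n_steps >= 3)")
        if not (0.0 < self.gamma_ars < 1.0 and 0.0 < self.gamma_transit < 1.0):
            raise ValueError("move persistence must lie strictly in (0, 1)")
        if not self.gamma_ars < self.gamma_transit:
            raise ValueError("require gamma_ars < gamma_transit")
        if self.switch_prob.shape != (2, 2) or not np.allclose(
            self.switch_prob.sum(axis=1), 1.0
        ):
            raise ValueError("switch_prob rows must sum to 1")
        if (self.switch_prob < 0).any():
            raise ValueError("switch_prob entries must be non-negative")
        if self.Sigma.shape != (2, 2) or np.linalg.eigvalsh(self.Sigma).min() <= 0:
            raise ValueError("Sigma must be 2x2 positive definite")
        total = sum(self.class_mix.get(lc, 0.0) for lc in LC_CLASSES)
        if not np.isclose(total, 1.0):
            raise ValueError("class_mix must sum to 1 over the 7 Argos classes")
        if self.mean_obs_interval <= 0:
            raise ValueError("mean_obs_interval must be positive")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated observations.

    Per whale (keyed by tag id): deployment time ``t0``, regular step
    times in hours from ``t0``, true lon/lat at each step, and the true
    behavioural state ``b`` in {1, 2}.
    """

    tracks: dict[str, dict]
    config: SimConfig

    def states_at(self, tag_id: str, hours: np.ndarray) -> np.ndarray:
        """True state at the nearest regular step to each queried time."""
        tr = self.tracks[tag_id]
        idx = np.clip(
            np.rint(np.asarray(hours, dtype=float) / self.config.dt_hours),
            0,
            len(tr["b"]) - 1,
        ).astype(int)
        return tr["b"][idx]

    def positions_at(self, tag_id: str, hours: np.ndarray) -> np.ndarray:
        """Linear interpolation of the true path at arbitrary times."""
        tr = self.tracks[tag_id]
        h = np.asarray(hours, dtype=float)
        lon = np.interp(h, tr["times_h"], tr["lon"])
        lat = np.interp(h, tr["times_h"], tr["lat"])
        return np.column_stack([lon, lat])


def _simulate_states(rng, config: SimConfig, n: int) -> np.ndarray:
    """Markov-chain states in {0, 1} (0 = transit, 1 = ARS)."""
    A = config.switch_prob
    if config.initial_state is not None:
        s = config.initial_state - 1
    else:
        # stationary distribution of the 2-state chain
        p12, p21 = A[0, 1], A[1, 0]
        pi_ars = p12 / (p12 + p21) if (p12 + p21) > 0 else 0.5
        s = int(rng.random() < pi_ars)
    out = np.empty(n, dtype=np.int8)
    u = rng.random(n)
    for t in range(n):
        out[t] = s
        if u[t] >= A[s, s]:
            s = 1 - s
    return out


def simulate_tracks(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate Argos-like observations from a switching random walk.

    For each whale a first-difference correlated random walk is simulated
    on a regular ``dt_hours`` grid: ``d_t = gamma[b_t] * d_{t-1} +
    eps_t``, ``eps_t ~ N(0, Sigma)``, positions the cumulative sum of the
    displacements and states ``b_t`` following the configured Markov
    chain.  Observation times arrive as a Poisson process (exponential
    inter-arrivals with mean ``mean_obs_interval`` hours), with arrivals
    inside scheduled gaps deleted; each fix is the linear interpolation
    of the true path at its time plus class-specific heavy-tailed error.

    Returns a time-sorted observation frame (``tag_id, timestamp, lc,
    lon, lat``) and the :class:`SimTruth`.  Bit-reproducible under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    L = np.linalg.cholesky(config.Sigma)
    gamma = np.array([config.gamma_transit, config.gamma_ars])
    lon0, lat0, lon1, lat1 = config.deploy_bbox
    t_start = pd.Timestamp(config.deploy_start, tz="UTC")
    t_end = pd.Timestamp(config.deploy_end, tz="UTC")
    window_h = max((t_end - t_start) / pd.Timedelta(hours=1), 0.0)
    classes = np.array(LC_CLASSES)
    mix = np.array([config.class_mix[c] for c in LC_CLASSES])
    mix = mix / mix.sum()

    frames = []
    tracks: dict[str, dict] = {}
    n = config.n_steps
    span_h = (n - 1) * config.dt_hours
    for w in range(config.n_whales):
        tag = f"SIM{w:02d}"
        if config.n_whales > 1:
            deploy = t_start + pd.Timedelta(hours=window_h * w / (config.n_whales - 1))
        else:
            deploy = t_start
        b = _simulate_states(rng, config, n)
        eps = rng.standard_normal((n, 2)) @ L.T
        d = np.empty((n, 2))
        d[0] = eps[0]
        for t in range(1, n):
            d[t] = gamma[b[t]] * d[t - 1] + eps[t]
        x0 = np.array([rng.uniform(lon0, lon1), rng.uniform(lat0, lat1)])
        pos = x0 + np.cumsum(d, axis=0) - d[0]
        times_h = np.arange(n) * config.dt_hours

        # irregular observation times: exponential inter-arrivals
        n_expect = int(span_h / config.mean_obs_interval * 1.5) + 20
        arrivals = np.cumsum(rng.exponential(config.mean_obs_interval, n_expect))
        arrivals = arrivals[arrivals <= span_h]
        keep = np.ones(arrivals.shape, dtype=bool)
        for start_h, dur_h in config.gap_schedule.get(w, []):
            keep &= ~((arrivals >= start_h) & (arrivals < start_h + dur_h))
        obs_h = np.concatenate([[0.0], arrivals[keep]])  # a fix at deployment

        lon = np.interp(obs_h, times_h, pos[:, 0])
        lat = np.interp(obs_h, times_h, pos[:, 1])
        lc = classes[rng.choice(len(classes), size=len(obs_h), p=mix)]
        sc = config.error_model.scale_arrays(lc)
        nu = config.error_model.df_array(lc)
        err = rng.standard_t(np.repeat(nu[:, None], 2, axis=1)) * sc
        frames.append(
            pd.DataFrame(
                {
                    "tag_id": tag,
                    "timestamp": deploy + pd.to_timedelta(obs_h, unit="h"),
                    "lc": lc,
                    "lon": lon + err[:, 0],
                    "lat": lat + err[:, 1],
                }
            )
        )
        tracks[tag] = {
            "t0": deploy,
            "times_h": times_h,
            "lon": pos[:, 0],
            "lat": pos[:, 1],
            "b": (b + 1).astype(np.int8),
        }

    obs = pd.concat(frames, ignore_index=True)[OBS_COLUMNS]
    return obs, SimTruth(tracks=tracks, config=config)


# ---------------------------------------------------------------------------
# seascape fields


@dataclass
class SeascapeFieldSet:
    """Named environment rasters on a shared regular lon/lat(/time) grid.

    Wraps an :class:`xarray.Dataset`.  Time-varying variables carry dims
    ``(time, lat, lon)``; static ones (bathymetry and derivatives)
    ``(lat, lon)``.  Depth uses the negative-down convention (ocean
    depth < 0), recorded in the variable attributes.
    """

    data: xr.Dataset

    def __post_init__(self) -> None:
        for c in ("lon", "lat"):
            if c not in self.data.coords:
                raise ValueError(f"field set missing coordinate {c!r}")
        if "time" in self.data.coords and len(self.data.time) > 1:
            dt = np.diff(self.data.time.values.astype("datetime64[ns]").astype(np.int64))
            if not np.allclose(dt, dt[0]):
                raise ValueError("time axis must have a regular cadence")

    @property
    def variables(self) -> list[str]:
        return list(self.data.data_vars)

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        lon = self.data.lon.values
        lat = self.data.lat.values
        return float(lon.min()), float(lat.min()), float(lon.max()), float(lat.max())

    def to_netcdf(self, path) -> None:
        ds = self.data.copy()
        if "time" in ds.coords:
            ds["time"] = ds.time.dt.tz_localize(None) if hasattr(ds.time.dt, "tz_localize") else ds.time
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "SeascapeFieldSet":
        return cls(xr.load_dataset(path, engine="scipy"))


@dataclass(frozen=True)
class SstLink:
    """Warp SST so true-ARS cells preferentially fall in a thermal band.

    With probability ``strength`` each raster cell/time visited during a
    true ARS step is overwritten with a value inside ``band`` and each
    transit-visited cell with a value outside it, leaving a positive
    control for habitat models without creating complete separation.
    """

    truth: SimTruth
    band: tuple[float, float] = (14.0, 17.0)
    strength: float = 0.85


def _smooth_field(rng, shape, sigma_space=6.0, sigma_time=1.0) -> np.ndarray:
    z = rng.standard_normal(shape)
    if len(shape) == 3:
        if sigma_space > 0:
            z = gaussian_filter(z, sigma=(0, sigma_space, sigma_space), mode="nearest")
        if shape[0] > 1 and sigma_time > 0:
            z = gaussian_filter1d(z, sigma=sigma_time, axis=0, mode="nearest")
    elif sigma_space > 0:
        z = gaussian_filter(z, sigma=sigma_space, mode="nearest")
    s = z.std()
    return z / s if s > 0 else z


def simulate_seascape(
    bbox: tuple[float, float, float, float],
    time_start: str = "2015-01-01",
    time_end: str = "2015-08-01",
    cadence_days: float = 8.0,
    resolution_deg: float = 0.05,
    link: SstLink | None = None,
    constants: dict[str, float] | None = None,
    smooth_space_cells: float = 6.0,
    smooth_time_steps: float = 1.0,
    seed: int = 0,
) -> SeascapeFieldSet:
    """Generate smooth random seascape rasters over ``bbox``.

    ``bbox`` is (lon_min, lat_min, lon_max, lat_max) and must be
    non-degenerate.  Fields: ``sst`` (°C), ``ssha`` (m), ``chla``
    (mg m-3, positive), ``wind_speed`` (km h-1), ``wind_direction``
    (deg), ``eke`` (m2 s-2), ``upwelling_index``, and static ``depth``
    (m, negative down) with derived ``rugosity``, ``slope`` and
    ``aspect``.  ``constants`` pins named variables to a constant value
    (useful for extraction tests).  When ``link`` is given, SST is
    warped toward/away from the link band at visited cells.
    """
    lon_min, lat_min, lon_max, lat_max = bbox
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError("degenerate bounding box")
    rng = np.random.default_rng(seed)
    lon = np.arange(lon_min, lon_max + resolution_deg / 2, resolution_deg)
    lat = np.arange(lat_min, lat_max + resolution_deg / 2, resolution_deg)
    t0 = pd.Timestamp(time_start)
    t1 = pd.Timestamp(time_end)
    n_t = max(int(np.floor((t1 - t0) / pd.Timedelta(days=cadence_days))) + 1, 1)
    times = t0 + pd.to_timedelta(np.arange(n_t) * cadence_days, unit="D")
    shape = (n_t, len(lat), len(lon))

    def field(three_d=True, sigma=None):
        return _smooth_field(
            rng,
            shape if three_d else (len(lat), len(lon)),
            sigma_space=smooth_space_cells if sigma is None else sigma,
            sigma_time=smooth_time_steps,
        )

    lat_grad = np.linspace(1.0, -1.0, len(lat))[None, :, None]  # warmer north
    sst = 16.0 + 2.0 * lat_grad + 2.5 * field()
    ssha = 0.12 * field()
    chla = np.exp(-1.0 + 0.8 * field())
    wind_speed = np.clip(15.0 + 6.0 * field(), 0.0, None)
    wind_direction = (180.0 + 90.0 * field()) % 360.0
    eke = np.exp(-3.0 + 0.9 * field())
    upwelling_index = 0.5 * field()
    depth = -2500.0 + 1200.0 * field(three_d=False, sigma=(smooth_space_cells or 6.0) * 4 / 3)
    depth = np.clip(depth, None, -10.0)

    dzdy, dzdx = np.gradient(depth, resolution_deg * 111.0, resolution_deg * 111.0)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy) / 1000.0))
    aspect = (np.degrees(np.arctan2(dzdy, dzdx)) + 360.0) % 360.0
    rugosity = gaussian_filter(np.abs(depth - gaussian_filter(depth, 3.0)), 1.0)

    data = {
        "sst": (("time", "lat", "lon"), sst, {"units": "degC"}),
        "ssha": (("time", "lat", "lon"), ssha, {"units": "m"}),
        "chla": (("time", "lat", "lon"), chla, {"units": "mg m-3"}),
        "wind_speed": (("time", "lat", "lon"), wind_speed, {"units": "km h-1"}),
        "wind_direction": (("time", "lat", "lon"), wind_direction, {"units": "degree"}),
        "eke": (("time", "lat", "lon"), eke, {"units": "m2 s-2"}),
        "upwelling_index": (("time", "lat", "lon"), upwelling_index, {"units": "1"}),
        "depth": (("lat", "lon"), depth, {"units": "m", "positive": "up"}),
        "slope": (("lat", "lon"), slope, {"units": "degree"}),
        "aspect": (("lat", "lon"), aspect, {"units": "degree"}),
        "rugosity": (("lat", "lon"), rugosity, {"units": "m"}),
    }
    ds = xr.Dataset(
        {k: xr.DataArray(v[1], dims=v[0], attrs=v[2]) for k, v in data.items()},
        coords={"lon": lon, "lat": lat, "time": times},
        attrs={"resolution_deg": resolution_deg, "cadence_days": cadence_days},
    )
    if constants:
        for name, value in constants.items():
            ds[name] = xr.full_like(ds[name], float(value))
    if link is not None:
        ds = _apply_sst_link(ds, link, rng)
    return SeascapeFieldSet(ds)


def nearest_cell_index(coord: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Nearest cell-center index on a regular coordinate axis."""
    step = coord[1] - coord[0] if len(coord) > 1 else 1.0
    return np.clip(np.rint((values - coord[0]) / step).astype(int), 0, len(coord) - 1)


def nearest_time_index(times: pd.DatetimeIndex, when: pd.DatetimeIndex) -> np.ndarray:
    """Nearest time-slice index (same convention as covariate extraction)."""
    it = np.clip(times.searchsorted(when, side="right") - 1, 0, len(times) - 1)
    nxt = np.clip(it + 1, 0, len(times) - 1)
    d_prev = np.abs((when - times[it]).to_numpy())
    d_next = np.abs((times[nxt] - when).to_numpy())
    return np.where(d_next < d_prev, nxt, it)


def _apply_sst_link(ds: xr.Dataset, link: SstLink, rng) -> xr.Dataset:
    lo, hi = link.band
    sst = ds["sst"].values.copy()
    lon = ds.lon.values
    lat = ds.lat.values
    times = pd.DatetimeIndex(ds.time.values)
    for tag, tr in link.truth.tracks.items():
        t0 = tr["t0"].tz_localize(None) if tr["t0"].tzinfo else tr["t0"]
        abs_t = pd.DatetimeIndex(t0 + pd.to_timedelta(tr["times_h"], unit="h"))
        it = nearest_time_index(times, abs_t)
        ix = nearest_cell_index(lon, tr["lon"])
        iy = nearest_cell_index(lat, tr["lat"])
        apply = rng.random(len(abs_t)) < link.strength
        in_band = rng.uniform(lo + 0.1, hi - 0.1, len(abs_t))
        # out-of-band values split between below and above the band
        below = rng.random(len(abs_t)) < 0.5
        out_band = np.where(
            below,
            rng.uniform(lo - 4.0, lo - 0.5, len(abs_t)),
            rng.uniform(hi + 0.5, hi + 4.0, len(abs_t)),
        )
        is_ars = tr["b"] == 2
        vals = np.where(is_ars, in_band, out_band)
        sel = apply
        sst[it[sel], iy[sel], ix[sel]] = vals[sel]
    out = ds.copy()
    out["sst"] = (("time", "lat", "lon"), sst, ds["sst"].attrs)
    return out
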