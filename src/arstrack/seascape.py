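"""Seascape covariate extraction and collinearity screening.

Covariates are sampled at estimated whale locations with the lags,
spatial windows and transforms used downstream by the habitat model:

* instantaneous fields (SST, SSHa, depth and derivatives, EKE,
  upwelling index) at the nearest cell and time slice;
* variability fields (``sst_sd``, ``ssha_sd``) as the standard deviation
  over a square spatial window of configurable area (default 100 km2)
  centred on the location;
* lagged fields: chlorophyll *a* as the mean over the window ending at
  the location's time and starting ``chla_lag_days`` earlier (default
  30 d); wind speed as the mean over the prior ``wind_lag_days``
  (default 7 d) at a nominated fixed point location, not at the whale;
* transforms applied once here — log(chla), log10(ssha_sd), log of
  positive depth — so the model sees final covariates.

Collinearity is screened with pairwise Pearson correlation (flag
|rho| >= 0.8) and variance inflation factors (flag VIF >= 3), keeping
the 100-km2 variability scale and the 30-day chlorophyll lag when a
flagged pair is a scale/lag family, and otherwise dropping the
later-listed variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from arstrack.movement import StateSeries
from arstrack.simulate import SeascapeFieldSet

logger = logging.getLogger(__name__)

_BASE_VARS = ("sst", "ssha", "eke", "upwelling_index", "wind_direction")
_STATIC_VARS = ("depth", "rugosity", "slope", "aspect")


@dataclass
class ExtractionSpec:
    """Lags, windows and transforms for covariate extraction."""

    sd_window_km2: float = 100.0
    chla_lag_days: float = 30.0
    wind_lag_days: float = 7.0
    wind_point: tuple[float, float] | None = None  # (lon, lat), required for wind
    method: str = "nearest"  # or "bilinear"
    log_chla: bool = True
    log10_ssha_sd: bool = True
    log_depth: bool = True

    def metadata(self) -> dict:
        return {
            "sd_window_km2": self.sd_window_km2,
            "chla_lag_days": self.chla_lag_days,
            "wind_lag_days": self.wind_lag_days,
            "wind_point": self.wind_point,
            "method": self.method,
            "transforms": {
                "chla": "log" if self.log_chla else None,
                "ssha_sd": "log10" if self.log10_ssha_sd else None,
                "depth": "log(-depth)" if self.log_depth else None,
            },
        }


def _series_frame(series) -> pd.DataFrame:
    if isinstance(series, pd.DataFrame):
        return series
    if isinstance(series, StateSeries):
        return series.data
    return pd.concat([_series_frame(s) for s in series], ignore_index=True)


def _nearest_index(coord: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-cell indices plus an out-of-range mask (half-cell tolerance)."""
    step = coord[1] - coord[0] if len(coord) > 1 else 1.0
    idx = np.rint((values - coord[0]) / step).astype(int)
    bad = (values < coord[0] - step / 2) | (values > coord[-1] + step / 2)
    return np.clip(idx, 0, len(coord) - 1), bad


def _sd_window_cells(fields: SeascapeFieldSet, area_km2: float) -> tuple[int, int]:
    res = float(fields.data.attrs.get("resolution_deg", abs(fields.data.lon.values[1] - fields.data.lon.values[0])))
    side_km = np.sqrt(area_km2)
    mean_lat = float(fields.data.lat.values.mean())
    n_lat = max(1, int(np.round(side_km / (111.0 * res))))
    n_lon = max(1, int(np.round(side_km / (111.0 * res * max(np.cos(np.radians(mean_lat)), 0.1)))))
    return n_lat, n_lon


def _windowed_sd(arr: np.ndarray, size: tuple[int, ...]) -> np.ndarray:
    m = uniform_filter(arr, size=size, mode="nearest")
    m2 = uniform_filter(arr**2, size=size, mode="nearest")
    return np.sqrt(np.maximum(m2 - m**2, 0.0))


def extract(
    series,
    fields: SeascapeFieldSet,
    spec: ExtractionSpec | None = None,
    variables: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Extract seascape covariates at every state location.

    ``series`` may be a :class:`StateSeries`, a list of them, or a frame
    with columns ``tag_id, timestamp, lon, lat`` (and optionally
    ``mode_state``/``b``).  Returns the covariate matrix — one row per
    input location, ``NaN`` for locations outside the raster or with lag
    windows preceding the raster start — and a metadata dict recording
    lags, windows, transforms and missing-row counts.  Extraction is
    deterministic given fields and series.
    """
    spec = spec or ExtractionSpec()
    df = _series_frame(series).reset_index(drop=True)
    ds = fields.data
    lon_c = ds.lon.values
    lat_c = ds.lat.values
    times = pd.DatetimeIndex(ds.time.values) if "time" in ds.coords else None

    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    ix, bad_x = _nearest_index(lon_c, lon)
    iy, bad_y = _nearest_index(lat_c, lat)
    outside = bad_x | bad_y

    t = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    if times is not None:
        it = np.clip(times.searchsorted(t, side="right") - 1, 0, len(times) - 1)
        # nearest slice: compare against the following slice too
        nxt = np.clip(it + 1, 0, len(times) - 1)
        d_prev = np.abs((t - times[it]).to_numpy())
        d_next = np.abs((times[nxt] - t).to_numpy())
        it = np.where(d_next < d_prev, nxt, it)
    else:
        it = None

    want = variables or [v for v in ds.data_vars]
    out = {}
    base_cols = ["tag_id", "timestamp", "lon", "lat"]
    for extra in ("segment", "mode_state", "b"):
        if extra in df.columns:
            base_cols.append(extra)
    result = df[base_cols].copy()

    for v in want:
        if v not in ds.data_vars or v in ("wind_speed", "chla"):
            continue
        arr = ds[v].values
        if arr.ndim == 3:
            vals = arr[it, iy, ix]
        else:
            vals = arr[iy, ix]
        out[v] = np.where(outside, np.nan, vals)

    nlat, nlon = _sd_window_cells(fields, spec.sd_window_km2)
    for base, name in (("sst", "sst_sd"), ("ssha", "ssha_sd")):
        if base in ds.data_vars and (variables is None or name in variables):
            arr = ds[base].values
            sd = _windowed_sd(arr, (1, nlat, nlon) if arr.ndim == 3 else (nlat, nlon))
            vals = sd[it, iy, ix] if arr.ndim == 3 else sd[iy, ix]
            out[name] = np.where(outside, np.nan, vals)

    if "chla" in ds.data_vars and times is not None and (
        variables is None or "chla" in variables
    ):
        arr = ds["chla"].values
        csum = np.concatenate([np.zeros((1,) + arr.shape[1:]), np.cumsum(arr, axis=0)])
        t_lo = t - pd.Timedelta(days=spec.chla_lag_days)
        i0 = times.searchsorted(t_lo, side="left")
        i1 = times.searchsorted(t, side="right")
        n_slices = i1 - i0
        before_start = (t_lo < times[0]).to_numpy()
        vals = np.full(len(df), np.nan)
        ok = (~outside) & (~before_start) & (n_slices > 0)
        if ok.any():
            s = (csum[i1[ok], iy[ok], ix[ok]] - csum[i0[ok], iy[ok], ix[ok]]) / n_slices[ok]
            vals[ok] = s
        out["chla"] = vals

    if "wind_speed" in ds.data_vars and times is not None and (
        variables is None or "wind_speed" in variables
    ):
        if spec.wind_point is None:
            raise ValueError(
                "wind_speed extraction requires spec.wind_point (the nominated "
                "fixed point location for the coastal wind series)"
            )
        wx, badx = _nearest_index(lon_c, np.array([spec.wind_point[0]]))
        wy, bady = _nearest_index(lat_c, np.array([spec.wind_point[1]]))
        if badx[0] or bady[0]:
            raise ValueError("wind_point lies outside the raster")
        wseries = ds["wind_speed"].values[:, wy[0], wx[0]]
        csum = np.concatenate([[0.0], np.cumsum(wseries)])
        t_lo = t - pd.Timedelta(days=spec.wind_lag_days)
        i0 = times.searchsorted(t_lo, side="left")
        i1 = times.searchsorted(t, side="right")
        n_slices = i1 - i0
        before_start = (t_lo < times[0]).to_numpy()
        vals = np.full(len(df), np.nan)
        ok = (~before_start) & (n_slices > 0)
        vals[ok] = (csum[i1[ok]] - csum[i0[ok]]) / n_slices[ok]
        out["wind_speed"] = vals

    # transforms, applied exactly once
    if "chla" in out and spec.log_chla:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["chla"] = np.where(out["chla"] > 0, np.log(out["chla"]), np.nan)
    if "ssha_sd" in out and spec.log10_ssha_sd:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["ssha_sd"] = np.where(
                out["ssha_sd"] > 0, np.log10(out["ssha_sd"]), np.nan
            )
    if "depth" in out and spec.log_depth:
        d = -np.asarray(out["depth"], dtype=float)  # negative-down -> positive depth
        with np.errstate(divide="ignore", invalid="ignore"):
            out["depth"] = np.where(d > 0, np.log(d), np.nan)

    for k, v in out.items():
        result[k] = v
    n_missing = int(result[list(out)].isna().any(axis=1).sum())
    meta = spec.metadata()
    meta.update(
        {
            "n_rows": len(result),
            "n_missing": n_missing,
            "sd_window_cells": (nlat, nlon),
            "variables": list(out),
        }
    )
    if n_missing:
        logger.info("extraction produced %d rows with missing covariates", n_missing)
    return result, meta


# ---------------------------------------------------------------------------
# collinearity screening


@dataclass
class CollinearityReport:
    """Pairwise correlations, VIFs and the resolved drop list."""

    rho: pd.DataFrame
    vif: pd.Series
    flagged_pairs: list[tuple[str, str, float]]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (variable, reason)

    @property
    def kept(self) -> list[str]:
        drop = {d for d, _ in self.dropped}
        return [c for c in self.rho.columns if c not in drop]


def _family_preference(a: str, b: str) -> str | None:
    """Which of a collinear pair to keep, for known scale/lag families.

    Chlorophyll lag family: keep the 30-day variant.  Variability-window
    family: keep the 100-km2 variant.  Returns the name to keep, or
    ``None`` when the pair is not a recognised family.
    """
    la, lb = a.lower(), b.lower()
    if "chla" in la and "chla" in lb:
        if "30" in la and "30" not in lb:
            return a
        if "30" in lb and "30" not in la:
            return b
    if ("_sd" in la and "_sd" in lb) or ("sd" in la.split("_") and "sd" in lb.split("_")):
        if "100" in la and "100" not in lb:
            return a
        if "100" in lb and "100" not in la:
            return b
    return None


def _vif(X: np.ndarray) -> np.ndarray:
    """VIF per column from the inverse correlation matrix."""
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    R = np.corrcoef(Xs, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        Rinv = np.linalg.pinv(R)
    return np.diag(Rinv)


def screen_collinearity(
    matrix: pd.DataFrame,
    vif_max: float = 3.0,
    rho_max: float = 0.8,
    columns: list[str] | None = None,
) -> CollinearityReport:
    """Flag and resolve collinear covariates.

    Pairs with |Pearson rho| >= ``rho_max`` are resolved first (family
    preference, else drop the later-listed variable), then variables
    with VIF >= ``vif_max`` are dropped one at a time, highest first.
    Constant columns have undefined VIF and are dropped with a reason.
    Requires at least two numeric columns and more rows than columns.
    """
    if columns is None:
        exclude = {"tag_id", "timestamp", "lon", "lat", "mode_state", "b", "segment"}
        columns = [
            c
            for c in matrix.columns
            if c not in exclude and pd.api.types.is_numeric_dtype(matrix[c])
        ]
    if len(columns) < 2:
        raise ValueError("need at least two numeric covariate columns")
    X = matrix[columns].dropna()
    if len(X) <= len(columns):
        raise ValueError("need more rows than covariate columns")

    dropped: list[tuple[str, str]] = []
    active = list(columns)
    const = [c for c in active if X[c].std(ddof=0) == 0]
    for c in const:
        dropped.append((c, "constant column (VIF undefined)"))
        active.remove(c)

    rho = X[columns].corr()
    flagged = []
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            r = rho.loc[a, b]
            if abs(r) >= rho_max:
                flagged.append((a, b, float(r)))
    for a, b, r in flagged:
        if a not in active or b not in active:
            continue
        keep = _family_preference(a, b)
        if keep is None:
            keep = a  # drop the later-listed variable
        drop = b if keep == a else a
        dropped.append((drop, f"|rho|={abs(r):.3f} >= {rho_max} with {keep}"))
        active.remove(drop)

    while len(active) >= 2:
        vifs = _vif(X[active].to_numpy(dtype=float))
        worst = int(np.nanargmax(vifs))
        if vifs[worst] >= vif_max:
            name = active[worst]
            dropped.append((name, f"VIF={vifs[worst]:.2f} >= {vif_max}"))
            active.remove(name)
        else:
            break
    vif_final = pd.Series(
        _vif(X[active].to_numpy(dtype=float)) if len(active) >= 2 else [1.0] * len(active),
        index=active,
        name="vif",
    )
    return CollinearityReport(
        rho=rho, vif=vif_final, flagged_pairs=flagged, dropped=dropped
    )
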