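"""Reading, validating and segmenting raw Argos location records.

Argos assigns each fix one of seven quality classes (3, 2, 1, 0, A, B, Z),
loosely ordered by positional accuracy.  All classes — including Z — are
retained here; quality enters the analysis through the state-space model's
class-specific measurement-error scales, not through prefiltering.

Tracks with intermittent transmission are split into segments wherever the
gap between consecutive fixes exceeds 48 h, and segments with fewer than
20 observations are discarded before modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven Argos location classes, best to worst nominal quality.
LC_CLASSES: tuple[str, ...] = ("3", "2", "1", "0", "A", "B", "Z")

OBS_COLUMNS = ["tag_id", "timestamp", "lc", "lon", "lat"]


@dataclass(frozen=True)
class ArgosObservation:
    """One raw satellite fix with its Argos quality class."""

    tag_id: str
    time: pd.Timestamp
    lc: str
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if self.lc not in LC_CLASSES:
            raise ValueError(f"unknown Argos class {self.lc!r}")
        if not (-180.0 <= self.lon <= 180.0) or not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"coordinates out of range: ({self.lon}, {self.lat})")


@dataclass
class TrackSegment:
    """A gap-free, length-filtered run of observations from one tag.

    ``data`` is a time-sorted frame with columns ``tag_id, timestamp, lc,
    lon, lat``; construction enforces non-decreasing times (duplicate
    timestamps are allowed — satellite passes can double-report).
    """

    tag_id: str
    segment_index: int
    data: pd.DataFrame

    def __post_init__(self) -> None:
        t = pd.to_datetime(self.data["timestamp"]).astype("int64").to_numpy()
        if len(t) and (np.diff(t) < 0).any():
            raise ValueError("segment timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def start(self) -> pd.Timestamp:
        return self.data["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.data["timestamp"].iloc[-1]

    @property
    def span_hours(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)

    def hours_since_start(self) -> np.ndarray:
        """Observation times as float hours from the first fix."""
        dt = self.data["timestamp"] - self.start
        return (dt / pd.Timedelta(hours=1)).to_numpy(dtype=float)


@dataclass(frozen=True)
class Deployment:
    """Tag deployment metadata for one whale."""

    tag_id: str
    tag_type: str  # "SPLASH" or "SPOT"
    deploy_time: pd.Timestamp
    deploy_lon: float
    deploy_lat: float
    first_tx: pd.Timestamp
    last_tx: pd.Timestamp

    def __post_init__(self) -> None:
        if self.first_tx > self.last_tx:
            raise ValueError("first_tx must not be after last_tx")

    @property
    def duration_days(self) -> float:
        """Transmission span in days, including any gaps."""
        return (self.last_tx - self.first_tx) / pd.Timedelta(days=1)


@dataclass
class ReadReport:
    """Row-level accounting from :func:`read_argos`."""

    n_read: int = 0
    n_valid: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)  # (line_no, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.errors)


def read_argos(path, *, sep: str = ",", return_report: bool = False):
    """Read Argos observations from delimited text.

    The file must carry a header with at least ``tag_id, timestamp, lc,
    lon, lat``.  Every well-formed row is returned regardless of location
    class (class Z included).  Malformed rows — unparseable timestamps,
    unknown class tokens, out-of-range coordinates — are rejected with
    their 1-based line number recorded in the report and logged; they are
    never silently dropped.

    Returns a DataFrame (with ``return_report=True``, a
    ``(DataFrame, ReadReport)`` pair).  An empty file yields an explicit
    empty frame with the standard columns.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in OBS_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    report = ReadReport(n_read=len(raw))
    rows = []
    for i, row in enumerate(raw.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        lc = str(getattr(row, "lc")).strip()
        if lc not in LC_CLASSES:
            report.errors.append((line_no, f"unknown Argos class {lc!r}"))
            continue
        try:
            t = pd.Timestamp(getattr(row, "timestamp"))
        except (ValueError, TypeError):
            report.errors.append((line_no, f"unparseable timestamp {getattr(row, 'timestamp')!r}"))
            continue
        if t.tzinfo is None:
            t = t.tz_localize("UTC")
        else:
            t = t.tz_convert("UTC")
        try:
            lon = float(getattr(row, "lon"))
            lat = float(getattr(row, "lat"))
        except (ValueError, TypeError):
            report.errors.append((line_no, "non-numeric coordinates"))
            continue
        if not np.isfinite(lon) or not np.isfinite(lat):
            report.errors.append((line_no, "non-finite coordinates"))
            continue
        if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
            report.errors.append((line_no, f"coordinate out of range ({lon}, {lat})"))
            continue
        rows.append((str(getattr(row, "tag_id")), t, lc, lon, lat))
    report.n_valid = len(rows)
    for line_no, reason in report.errors:
        logger.warning("rejected row at line %d: %s", line_no, reason)
    df = pd.DataFrame(rows, columns=OBS_COLUMNS)
    if df.empty:
        df = df.astype({"tag_id": str, "lc": str, "lon": float, "lat": float})
    if return_report:
        return df, report
    return df


def write_observations(df: pd.DataFrame, path, *, sep: str = ",") -> None:
    """Write observations as delimited text with the standard header."""
    out = df[OBS_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, sep=sep, index=False)


def segment_track(
    observations: pd.DataFrame,
    gap_hours: float = 48.0,
    min_obs: int = 20,
) -> list[TrackSegment]:
    """Split a single tag's observations into gap-free segments.

    A split occurs exactly where the interval between consecutive fixes
    strictly exceeds ``gap_hours`` ("exceeded 48 h": a gap of exactly
    48.0 h does not split).  Segments with fewer than ``min_obs``
    observations are removed; surviving segments get dense indices from
    0.  Input is stably sorted by time if not already sorted, so
    duplicate timestamps keep their input order.
    """
    if observations.empty:
        return []
    tags = observations["tag_id"].unique()
    if len(tags) != 1:
        raise ValueError(f"segment_track expects a single tag, got {list(tags)}")
    df = observations.sort_values("timestamp", kind="stable").reset_index(drop=True)
    t = pd.to_datetime(df["timestamp"], utc=True)
    gaps_h = t.diff() / pd.Timedelta(hours=1)
    # boundary strictly after any interval > gap_hours
    new_seg = (gaps_h > gap_hours).fillna(False).to_numpy()
    seg_id = np.cumsum(new_seg)
    segments: list[TrackSegment] = []
    for _, chunk in df.groupby(seg_id, sort=True):
        if len(chunk) >= min_obs:
            segments.append(
                TrackSegment(
                    tag_id=str(tags[0]),
                    segment_index=len(segments),
                    data=chunk.reset_index(drop=True),
                )
            )
    return segments


def segment_all(observations: pd.DataFrame, gap_hours: float = 48.0, min_obs: int = 20) -> list[TrackSegment]:
    """Segment a multi-tag observation frame, tag by tag."""
    out: list[TrackSegment] = []
    for tag in observations["tag_id"].unique():
        out.extend(
            segment_track(
                observations[observations["tag_id"] == tag], gap_hours, min_obs
            )
        )
    return out


def mean_interval(observations: pd.DataFrame | pd.Series) -> float:
    """Arithmetic mean of successive inter-fix intervals, in hours.

    Raises ``ValueError`` with fewer than two observations (the interval
    is undefined).
    """
    if isinstance(observations, pd.DataFrame):
        times = pd.to_datetime(observations["timestamp"], utc=True)
    else:
        times = pd.to_datetime(observations, utc=True)
    if len(times) < 2:
        raise ValueError("mean_interval requires at least two observations")
    times = times.sort_values(kind="stable")
    dt_h = times.diff().dropna() / pd.Timedelta(hours=1)
    return float(dt_h.mean())
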