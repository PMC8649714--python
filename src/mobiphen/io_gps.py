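"""Reading, validating and day-partitioning duty-cycled GPS and survey data.

The on-disk dialects are deliberately minimal CSV:

* GPS: header ``timestamp,latitude,longitude,accuracy`` (accuracy optional);
  timestamps are either ISO-8601 strings or epoch seconds, auto-detected
  once per file.
* Momentary sadness survey: header ``participant_id,timestamp,level`` with
  a four-level ordinal answer.

Timestamps are held internally as float epoch seconds (UTC).  Calendar days
are assigned under a single configurable fixed UTC offset per cohort; the
study populations are single-region, so a per-point timezone lookup would
add nondeterminism for no benefit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86400.0

#: ordinal sadness answers, least to most severe
SADNESS_LEVELS = ("not_at_all", "a_little_bit", "quite_a_bit", "very_much")
#: levels that flag a report as severe sadness (would justify intervention)
SEVERE_LEVELS = frozenset({"quite_a_bit", "very_much"})


class FormatError(ValueError):
    """A file does not conform to the documented CSV dialect."""


@dataclasses.dataclass(frozen=True)
class DayKey:
    """One participant's local calendar day under a fixed UTC offset."""

    participant_id: str
    local_date: object  # datetime.date

    def __str__(self) -> str:
        return f"{self.participant_id}:{self.local_date.isoformat()}"


@dataclasses.dataclass
class GpsTrace:
    """One participant's ordered, timestamped coordinate stream.

    Attributes
    ----------
    participant_id : str
        Opaque identifier.
    points : pandas.DataFrame
        Columns ``t`` (float epoch seconds), ``lat``, ``lon`` (degrees) and
        ``accuracy`` (meters, NaN where missing), sorted non-decreasing in
        ``t``.  Duplicate timestamps are permitted; downstream bin averaging
        absorbs them.
    """

    participant_id: str
    points: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"t", "lat", "lon"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"trace missing columns {sorted(missing)}")
        if "accuracy" not in self.points.columns:
            self.points = self.points.assign(accuracy=np.nan)
        t = self.points["t"].to_numpy()
        if len(t) and np.any(np.diff(t) < 0):
            self.points = self.points.sort_values("t", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def t(self) -> np.ndarray:
        return self.points["t"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.points["lat"].to_numpy(dtype=float)

    @property
    def lon(self) -> np.ndarray:
        return self.points["lon"].to_numpy(dtype=float)

    def validate(self) -> dict:
        """Return validation diagnostics (duplicate timestamps, bounds)."""
        t = self.t
        n_dup = int(len(t) - len(np.unique(t))) if len(t) else 0
        ok_lat = np.all(np.abs(self.lat) <= 90.0) if len(t) else True
        ok_lon = np.all(np.abs(self.lon) <= 180.0) if len(t) else True
        return {
            "n_points": len(t),
            "n_duplicate_timestamps": n_dup,
            "coords_in_range": bool(ok_lat and ok_lon),
            "sorted": bool(np.all(np.diff(t) >= 0)) if len(t) else True,
        }


@dataclasses.dataclass(frozen=True)
class SadnessReport:
    """A timestamped momentary sadness self-report.

    ``severe`` is derived, never stored independently: it is True exactly
    when the ordinal answer is "quite_a_bit" or "very_much".
    """

    participant_id: str
    t: float
    level: str

    def __post_init__(self) -> None:
        if self.level not in SADNESS_LEVELS:
            raise FormatError(f"unknown sadness level {self.level!r}")

    @property
    def severe(self) -> bool:
        return self.level in SEVERE_LEVELS


def _parse_timestamps(raw: pd.Series) -> np.ndarray:
    """Parse a timestamp column as epoch seconds or ISO-8601, file-wide.

    The convention is detected once per file (from the first non-null
    entry), never per row, so a file mixing the two dialects fails loudly.
    """
    first = raw.dropna()
    if first.empty:
        return np.array([], dtype=float)
    probe = str(first.iloc[0])
    try:
        float(probe)
        numeric = True
    except ValueError:
        numeric = False
    if numeric:
        return pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
    parsed = pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")
    return parsed.astype("int64").to_numpy() / 1e9


def read_gps_csv(path: str | Path, participant_id: str | None = None) -> GpsTrace:
    """Read a GPS CSV into a sorted :class:`GpsTrace`.

    Rows with unparseable timestamps or out-of-range coordinates are dropped
    and counted in ``trace.n_dropped_rows``.

    Raises
    ------
    FormatError
        If a mandatory column (timestamp, latitude, longitude) is absent.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"timestamp", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    t = _parse_timestamps(df["timestamp"])
    lat = pd.to_numeric(df["latitude"], errors="coerce").to_numpy(dtype=float)
    lon = pd.to_numeric(df["longitude"], errors="coerce").to_numpy(dtype=float)
    if "accuracy" in df.columns:
        acc = pd.to_numeric(df["accuracy"], errors="coerce").to_numpy(dtype=float)
    else:
        acc = np.full(len(df), np.nan)
    ok = (
        np.isfinite(t)
        & np.isfinite(lat)
        & np.isfinite(lon)
        & (np.abs(lat) <= 90.0)
        & (np.abs(lon) <= 180.0)
    )
    n_dropped = int(len(df) - ok.sum())
    points = pd.DataFrame({"t": t[ok], "lat": lat[ok], "lon": lon[ok], "accuracy": acc[ok]})
    trace = GpsTrace(participant_id or path.stem, points)
    trace.n_dropped_rows = n_dropped
    return trace


def write_gps_csv(trace: GpsTrace, path: str | Path) -> None:
    """Write a trace in the canonical GPS dialect (epoch-second timestamps)."""
    out = pd.DataFrame(
        {
            "timestamp": trace.points["t"].map(lambda v: np.format_float_positional(v, trim="0")),
            "latitude": trace.points["lat"],
            "longitude": trace.points["lon"],
            "accuracy": trace.points["accuracy"],
        }
    )
    out.to_csv(path, index=False, float_format="%.10f")


def read_sadness_csv(path: str | Path) -> list[SadnessReport]:
    """Read a survey CSV into :class:`SadnessReport` objects.

    Level strings are normalized (lowercased, spaces to underscores) so both
    ``"quite a bit"`` and ``"quite_a_bit"`` are accepted; anything else is a
    :class:`FormatError` naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"participant_id", "timestamp", "level"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    t = _parse_timestamps(df["timestamp"])
    reports = []
    for i, row in df.iterrows():
        level = str(row["level"]).strip().lower().replace(" ", "_")
        if level not in SADNESS_LEVELS:
            raise FormatError(f"{path}: row {i}: unknown sadness level {row['level']!r}")
        reports.append(SadnessReport(str(row["participant_id"]), float(t[i]), level))
    return reports


def write_sadness_csv(reports: list[SadnessReport], path: str | Path) -> None:
    pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in reports],
            "timestamp": [repr(r.t) for r in reports],
            "level": [r.level for r in reports],
        }
    ).to_csv(path, index=False)


def local_date(t: float | np.ndarray, utc_offset_h: float):
    """Local calendar date(s) of epoch time(s) under a fixed UTC offset."""
    shifted = pd.to_datetime(np.asarray(t, dtype=float) + utc_offset_h * 3600.0, unit="s")
    if np.ndim(t) == 0:
        return pd.Timestamp(shifted).date()
    return pd.DatetimeIndex(np.atleast_1d(shifted)).date


def day_start_epoch(date, utc_offset_h: float) -> float:
    """Epoch seconds of local midnight for ``date`` under the offset."""
    return pd.Timestamp(date).timestamp() - utc_offset_h * 3600.0


def split_by_day(trace: GpsTrace, utc_offset_h: float = -6.0) -> dict[DayKey, GpsTrace]:
    """Partition a trace into local calendar days.

    The outputs form an exact partition of the input points: every point
    lands in exactly one day, each sub-trace lies within [00:00, 24:00)
    local time of its day.
    """
    if len(trace) == 0:
        return {}
    dates = local_date(trace.t, utc_offset_h)
    out: dict[DayKey, GpsTrace] = {}
    df = trace.points.assign(_date=dates)
    for date, sub in df.groupby("_date", sort=True):
        key = DayKey(trace.participant_id, date)
        out[key] = GpsTrace(trace.participant_id, sub.drop(columns="_date").reset_index(drop=True))
    return out
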