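"""Binned displacement series and Daily Displacement Profiles (DDPs).

A day's GPS trace is placed into fixed-width time-of-day bins (48 half-hour
bins for DDPs, 96 quarter-hour bins for circadian analysis).  Each observed
bin holds the arithmetic mean coordinate of its pings; an empty bin carries
forward the most recent available coordinate (searching backward within the
day, then an optional cross-day seed).  Differencing adjacent bin centroids
with the haversine distance yields the displacement series; for a single
48-bin day this is the 47-element Daily Displacement Profile.

Mean lat/lon in degrees is an adequate centroid at city scale and far from
the antimeridian; this package does not attempt spherical averaging.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from mobiphen.io_gps import GpsTrace, DayKey, split_by_day, day_start_epoch, SECONDS_PER_DAY

EARTH_RADIUS_M = 6_371_000.0


class InvalidDayError(ValueError):
    """A day cannot be binned (no data and no carry seed)."""


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in meters between coordinate pairs (degrees).

    Vectorized over numpy arrays; symmetric; zero iff the coordinates are
    identical. Earth radius 6,371,000 m.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


@dataclasses.dataclass
class BinnedDay:
    """Per-bin mean coordinates for one participant-day.

    ``observed[i]`` is True iff at least one ping fell in bin ``i``;
    unobserved bins hold a carried-forward coordinate.
    """

    day_key: DayKey
    bin_width_min: int
    centroids: np.ndarray  # (n_bins, 2) lat, lon
    observed: np.ndarray  # (n_bins,) bool

    @property
    def n_bins(self) -> int:
        return int(round(1440 / self.bin_width_min))

    @property
    def coverage(self) -> float:
        return float(np.mean(self.observed))


@dataclasses.dataclass
class DailyDisplacementProfile:
    """47 inter-bin haversine displacements for one participant-day."""

    day_key: DayKey
    displacements: np.ndarray  # (47,) meters
    coverage: float

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.shape != (47,):
            raise ValueError("a DDP has exactly 47 displacement values")
        if np.any(self.displacements < 0):
            raise ValueError("displacements must be non-negative")


def bin_day(
    trace_day: GpsTrace,
    bin_width_min: int = 30,
    utc_offset_h: float = -6.0,
    carry_seed: tuple[float, float] | None = None,
    day_date=None,
) -> BinnedDay:
    """Bin one local day's pings into fixed-width time-of-day bins.

    Parameters
    ----------
    trace_day : GpsTrace
        Points all belonging to one local calendar day.
    carry_seed : (lat, lon), optional
        Coordinate used to fill leading empty bins (typically the previous
        day's last known position).  A fully empty day without a seed is
        rejected with :class:`InvalidDayError`.
    day_date : datetime.date, optional
        Day to bin; inferred from the first point when omitted.
    """
    n_bins = int(round(1440 / bin_width_min))
    if n_bins * bin_width_min != 1440:
        raise ValueError("bin width must divide 24 h")
    if len(trace_day) == 0 and carry_seed is None:
        raise InvalidDayError("empty day and no carry seed")
    if day_date is None:
        if len(trace_day) == 0:
            raise InvalidDayError("cannot infer date of an empty day")
        from mobiphen.io_gps import local_date

        day_date = local_date(float(trace_day.t[0]), utc_offset_h)
    start = day_start_epoch(day_date, utc_offset_h)
    centroids = np.full((n_bins, 2), np.nan)
    observed = np.zeros(n_bins, dtype=bool)
    if len(trace_day):
        idx = np.floor((trace_day.t - start) / (bin_width_min * 60.0)).astype(int)
        if np.any((idx < 0) | (idx >= n_bins)):
            raise ValueError("trace contains points outside the stated day")
        df = pd.DataFrame({"t": trace_day.t, "bin": idx, "lat": trace_day.lat, "lon": trace_day.lon})
        # exactly duplicated records (same time and coordinates) are data
        # artifacts; drop them so they cannot double-weight a bin mean
        df = df.drop_duplicates(["t", "lat", "lon"]).drop(columns="t")
        means = df.groupby("bin").mean()
        centroids[means.index.to_numpy()] = means[["lat", "lon"]].to_numpy()
        observed[means.index.to_numpy()] = True
    # carry forward: most recent available coordinate, else the seed
    last = None if carry_seed is None else np.asarray(carry_seed, dtype=float)
    if last is None:
        # leading gap on a participant's first day: backfill from the first
        # observed coordinate so leading displacements are zero
        first_obs = int(np.argmax(observed))
        last = centroids[first_obs].copy()
    for i in range(n_bins):
        if observed[i]:
            last = centroids[i]
        else:
            centroids[i] = last
    key = DayKey(trace_day.participant_id, day_date)
    return BinnedDay(key, bin_width_min, centroids, observed)


def build_ddp(binned: BinnedDay) -> DailyDisplacementProfile:
    """Difference adjacent half-hour centroids into a 47-element DDP."""
    if binned.n_bins != 48 or binned.centroids.shape[0] != 48:
        raise ValueError("a DDP requires 48 half-hour bins")
    c = binned.centroids
    disp = haversine_m(c[:-1, 0], c[:-1, 1], c[1:, 0], c[1:, 1])
    return DailyDisplacementProfile(binned.day_key, disp, binned.coverage)


def binned_days(
    trace: GpsTrace,
    bin_width_min: int = 30,
    utc_offset_h: float = -6.0,
) -> list[BinnedDay]:
    """Bin every consecutive calendar day of a trace, carrying across days.

    Days between the first and last observed date with no pings at all are
    still emitted (fully carried forward), so the concatenated bins form an
    unbroken time grid over the study period.
    """
    days = split_by_day(trace, utc_offset_h)
    if not days:
        return []
    dates = sorted(k.local_date for k in days)
    by_date = {k.local_date: v for k, v in days.items()}
    all_dates = pd.date_range(dates[0], dates[-1], freq="D").date
    out: list[BinnedDay] = []
    carry = None
    for date in all_dates:
        day_trace = by_date.get(date, GpsTrace(trace.participant_id, trace.points.iloc[0:0]))
        binned = bin_day(day_trace, bin_width_min, utc_offset_h, carry_seed=carry, day_date=date)
        carry = tuple(binned.centroids[-1])
        out.append(binned)
    return out


def ddp_table(
    trace: GpsTrace,
    utc_offset_h: float = -6.0,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """All DDPs of a trace as a tidy frame, coverage-filtered.

    Columns ``participant_id, date, coverage, d01..d47``; one row per day
    with bin coverage at or above ``min_coverage``.
    """
    rows = []
    for binned in binned_days(trace, 30, utc_offset_h):
        if binned.coverage < min_coverage:
            continue
        ddp = build_ddp(binned)
        rows.append(
            {
                "participant_id": trace.participant_id,
                "date": binned.day_key.local_date,
                "coverage": ddp.coverage,
                **{f"d{i + 1:02d}": ddp.displacements[i] for i in range(47)},
            }
        )
    return pd.DataFrame(rows)


def displacement_series(
    trace: GpsTrace,
    bin_width_min: int = 15,
    utc_offset_h: float = -6.0,
) -> np.ndarray:
    """Inter-bin displacement magnitudes across the whole study period.

    The trace is binned day by day (carry-forward across day boundaries) and
    adjacent centroids are differenced, yielding ``total_bins - 1`` values.
    Element ``i`` is the displacement *into* bin ``i + 1`` of the period
    grid; callers aligning values to time of day should offset by one bin.
    """
    binned = binned_days(trace, bin_width_min, utc_offset_h)
    if not binned:
        return np.array([], dtype=float)
    c = np.vstack([b.centroids for b in binned])
    return np.asarray(haversine_m(c[:-1, 0], c[:-1, 1], c[1:, 0], c[1:, 1]), dtype=float)
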