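"""Seven daily GPS digital phenotypes built on significant-place clustering.

A participant's trace is first segmented into *stays* (periods dwelling at
one spot) and transit by a greedy temporal clustering of consecutive
points: a candidate cluster grows while each new point lies within
``d_thresh_m`` of its running centroid and is committed as a stay when its
time span reaches ``t_min_s``.  Committed stays whose centroids fall within
``merge_thresh_m`` of each other are merged into *significant places*.
*Home* is the place with the most pooled dwell between 00:00 and 06:00
local over the whole study period.

Per day the module derives:

===========  ==================================================================
loc_var      square root of the variance of the day's coordinates (meters,
             local equirectangular projection)
num_pls      number of distinct significant places visited
ent_pls      normalized entropy of dwell time across places, in [0, 1]
perc_home    percent of labeled (stay + transit) time spent at home
total_dist   sum of consecutive-point haversine distances (meters)
max_dist     greatest pairwise point distance (meters, exact)
routine_idx  similarity of the day's time-slotted place sequence to the
             participant's other days, in [0, 1]
===========  ==================================================================
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from mobiphen.displacement import haversine_m, EARTH_RADIUS_M
from mobiphen.io_gps import GpsTrace, local_date, day_start_epoch, SECONDS_PER_DAY

TRANSIT = -1  # null place label

DEFAULT_D_THRESH_M = 75.0
DEFAULT_T_MIN_S = 600.0
DEFAULT_MERGE_THRESH_M = 100.0
DEFAULT_SLOT_WIDTH_MIN = 30


@dataclasses.dataclass
class Place:
    """A significant place: merged stay cluster with positive total dwell."""

    place_id: int
    centroid: tuple[float, float]  # lat, lon
    total_dwell_s: float
    visit_count: int


class UndefinedFeatureError(ValueError):
    """A phenotype is undefined for this input (too few points / no home)."""


def project_local_m(lat, lon, lat0: float, lon0: float) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection to meters about (lat0, lon0).

    Adequate at city scale; not valid near the poles or the antimeridian.
    """
    y = EARTH_RADIUS_M * np.radians(np.asarray(lat, dtype=float) - lat0)
    x = EARTH_RADIUS_M * np.radians(np.asarray(lon, dtype=float) - lon0) * np.cos(np.radians(lat0))
    return x, y


def location_variance(lat: np.ndarray, lon: np.ndarray) -> float:
    """sqrt of the summed coordinate variance, in meters.

    Population variance of the locally projected x and y coordinates about
    the day centroid; translation invariant by construction.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if len(lat) < 2:
        raise UndefinedFeatureError("location variance needs at least 2 points")
    x, y = project_local_m(lat, lon, float(lat.mean()), float(lon.mean()))
    return float(np.sqrt(np.var(x) + np.var(y)))


def total_distance(lat: np.ndarray, lon: np.ndarray) -> float:
    """Sum of consecutive-point haversine distances; 0 for < 2 points."""
    if len(lat) < 2:
        return 0.0
    return float(np.sum(haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])))


def max_distance(lat: np.ndarray, lon: np.ndarray, chunk: int = 1024) -> float:
    """Greatest pairwise haversine distance, exact O(n²); 0 for < 2 points."""
    n = len(lat)
    if n < 2:
        return 0.0
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    best = 0.0
    for i0 in range(0, n, chunk):
        sl = slice(i0, min(i0 + chunk, n))
        d = haversine_m(
            lat[sl][:, None], lon[sl][:, None], lat[None, :], lon[None, :]
        )
        best = max(best, float(np.max(d)))
    return best


def place_entropy(dwell_s) -> float:
    """Normalized Shannon entropy of dwell shares: −Σ p ln p / ln K; 0 if K=1."""
    d = np.asarray(dwell_s, dtype=float)
    d = d[d > 0]
    if len(d) == 0:
        raise UndefinedFeatureError("entropy needs at least one positive dwell")
    if len(d) == 1:
        return 0.0
    p = d / d.sum()
    return float(-(p * np.log(p)).sum() / np.log(len(d)))


def extract_places(
    trace: GpsTrace,
    d_thresh_m: float = DEFAULT_D_THRESH_M,
    t_min_s: float = DEFAULT_T_MIN_S,
    merge_thresh_m: float = DEFAULT_MERGE_THRESH_M,
) -> tuple[list[Place], pd.DataFrame, np.ndarray]:
    """Segment a trace into significant places, stays and per-point labels.

    Returns
    -------
    places : list of Place
    stays : DataFrame
        One committed stay per row: ``t_start, t_end, place_id, lat, lon``.
    labels : ndarray of int
        Per-point place label; ``TRANSIT`` (−1) for points not in any stay.

    Deterministic given inputs and thresholds.
    """
    t, lat, lon = trace.t, trace.lat, trace.lon
    n = len(t)
    labels = np.full(n, TRANSIT, dtype=int)
    committed: list[tuple[float, float, float, float, list[int]]] = []

    def flush(idx: list[int]) -> None:
        if not idx:
            return
        span = t[idx[-1]] - t[idx[0]]
        if span >= t_min_s:
            committed.append(
                (t[idx[0]], t[idx[-1]], float(lat[idx].mean()), float(lon[idx].mean()), list(idx))
            )

    cur: list[int] = []
    sum_lat = sum_lon = 0.0
    for i in range(n):
        if cur:
            c_lat = sum_lat / len(cur)
            c_lon = sum_lon / len(cur)
            if haversine_m(c_lat, c_lon, lat[i], lon[i]) <= d_thresh_m:
                cur.append(i)
                sum_lat += lat[i]
                sum_lon += lon[i]
                continue
            flush(cur)
        cur = [i]
        sum_lat, sum_lon = float(lat[i]), float(lon[i])
    flush(cur)

    # merge committed stays into places by centroid proximity
    place_lat: list[float] = []
    place_lon: list[float] = []
    place_w: list[float] = []
    place_visits: list[int] = []
    stay_rows = []
    for t0, t1, s_lat, s_lon, idx in committed:
        dwell = t1 - t0
        pid = None
        if place_lat:
            d = haversine_m(np.array(place_lat), np.array(place_lon), s_lat, s_lon)
            j = int(np.argmin(d))
            if d[j] <= merge_thresh_m:
                pid = j
        if pid is None:
            pid = len(place_lat)
            place_lat.append(s_lat)
            place_lon.append(s_lon)
            place_w.append(0.0)
            place_visits.append(0)
        # dwell-weighted running centroid
        w0, w1 = place_w[pid], place_w[pid] + max(dwell, 1.0)
        frac = max(dwell, 1.0) / w1
        place_lat[pid] += (s_lat - place_lat[pid]) * frac
        place_lon[pid] += (s_lon - place_lon[pid]) * frac
        place_w[pid] = w1
        place_visits[pid] += 1
        labels[idx] = pid
        stay_rows.append({"t_start": t0, "t_end": t1, "place_id": pid, "lat": s_lat, "lon": s_lon})

    places = [
        Place(pid, (place_lat[pid], place_lon[pid]), place_w[pid], place_visits[pid])
        for pid in range(len(place_lat))
    ]
    stays = pd.DataFrame(stay_rows, columns=["t_start", "t_end", "place_id", "lat", "lon"])
    return places, stays, labels


def _overlap(a0: np.ndarray, a1: np.ndarray, b0: float, b1: float) -> np.ndarray:
    return np.clip(np.minimum(a1, b1) - np.maximum(a0, b0), 0.0, None)


def identify_home(stays: pd.DataFrame, utc_offset_h: float = -6.0) -> int:
    """Home = place with maximal pooled dwell between 00:00 and 06:00 local.

    Raises :class:`UndefinedFeatureError` when no stay touches that window
    over the whole period (home undefined for the participant).
    """
    if stays.empty:
        raise UndefinedFeatureError("no stays: home undefined")
    t0 = stays["t_start"].to_numpy()
    t1 = stays["t_end"].to_numpy()
    shift = utc_offset_h * 3600.0
    # overlap of each stay with every local 00:00-06:00 window it touches
    day0 = np.floor((t0 + shift) / SECONDS_PER_DAY).astype(int)
    day1 = np.floor((t1 + shift) / SECONDS_PER_DAY).astype(int)
    dwell = np.zeros(len(stays))
    for k in range(len(stays)):
        for day in range(day0[k], day1[k] + 1):
            w0 = day * SECONDS_PER_DAY - shift
            dwell[k] += float(_overlap(t0[k : k + 1], t1[k : k + 1], w0, w0 + 6 * 3600.0)[0])
    pooled = pd.Series(dwell).groupby(stays["place_id"].to_numpy()).sum()
    pooled = pooled[pooled > 0]
    if pooled.empty:
        raise UndefinedFeatureError("no 00:00-06:00 dwell: home undefined")
    return int(pooled.idxmax())


def slot_labels(stays: pd.DataFrame, t0: float, t1: float, slot_width_min: int) -> np.ndarray:
    """Modal place label per time slot of [t0, t1); TRANSIT where no stay."""
    width = slot_width_min * 60.0
    n_slots = int(round((t1 - t0) / width))
    labels = np.full(n_slots, TRANSIT, dtype=int)
    if stays.empty:
        return labels
    s0 = stays["t_start"].to_numpy()
    s1 = stays["t_end"].to_numpy()
    pid = stays["place_id"].to_numpy()
    n_places = int(pid.max()) + 1
    starts = t0 + np.arange(n_slots) * width
    # (n_slots, n_stays) overlap matrix; stay counts are small
    ov = np.clip(
        np.minimum(s1[None, :], starts[:, None] + width) - np.maximum(s0[None, :], starts[:, None]),
        0.0,
        None,
    )
    for s in range(n_slots):
        if ov[s].sum() > 0:
            per_place = np.bincount(pid, weights=ov[s], minlength=n_places)
            labels[s] = int(np.argmax(per_place))
    return labels


def routine_index(day_labels: np.ndarray) -> np.ndarray:
    """Per-day routine index from a (days × slots) label matrix.

    Day ``d``'s index is the mean over slots of the fraction of *other* days
    whose label in that slot equals day ``d``'s (null labels compare equal
    to null).  Requires ≥ 2 days.
    """
    m = np.asarray(day_labels)
    if m.ndim != 2 or m.shape[0] < 2:
        raise UndefinedFeatureError("routine index requires at least 2 days")
    d = m.shape[0]
    out = np.empty(d)
    for i in range(d):
        matches = (m == m[i]).mean(axis=0) * d - 1  # exclude self-match
        out[i] = float(np.mean(matches / (d - 1)))
    return out


def window_features(
    trace: GpsTrace,
    stays: pd.DataFrame,
    home_id: int | None,
    t0: float,
    t1: float,
    denominator: str = "labeled",
) -> dict:
    """The six window-local phenotypes over [t0, t1) (routine_idx excluded).

    ``denominator`` picks the perc_home convention: "labeled" divides by
    time covered by the trace span (stays + transit), "wallclock" by the
    window length.  NaN features mark undefined values (e.g. < 2 points).
    """
    sel = (trace.t >= t0) & (trace.t < t1)
    lat, lon, t = trace.lat[sel], trace.lon[sel], trace.t[sel]
    out: dict[str, float] = {}
    if len(t) >= 2:
        out["loc_var"] = location_variance(lat, lon)
        out["total_dist"] = total_distance(lat, lon)
        out["max_dist"] = max_distance(lat, lon)
    else:
        out["loc_var"] = np.nan
        out["total_dist"] = 0.0 if len(t) else np.nan
        out["max_dist"] = 0.0 if len(t) else np.nan
    if stays.empty:
        out.update(num_pls=np.nan, ent_pls=np.nan, perc_home=np.nan)
        return out
    ov = _overlap(stays["t_start"].to_numpy(), stays["t_end"].to_numpy(), t0, t1)
    per_place = pd.Series(ov).groupby(stays["place_id"].to_numpy()).sum()
    per_place = per_place[per_place > 0]
    if per_place.empty:
        out.update(num_pls=0.0, ent_pls=np.nan, perc_home=np.nan)
        return out
    out["num_pls"] = float(len(per_place))
    out["ent_pls"] = place_entropy(per_place.to_numpy())
    if denominator == "wallclock":
        denom = t1 - t0
    else:
        denom = float(np.clip(t[-1] - t[0], 0.0, t1 - t0)) if len(t) >= 2 else 0.0
    home_dwell = float(per_place.get(home_id, 0.0)) if home_id is not None else np.nan
    # stays interpolate across ping gaps, so dwell can slightly exceed the
    # covered point span; cap at 100
    out["perc_home"] = min(100.0, 100.0 * home_dwell / denom) if denom > 0 else np.nan
    return out


def daily_phenotypes(
    trace: GpsTrace,
    utc_offset_h: float = -6.0,
    d_thresh_m: float = DEFAULT_D_THRESH_M,
    t_min_s: float = DEFAULT_T_MIN_S,
    merge_thresh_m: float = DEFAULT_MERGE_THRESH_M,
    slot_width_min: int = DEFAULT_SLOT_WIDTH_MIN,
    denominator: str = "labeled",
) -> pd.DataFrame:
    """Per-day table of the seven phenotypes for one participant.

    Columns ``participant_id, date, loc_var, num_pls, ent_pls, perc_home,
    total_dist, max_dist, routine_idx``.  perc_home is NaN throughout when
    home is undefined (no 00:00-06:00 dwell over the period); routine_idx is
    NaN when fewer than 2 days of data exist.
    """
    if len(trace) == 0:
        return pd.DataFrame(
            columns=["participant_id", "date", "loc_var", "num_pls", "ent_pls",
                     "perc_home", "total_dist", "max_dist", "routine_idx"]
        )
    _, stays, _ = extract_places(trace, d_thresh_m, t_min_s, merge_thresh_m)
    try:
        home_id = identify_home(stays, utc_offset_h)
    except UndefinedFeatureError:
        home_id = None
    dates = sorted(set(local_date(trace.t, utc_offset_h)))
    rows = []
    label_rows = []
    for date in dates:
        d0 = day_start_epoch(date, utc_offset_h)
        feats = window_features(trace, stays, home_id, d0, d0 + SECONDS_PER_DAY, denominator)
        rows.append({"participant_id": trace.participant_id, "date": date, **feats})
        label_rows.append(slot_labels(stays, d0, d0 + SECONDS_PER_DAY, slot_width_min))
    df = pd.DataFrame(rows)
    if len(dates) >= 2:
        df["routine_idx"] = routine_index(np.vstack(label_rows))
    else:
        df["routine_idx"] = np.nan
    if home_id is None:
        df["perc_home"] = np.nan
    return df
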