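"""Seeded synthetic cohorts: duty-cycled GPS traces plus coupled mood reports.

The generator emulates the sensing regime of a smartphone study whose GPS
sensor scans for one minute out of every ten, and plants the behavioral
structure the analysis layers are meant to recover:

* each participant has a **home** and a small set of **anchor places**
  (clustered on one side of home, like a campus district);
* each day is an alternating home / excursion schedule: with probability
  governed by the regime's ``home_fraction`` the participant leaves home
  once, departing and returning at times drawn from a 48-slot
  time-of-day intensity profile (``peak_profile``), visiting one or more
  anchors with straight-line constant-speed transits between them;
* pings are emitted only inside the first 60 s of each 10-minute cycle,
  cycles drop out i.i.d., and positions get isotropic Gaussian noise;
* one momentary sadness report per participant-day at a uniformly random
  daytime minute, with ``P(severe) = logistic(beta0 + Σ beta·z(feature) +
  u_participant)`` computed from the generator's own noise-free mobility
  features over the 24 hours preceding the prompt, so the mobility→mood
  coupling is tunable, known, and aligned with what a 24-hour pre-report
  feature window can observe.

Two presets encode contrasting routines: ``pre2020`` (three anchors,
bimodal morning/evening movement, less time at home) and ``mid2020`` (one
to two anchors, flat midday movement, more time at home).

All randomness flows from one integer seed through ``numpy.random.
SeedSequence`` spawning; identical configs + seed give identical output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from mobiphen.io_gps import GpsTrace, SadnessReport, SECONDS_PER_DAY
from mobiphen.displacement import haversine_m
from mobiphen.phenotypes import project_local_m, place_entropy

CYCLE_S = 600.0  # duty cycle period
SCAN_S = 60.0  # scan window at the head of each cycle
SLOT_S = 1800.0  # half-hour scheduling slots
N_SLOTS = 48

#: features of the ground-truth log that a coupling may weight
COUPLABLE_FEATURES = ("loc_var", "num_pls", "ent_pls", "perc_home", "total_dist", "max_dist")


def _bimodal_profile() -> np.ndarray:
    """Movement intensity peaked 8-10 a.m. and 7-9 p.m., quiet at night."""
    w = np.zeros(N_SLOTS)
    w[12:44] = 0.02  # awake 6:00-22:00
    w[16:20] = 1.0  # 8:00-10:00
    w[38:42] = 1.0  # 19:00-21:00
    return w


def _midday_profile() -> np.ndarray:
    """Flat midday movement 10 a.m.-6 p.m., quiet mornings and evenings."""
    w = np.zeros(N_SLOTS)
    w[12:44] = 0.02
    w[20:36] = 1.0  # 10:00-18:00
    return w


@dataclasses.dataclass
class RegimeConfig:
    """Behavioral regime of a simulated cohort."""

    n_participants: int = 20
    n_days: int = 21
    n_places: float = 3.0  # typical non-home anchor count per participant
    peak_profile: np.ndarray = dataclasses.field(default_factory=_bimodal_profile)
    home_fraction: float = 0.55  # target fraction of time at home
    trip_speed_mps: float = 5.0
    jitter_sd_m: float = 10.0
    dropout_prob: float = 0.2
    pings_per_scan: int = 3
    min_away_s: float = 4 * 3600.0  # minimum departure-to-return gap
    anchor_dist_m: float = 1500.0  # typical home-to-anchor distance
    utc_offset_h: float = -6.0

    def __post_init__(self) -> None:
        self.peak_profile = np.asarray(self.peak_profile, dtype=float)
        if self.peak_profile.shape != (N_SLOTS,) or np.any(self.peak_profile < 0):
            raise ValueError("peak_profile must be 48 non-negative weights")
        for p in (self.home_fraction, self.dropout_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclasses.dataclass
class CouplingConfig:
    """Logistic coupling from standardized daily features to severe sadness."""

    beta0: float = float(logit(0.35))
    betas: dict = dataclasses.field(default_factory=dict)
    sigma_u: float = 0.5  # SD of the participant random intercept
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")
        unknown = set(self.betas) - set(COUPLABLE_FEATURES)
        if unknown:
            raise ValueError(f"unknown coupling features {sorted(unknown)}")


PRESETS: dict[str, RegimeConfig] = {
    "pre2020": RegimeConfig(
        n_places=3.0,
        peak_profile=_bimodal_profile(),
        home_fraction=0.55,
    ),
    "mid2020": RegimeConfig(
        n_places=1.5,
        peak_profile=_midday_profile(),
        home_fraction=0.80,
    ),
}


@dataclasses.dataclass
class DayPath:
    """Continuous noise-free path for one participant-day.

    Piecewise linear between breakpoints; a segment log records the kind of
    every interval (``home``, ``dwell`` at an anchor, or ``transit``).
    """

    times: np.ndarray  # breakpoint seconds from local midnight
    lats: np.ndarray
    lons: np.ndarray
    segments: list  # dicts: kind, t0, t1, place (anchor index or None)

    def position(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(t, dtype=float)
        return np.interp(t, self.times, self.lats), np.interp(t, self.times, self.lons)

    def transit_seconds(self) -> float:
        return sum(s["t1"] - s["t0"] for s in self.segments if s["kind"] == "transit")


def _expected_away_s(regime: RegimeConfig) -> float:
    """Exact expected departure→return gap under the scheduling profile."""
    w = regime.peak_profile
    min_slots = int(np.ceil(regime.min_away_s / SLOT_S))
    total = w.sum()
    if total == 0:
        return 0.0
    e = 0.0
    p_dep_mass = 0.0
    for i in range(N_SLOTS):
        if w[i] == 0:
            continue
        later = w[i + min_slots :]
        if later.sum() == 0:
            continue
        p_ret = later / later.sum()
        gap = (np.arange(i + min_slots, N_SLOTS) - i) * SLOT_S
        e += w[i] * float(p_ret @ gap)
        p_dep_mass += w[i]
    if p_dep_mass == 0:
        return 0.0
    return e / p_dep_mass


def _seg(kind, t0, t1, p0, p1, place=None):
    return {
        "kind": kind, "t0": float(t0), "t1": float(t1), "place": place,
        "lat0": float(p0[0]), "lon0": float(p0[1]), "lat1": float(p1[0]), "lon1": float(p1[1]),
    }


def _stationary_day(home: np.ndarray) -> DayPath:
    return DayPath(
        np.array([0.0, SECONDS_PER_DAY]),
        np.array([home[0], home[0]]),
        np.array([home[1], home[1]]),
        [_seg("home", 0.0, SECONDS_PER_DAY, home, home)],
    )


def simulate_participant_day(
    home: np.ndarray,
    places: np.ndarray,
    regime: RegimeConfig,
    rng: np.random.Generator,
) -> DayPath:
    """Simulate one day's continuous path: dwells at anchors, linear transits.

    The day starts and ends at home.  Departure and return slots are drawn
    from ``peak_profile`` (return at least ``min_away_s`` later); the
    excursion visits a regime-governed number of distinct anchors in
    sequence.  The probability of leaving home at all is scaled so that the
    long-run fraction of time at home tracks ``home_fraction``.
    """
    places = np.asarray(places, dtype=float).reshape(-1, 2)
    if len(places) == 0 or regime.home_fraction >= 1.0:
        return _stationary_day(home)
    e_away = _expected_away_s(regime)
    if e_away <= 0:
        return _stationary_day(home)
    p_out = min(1.0, (1.0 - regime.home_fraction) * SECONDS_PER_DAY / e_away)
    if rng.random() >= p_out:
        return _stationary_day(home)

    w = regime.peak_profile.copy()
    min_slots = int(np.ceil(regime.min_away_s / SLOT_S))
    valid_dep = np.array([w[i] > 0 and w[i + min_slots :].sum() > 0 for i in range(N_SLOTS)])
    if not valid_dep.any():
        return _stationary_day(home)
    p_dep = np.where(valid_dep, w, 0.0)
    dep_slot = int(rng.choice(N_SLOTS, p=p_dep / p_dep.sum()))
    later = np.arange(dep_slot + min_slots, N_SLOTS)
    p_ret = w[later] / w[later].sum()
    ret_slot = int(rng.choice(later, p=p_ret))
    t_dep = (dep_slot + rng.random()) * SLOT_S
    t_ret = (ret_slot + rng.random()) * SLOT_S

    # how many distinct anchors this excursion visits
    k = 1 + int(rng.poisson(0.35 * max(0.0, regime.n_places - 1.0)))
    k = min(k, len(places))
    order = rng.permutation(len(places))[:k]
    while k >= 1:
        stops = places[order[:k]]
        route = np.vstack([home, stops, home])
        leg_d = haversine_m(route[:-1, 0], route[:-1, 1], route[1:, 0], route[1:, 1])
        transit_total = float(np.sum(leg_d)) / regime.trip_speed_mps
        interior = (t_ret - t_dep) - transit_total
        if interior >= 600.0 * k:
            break
        k -= 1
    if k < 1:
        return _stationary_day(home)

    # dwell allocation: 10 min floor per stop, remainder split Dirichlet
    extra = interior - 600.0 * k
    dwells = 600.0 + rng.dirichlet(np.ones(k)) * extra

    times = [0.0, t_dep]
    lats = [home[0], home[0]]
    lons = [home[1], home[1]]
    segments = [_seg("home", 0.0, t_dep, home, home)]
    t = t_dep
    prev = home
    for j in range(k):
        stop = stops[j]
        tt = float(haversine_m(prev[0], prev[1], stop[0], stop[1])) / regime.trip_speed_mps
        segments.append(_seg("transit", t, t + tt, prev, stop))
        t += tt
        times.append(t)
        lats.append(stop[0])
        lons.append(stop[1])
        segments.append(_seg("dwell", t, t + dwells[j], stop, stop, place=int(order[j])))
        t += dwells[j]
        times.append(t)
        lats.append(stop[0])
        lons.append(stop[1])
        prev = stop
    tt = float(haversine_m(prev[0], prev[1], home[0], home[1])) / regime.trip_speed_mps
    segments.append(_seg("transit", t, t + tt, prev, home))
    t += tt
    times.append(t)
    lats.append(home[0])
    lons.append(home[1])
    segments.append(_seg("home", t, SECONDS_PER_DAY, home, home))
    times.append(SECONDS_PER_DAY)
    lats.append(home[0])
    lons.append(home[1])
    return DayPath(np.array(times), np.array(lats), np.array(lons), segments)


def emit_pings(
    path: DayPath,
    regime: RegimeConfig,
    rng: np.random.Generator,
    t_offset: float = 0.0,
    participant_id: str = "sim",
) -> GpsTrace:
    """Sample duty-cycled, noisy pings from a continuous day path.

    Pings fall only within the first ``SCAN_S`` seconds of each 10-minute
    cycle; whole cycles drop out i.i.d. with ``dropout_prob``; positions get
    isotropic Gaussian noise of SD ``jitter_sd_m``.
    """
    n_cycles = int(SECONDS_PER_DAY / CYCLE_S)
    keep = rng.random(n_cycles) >= regime.dropout_prob
    ts = []
    for c in np.flatnonzero(keep):
        offs = np.sort(rng.uniform(0.0, SCAN_S, regime.pings_per_scan))
        ts.append(c * CYCLE_S + offs)
    if not ts:
        return GpsTrace(participant_id, pd.DataFrame(columns=["t", "lat", "lon", "accuracy"]))
    t = np.concatenate(ts)
    lat, lon = path.position(t)
    lat0 = float(np.mean(path.lats))
    deg_per_m_lat = 1.0 / 111_194.9
    deg_per_m_lon = deg_per_m_lat / np.cos(np.radians(lat0))
    noise = rng.normal(0.0, regime.jitter_sd_m, (len(t), 2))
    lat = lat + noise[:, 0] * deg_per_m_lat
    lon = lon + noise[:, 1] * deg_per_m_lon
    points = pd.DataFrame({"t": t + t_offset, "lat": lat, "lon": lon, "accuracy": np.nan})
    return GpsTrace(participant_id, points)


def true_window_features(segments: list, t0: float, t1: float) -> dict:
    """Noise-free phenotypes over [t0, t1) from the generator's event log.

    ``segments`` carry absolute times and endpoint coordinates.  Dwell is
    keyed by place ("home" or anchor index); transits contribute distance
    proportionally to their overlap with the window.  With the whole-day
    window this yields the planted daily features.
    """
    dwell: dict[object, float] = {}
    coords: dict[object, tuple[float, float]] = {}
    total_dist = 0.0
    for s in segments:
        ov = min(s["t1"], t1) - max(s["t0"], t0)
        if ov <= 0:
            continue
        if s["kind"] == "transit":
            frac = ov / (s["t1"] - s["t0"]) if s["t1"] > s["t0"] else 0.0
            total_dist += frac * float(haversine_m(s["lat0"], s["lon0"], s["lat1"], s["lon1"]))
            continue
        key = "home" if s["kind"] == "home" else s["place"]
        dwell[key] = dwell.get(key, 0.0) + ov
        coords[key] = (s["lat0"], s["lon0"])
    if not dwell:
        raise ValueError("window outside the simulated period")
    keys = list(dwell)
    wts = np.array([dwell[k] for k in keys])
    pts = np.array([coords[k] for k in keys])
    x, y = project_local_m(pts[:, 0], pts[:, 1], float(pts[0, 0]), float(pts[0, 1]))
    wbar = wts / wts.sum()
    loc_var = float(
        np.sqrt(
            np.sum(wbar * (x - np.sum(wbar * x)) ** 2) + np.sum(wbar * (y - np.sum(wbar * y)) ** 2)
        )
    )
    if len(pts) >= 2:
        d = haversine_m(pts[:, None, 0], pts[:, None, 1], pts[None, :, 0], pts[None, :, 1])
        max_dist = float(np.max(d))
    else:
        max_dist = 0.0
    return {
        "loc_var": loc_var,
        "num_pls": float(len(keys)),
        "ent_pls": place_entropy(wts),
        "perc_home": 100.0 * dwell.get("home", 0.0) / (t1 - t0),
        "total_dist": total_dist,
        "max_dist": max_dist,
    }


@dataclasses.dataclass
class Cohort:
    """A simulated cohort: traces, survey reports and the ground-truth log."""

    traces: list  # GpsTrace per participant
    reports: list  # SadnessReport
    truth: pd.DataFrame  # per participant-day planted features, u, p_severe
    participants: pd.DataFrame  # per participant: home, anchors, u
    regime: RegimeConfig
    coupling: CouplingConfig
    seed: int


def simulate_cohort(
    regime: RegimeConfig,
    coupling: CouplingConfig | None = None,
    seed: int | None = None,
    start_date: str = "2020-02-01",
    id_prefix: str = "P",
    city_center: tuple[float, float] = (30.28, -97.74),
) -> Cohort:
    """Generate a full seeded cohort with mobility-coupled sadness labels.

    Severe-sadness probability per participant-day is
    ``expit(beta0 + Σ_f beta_f · z(feature_f) + u_participant)`` where the
    z-scores standardize the *planted* (noise-free) daily features across
    the whole cohort, and ``u ~ N(0, sigma_u²)``.  One report is emitted per
    participant-day at a uniformly random minute between 09:00 and 21:00
    local.
    """
    coupling = coupling or CouplingConfig()
    if seed is None:
        seed = coupling.seed if coupling.seed is not None else 0
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(regime.n_participants + 1)
    label_rng = np.random.default_rng(streams[-1])
    day0 = pd.Timestamp(start_date).timestamp() - regime.utc_offset_h * 3600.0

    traces: list[GpsTrace] = []
    truth_rows = []
    part_rows = []
    all_segments: list[list] = []  # absolute-time event log per participant
    deg_per_m = 1.0 / 111_194.9
    for i in range(regime.n_participants):
        rng = np.random.default_rng(streams[i])
        pid = f"{id_prefix}{i:03d}"
        home = np.array(city_center) + rng.normal(0.0, 2500.0, 2) * deg_per_m
        n_anchor = int(rng.poisson(regime.n_places))
        # anchors cluster in a 120-degree sector on one side of home
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        thetas = theta0 + rng.uniform(-np.pi / 3.0, np.pi / 3.0, n_anchor)
        dists = rng.gamma(4.0, regime.anchor_dist_m / 4.0, n_anchor)
        anchors = np.column_stack(
            [
                home[0] + dists * np.sin(thetas) * deg_per_m,
                home[1] + dists * np.cos(thetas) * deg_per_m / np.cos(np.radians(home[0])),
            ]
        )
        u_i = rng.normal(0.0, coupling.sigma_u)
        frames = []
        segments: list = []
        for d in range(regime.n_days):
            offset = day0 + d * SECONDS_PER_DAY
            path = simulate_participant_day(home, anchors, regime, rng)
            day_trace = emit_pings(path, regime, rng, t_offset=offset, participant_id=pid)
            frames.append(day_trace.points)
            for s in path.segments:
                segments.append({**s, "t0": s["t0"] + offset, "t1": s["t1"] + offset})
            feats = true_window_features(segments, offset, offset + SECONDS_PER_DAY)
            truth_rows.append(
                {
                    "participant_id": pid,
                    "date": (pd.Timestamp(start_date) + pd.Timedelta(days=d)).date(),
                    "day_index": d,
                    **feats,
                    "u": u_i,
                }
            )
        traces.append(GpsTrace(pid, pd.concat(frames, ignore_index=True)))
        all_segments.append(segments)
        part_rows.append(
            {
                "participant_id": pid,
                "home_lat": home[0],
                "home_lon": home[1],
                "n_anchors": n_anchor,
                "anchors": json.dumps(np.round(anchors, 7).tolist()),
                "u": u_i,
            }
        )

    truth = pd.DataFrame(truth_rows)
    # prompts: one per participant-day at a uniformly random daytime minute
    report_s = label_rng.uniform(9 * 3600.0, 21 * 3600.0, len(truth))
    truth["report_t"] = day0 + truth["day_index"].to_numpy() * SECONDS_PER_DAY + report_s

    # noise-free features of the 24 h preceding each prompt drive the label
    win_rows = []
    for i, row in enumerate(truth.itertuples()):
        pidx = int(row.Index // regime.n_days) if regime.n_days else 0
        segs = all_segments[pidx]
        t1 = float(row.report_t)
        t0 = max(t1 - SECONDS_PER_DAY, day0)
        win_rows.append(true_window_features(segs, t0, t1))
    win = pd.DataFrame(win_rows, index=truth.index).add_prefix("win_")
    truth = pd.concat([truth, win], axis=1)

    eta = np.full(len(truth), coupling.beta0) + truth["u"].to_numpy()
    for feat, beta in coupling.betas.items():
        v = truth[f"win_{feat}"].to_numpy(dtype=float)
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        eta += beta * z
    p = expit(eta)
    severe = label_rng.random(len(truth)) < p
    truth["p_severe"] = p
    truth["severe"] = severe

    levels_sev = np.where(label_rng.random(len(truth)) < 0.7, "quite_a_bit", "very_much")
    levels_ok = np.where(label_rng.random(len(truth)) < 0.6, "not_at_all", "a_little_bit")
    level = np.where(severe, levels_sev, levels_ok)
    reports = [
        SadnessReport(r.participant_id, float(r.report_t), lvl)
        for r, lvl in zip(truth.itertuples(), level)
    ]
    participants = pd.DataFrame(part_rows)
    return Cohort(traces, reports, truth, participants, regime, coupling, seed)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write a cohort in the package CSV dialects; returns written paths."""
    from mobiphen.io_gps import write_gps_csv, write_sadness_csv

    out = Path(out_dir)
    (out / "gps").mkdir(parents=True, exist_ok=True)
    paths = {"gps": []}
    for trace in cohort.traces:
        p = out / "gps" / f"{trace.participant_id}.csv"
        write_gps_csv(trace, p)
        paths["gps"].append(str(p))
    write_sadness_csv(cohort.reports, out / "surveys.csv")
    cohort.truth.to_csv(out / "ground_truth.csv", index=False)
    cohort.participants.to_csv(out / "participants.csv", index=False)
    paths["surveys"] = str(out / "surveys.csv")
    paths["ground_truth"] = str(out / "ground_truth.csv")
    paths["participants"] = str(out / "participants.csv")
    return paths
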