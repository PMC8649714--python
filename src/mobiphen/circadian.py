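"""Nonparametric circadian-rhythm metrics on a binned displacement series.

The five actigraphy-style metrics are computed on the magnitude of a
participant's binned GPS displacement over the study period (15-minute bins
by default, so ``bins_per_hour = 4``):

* **IS** (interdaily stability): variance of the 24-hour mean profile over
  total variance, ``[Σ_h (X̄_h − X̄)² / 24] / [Σ_i (X_i − X̄)² / n]`` with
  hourly means X̄_h pooled across days.  1 for a perfectly repeated daily
  pattern; ≈ 1/D for D days of exchangeable noise.
* **IV** (intradaily variability): normalized mean squared successive
  difference, ``[Σ_{i≥2} (X_i − X_{i−1})² / (n−1)] / [Σ_i (X_i − X̄)² / n]``.
  → 2 for white noise, small for slow smooth rhythms, up to ≈ 4 for a
  strictly alternating signal.
* **M10 / L5**: mean of the average time-of-day profile over its most
  active 10 consecutive hours / least active 5 consecutive hours, windows
  wrapping midnight.
* **RA** (relative amplitude): ``(M10 − L5) / (M10 + L5)``; 0 for a uniform
  signal, 1 when the least-active 5 hours are completely still.

All metrics assume the series is aligned to local midnight: element ``i``
of an aligned series belongs to day-bin ``(first_bin_index + i) mod
bins_per_day``.  A displacement series starts at the transition into the
period's second bin, hence its natural ``first_bin_index`` is 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from mobiphen.displacement import displacement_series
from mobiphen.io_gps import GpsTrace


class DegenerateSeriesError(ValueError):
    """Metric undefined: constant series (zero variance) or too short."""


@dataclasses.dataclass
class CircadianMetrics:
    """Per-participant circadian summary over the study period."""

    IS: float
    IV: float
    M10: float
    L5: float
    RA: float
    n: int


def _check_series(series: np.ndarray, min_len: int) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < min_len:
        raise DegenerateSeriesError(f"series must be 1-D with at least {min_len} samples")
    if not np.all(np.isfinite(x)):
        raise DegenerateSeriesError("series contains non-finite values")
    return x


def interdaily_stability(
    series: np.ndarray, bins_per_hour: int = 4, first_bin_index: int = 0
) -> float:
    """Interdaily stability of an aligned displacement series.

    Requires at least two days of samples and a non-constant series.
    """
    x = _check_series(series, 2)
    bins_per_day = 24 * bins_per_hour
    if len(x) < 2 * bins_per_day - 1:
        raise DegenerateSeriesError("IS requires the series to span at least 2 days")
    denom = np.var(x)  # Σ(X_i − X̄)² / n
    if denom == 0:
        raise DegenerateSeriesError("IS undefined for a constant series")
    hours = ((first_bin_index + np.arange(len(x))) // bins_per_hour) % 24
    xbar = x.mean()
    num = 0.0
    for h in range(24):
        sel = x[hours == h]
        if len(sel):
            num += (sel.mean() - xbar) ** 2
    return float(num / 24.0 / denom)


def intradaily_variability(series: np.ndarray) -> float:
    """Intradaily variability (normalized mean squared successive difference)."""
    x = _check_series(series, 2)
    denom = np.var(x)
    if denom == 0:
        raise DegenerateSeriesError("IV undefined for a constant series")
    n = len(x)
    num = np.sum(np.diff(x) ** 2) / (n - 1)
    return float(num / denom)


def average_daily_profile(
    series: np.ndarray, bins_per_hour: int = 4, first_bin_index: int = 0
) -> np.ndarray:
    """Mean signal per time-of-day bin across all days (length 24·bins_per_hour).

    Raises if any time-of-day bin is unrepresented (less than one complete
    day of coverage).
    """
    x = _check_series(series, 1)
    bins_per_day = 24 * bins_per_hour
    idx = (first_bin_index + np.arange(len(x))) % bins_per_day
    counts = np.bincount(idx, minlength=bins_per_day)
    if np.any(counts == 0):
        raise DegenerateSeriesError("profile requires at least one complete day of samples")
    sums = np.bincount(idx, weights=x, minlength=bins_per_day)
    return sums / counts


def m10_l5(
    series: np.ndarray, bins_per_hour: int = 4, first_bin_index: int = 0
) -> tuple[float, float]:
    """M10 and L5 from the average daily profile, windows wrapping midnight."""
    profile = average_daily_profile(series, bins_per_hour, first_bin_index)
    m10 = _best_window_mean(profile, 10 * bins_per_hour, maximize=True)
    l5 = _best_window_mean(profile, 5 * bins_per_hour, maximize=False)
    return m10, l5


def _best_window_mean(profile: np.ndarray, width: int, maximize: bool) -> float:
    # direct window means (not a cumsum trick): every window of a constant
    # profile then rounds identically, so M10 == L5 exactly in that case
    n = len(profile)
    wrapped = np.concatenate([profile, profile[: width - 1]])
    windows = np.lib.stride_tricks.sliding_window_view(wrapped, width)[:n]
    means = windows.mean(axis=1)
    return float(means.max() if maximize else means.min())


def relative_amplitude(m10: float, l5: float) -> float:
    """(M10 − L5) / (M10 + L5); defined as 0 for a completely still signal."""
    if m10 < l5:
        # a flat profile can round M10 one ulp below L5 (different window widths)
        if l5 - m10 <= 1e-9 * max(abs(l5), 1.0):
            m10 = l5
        else:
            raise ValueError("M10 must be >= L5")
    if m10 + l5 == 0:
        return 0.0
    return float((m10 - l5) / (m10 + l5))


def circadian_metrics(
    series: np.ndarray, bins_per_hour: int = 4, first_bin_index: int = 0
) -> CircadianMetrics:
    """All five metrics for one aligned series."""
    x = _check_series(series, 2)
    m10, l5 = m10_l5(x, bins_per_hour, first_bin_index)
    return CircadianMetrics(
        IS=interdaily_stability(x, bins_per_hour, first_bin_index),
        IV=intradaily_variability(x),
        M10=m10,
        L5=l5,
        RA=relative_amplitude(m10, l5),
        n=len(x),
    )


def participant_circadian_metrics(
    trace: GpsTrace,
    bin_width_min: int = 15,
    utc_offset_h: float = -6.0,
) -> CircadianMetrics:
    """Circadian metrics straight from a GPS trace over its study period.

    The 15-minute displacement series is computed with cross-day carry
    forward; a trailing partial day would unbalance the hourly means in IS,
    but the binning grid already spans whole calendar days, so no truncation
    is needed beyond what binning imposes.
    """
    series = displacement_series(trace, bin_width_min, utc_offset_h)
    bins_per_hour = 60 // bin_width_min
    # series[0] is the displacement into bin 1 of the first day
    return circadian_metrics(series, bins_per_hour, first_bin_index=1)
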