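"""Independent brute-force oracles used to cross-check the fast paths.

Deliberately written as literal double loops over the defining formulas, a
different shape from the vectorized implementations they check.
"""

import math


def naive_is(series, bins_per_hour, first_bin_index=0):
    n = len(series)
    xbar = sum(series) / n
    hour_sums, hour_counts = [0.0] * 24, [0] * 24
    for i in range(n):
        h = ((first_bin_index + i) // bins_per_hour) % 24
        hour_sums[h] += series[i]
        hour_counts[h] += 1
    num = 0.0
    for h in range(24):
        if hour_counts[h]:
            num += (hour_sums[h] / hour_counts[h] - xbar) ** 2
    num /= 24.0
    den = sum((x - xbar) ** 2 for x in series) / n
    return num / den


def naive_iv(series):
    n = len(series)
    xbar = sum(series) / n
    num = sum((series[i] - series[i - 1]) ** 2 for i in range(1, n)) / (n - 1)
    den = sum((x - xbar) ** 2 for x in series) / n
    return num / den


def naive_daily_profile(series, bins_per_hour, first_bin_index=0):
    bpd = 24 * bins_per_hour
    sums, counts = [0.0] * bpd, [0] * bpd
    for i, x in enumerate(series):
        b = (first_bin_index + i) % bpd
        sums[b] += x
        counts[b] += 1
    return [s / c for s, c in zip(sums, counts)]


def naive_m10_l5(series, bins_per_hour, first_bin_index=0):
    profile = naive_daily_profile(series, bins_per_hour, first_bin_index)
    bpd = len(profile)

    def window_mean(start, width):
        return sum(profile[(start + j) % bpd] for j in range(width)) / width

    w10, w5 = 10 * bins_per_hour, 5 * bins_per_hour
    m10 = max(window_mean(s, w10) for s in range(bpd))
    l5 = min(window_mean(s, w5) for s in range(bpd))
    return m10, l5


def naive_haversine_m(lat1, lon1, lat2, lon2, radius=6_371_000.0):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(a))


def naive_max_pairwise_m(lats, lons):
    best = 0.0
    for i in range(len(lats)):
        for j in range(i + 1, len(lats)):
            best = max(best, naive_haversine_m(lats[i], lons[i], lats[j], lons[j]))
    return best


def naive_welch(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    sa2 = sum((x - ma) ** 2 for x in a) / (na - 1)
    sb2 = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = sa2 / na + sb2 / nb
    t = (ma - mb) / math.sqrt(se2)
    dof = se2**2 / ((sa2 / na) ** 2 / (na - 1) + (sb2 / nb) ** 2 / (nb - 1))
    return t, dof
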