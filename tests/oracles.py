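"""Independent brute-force oracle implementations.

Deliberately naive (pure-Python loops, direct definitions) and kept
separate from the package so that agreement tests compare two
independently written code paths.
"""

import math


def sd(values):
    """Sample standard deviation by the direct definition (ddof=1)."""
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def rmssd(values):
    """Root mean square of successive differences."""
    diffs = [values[i + 1] - values[i] for i in range(len(values) - 1)]
    return math.sqrt(sum(d * d for d in diffs) / len(diffs))


def pnn50(values):
    """Percentage of successive differences exceeding 50 ms."""
    diffs = [abs(values[i + 1] - values[i]) for i in range(len(values) - 1)]
    return 100.0 * sum(1 for d in diffs if d > 50.0) / len(diffs)


def mean_instant_hr(values_ms):
    return sum(60000.0 / v for v in values_ms) / len(values_ms)


def apen(values, m, r):
    """Approximate entropy by direct O(n^2) template counting,
    self-matches included, Chebyshev distance."""
    n = len(values)

    def phi(mm):
        count_log_sum = 0.0
        k = n - mm + 1
        for i in range(k):
            matches = 0
            for j in range(k):
                d = max(abs(values[i + t] - values[j + t]) for t in range(mm))
                if d <= r:
                    matches += 1
            count_log_sum += math.log(matches / k)
        return count_log_sum / k

    return phi(m) - phi(m + 1)


def spearman_rho(x, y):
    """Spearman correlation via mid-ranks and the Pearson formula."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def pearson_r(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def band_fraction_periodogram(values, dt, band, total):
    """Band-power fraction via a plain rectangular periodogram (numpy-free
    DFT of the mean-removed series) — used to cross-check the Welch path."""
    n = len(values)
    mean = sum(values) / n
    x = [v - mean for v in values]
    power_band = 0.0
    power_total = 0.0
    for k in range(1, n // 2):
        f = k / (n * dt)
        re = sum(x[t] * math.cos(2 * math.pi * k * t / n) for t in range(n))
        im = sum(x[t] * math.sin(2 * math.pi * k * t / n) for t in range(n))
        p = re * re + im * im
        if total[0] <= f < total[1]:
            power_total += p
            if band[0] <= f < band[1]:
                power_band += p
    return power_band / power_total if power_total else float("nan")
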