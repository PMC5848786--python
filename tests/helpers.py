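"""Independent oracles used across the test suite.

These deliberately avoid the library code paths they check: percentiles
by hand-rolled sorting and rank interpolation, changepoints by an
exhaustive O(n^2) dynamic program without pruning, and solar position
by a Meeus-style algorithm distinct from the NOAA formulas used in the
package.
"""

from __future__ import annotations

import math

import numpy as np


def sort_percentile(values, q: float) -> float:
    """Linear-interpolation percentile computed from first principles."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    pos = (q / 100.0) * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def population_sd(values) -> float:
    xs = [float(v) for v in values]
    m = sum(xs) / len(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))


def optimal_partitioning(x, beta: float, minseg: int) -> list[int]:
    """Exhaustive penalized segmentation (no pruning): the PELT oracle."""
    x = np.asarray(x, float)
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i: int, j: int) -> float:
        m = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    F = np.full(n + 1, np.inf)
    F[0] = -beta
    last = np.zeros(n + 1, dtype=int)
    for t in range(minseg, n + 1):
        for tau in range(0, t - minseg + 1):
            if np.isinf(F[tau]):
                continue
            v = F[tau] + cost(tau, t) + beta
            if v < F[t]:
                F[t] = v
                last[t] = tau
    cps = []
    t = n
    while last[t] != 0:
        cps.append(int(last[t]))
        t = last[t]
    return sorted(cps)


def spencer_solar_elevation(lat, lon, utc_offset, when) -> float:
    """Solar elevation via Spencer's Fourier-series formulas (test oracle).

    ``when`` is a naive local-standard-time datetime.  Truncated
    fractional-year harmonics for declination and the equation of time;
    independent of the package's Meeus-series implementation and
    accurate to roughly a quarter degree.
    """
    doy = when.timetuple().tm_yday
    hours = when.hour + when.minute / 60.0 + when.second / 3600.0
    year = when.year
    days = 366 if (year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)) else 365
    gamma = 2.0 * math.pi / days * (doy - 1 + (hours - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    tst = hours * 60.0 + eqtime + 4.0 * lon - 60.0 * utc_offset
    ha = math.radians(tst / 4.0 - 180.0)
    latr = math.radians(lat)
    sin_alt = math.sin(latr) * math.sin(decl) + math.cos(latr) * math.cos(
        decl
    ) * math.cos(ha)
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_alt))))
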