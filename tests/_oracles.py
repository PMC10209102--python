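"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles, without
importing the package's own implementations: a high-precision NOAA-style
solar position routine, plain-loop brute-force BBT classifiers, and a
hand-rolled natural-cubic-spline tridiagonal solver.
"""

import math

import numpy as np


# --- NOAA solar position (Julian-century series, independent of the
# package's Spencer day-of-year approximation) -------------------------

def noaa_declination(date) -> float:
    jd = date.toordinal() + 1721424.5
    jc = (jd - 2451545.0) / 36525.0
    gmls = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    seqc = (
        math.sin(math.radians(gmas)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(math.radians(2 * gmas)) * (0.019993 - 0.000101 * jc)
        + math.sin(math.radians(3 * gmas)) * 0.000289
    )
    true_long = gmls + seqc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(
        math.radians(125.04 - 1934.136 * jc)
    )
    mean_obliq = 23 + (26 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60) / 60
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    return math.degrees(
        math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    )


def noaa_day_length_minutes(latitude: float, date) -> float:
    delta = math.radians(noaa_declination(date))
    phi = math.radians(latitude)
    cos_w0 = (math.cos(math.radians(90.833)) - math.sin(phi) * math.sin(delta)) / (
        math.cos(phi) * math.cos(delta)
    )
    cos_w0 = min(1.0, max(-1.0, cos_w0))
    return 8.0 * math.degrees(math.acos(cos_w0))


# --- brute-force BBT classifiers (plain loops over 1-based days) ------

def brute_coverline(bbt, offset=0.15):
    """(label, evidence_day, threshold) by direct enumeration."""
    n = len(bbt)
    if n < 11:
        return "indeterminate", None, None
    first10 = [bbt[d - 1] for d in range(1, 11) if not math.isnan(bbt[d - 1])]
    later = [d for d in range(11, n + 1) if not math.isnan(bbt[d - 1])]
    n_avail = sum(0 if math.isnan(v) else 1 for v in bbt)
    if not first10 or not later or n_avail < 10:
        return "indeterminate", None, None
    threshold = max(first10) + offset
    for d in later:
        if bbt[d - 1] > threshold:
            return "ovulatory", d, threshold
    return "anovulatory", None, threshold


def brute_three_over_six(bbt):
    """(label, evidence_day) by scanning every 9-day window with loops."""
    n = len(bbt)
    found_complete_window = False
    for i in range(7, n - 1):  # window start day i, 1-based
        days = list(range(i - 6, i + 3))
        vals = [bbt[d - 1] for d in days]
        if any(math.isnan(v) for v in vals):
            continue
        found_complete_window = True
        prior_max = max(vals[:6])
        if all(v > prior_max for v in vals[6:9]):
            return "ovulatory", i
    if not found_complete_window:
        return "indeterminate", None
    return "anovulatory", None


# --- natural cubic spline via the classical tridiagonal system --------

def natural_spline_eval(xs, ys, xq):
    """Evaluate the natural cubic spline through (xs, ys) at points xq.

    Solves the textbook tridiagonal system for the knot second
    derivatives (M_0 = M_n = 0) with dense linear algebra.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n = len(xs)
    h = np.diff(xs)
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    A[0, 0] = 1.0
    A[-1, -1] = 1.0
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2.0 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        rhs[i] = 6.0 * ((ys[i + 1] - ys[i]) / h[i] - (ys[i] - ys[i - 1]) / h[i - 1])
    M = np.linalg.solve(A, rhs)

    out = []
    for x in np.atleast_1d(np.asarray(xq, dtype=float)):
        j = int(np.clip(np.searchsorted(xs, x) - 1, 0, n - 2))
        hj = h[j]
        a = (xs[j + 1] - x) / hj
        b = (x - xs[j]) / hj
        val = (
            a * ys[j]
            + b * ys[j + 1]
            + ((a**3 - a) * M[j] + (b**3 - b) * M[j + 1]) * hj**2 / 6.0
        )
        out.append(val)
    return np.array(out)
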