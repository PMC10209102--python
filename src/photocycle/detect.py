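"""Per-cycle ovulation classifiers.

Four labelers, all deterministic functions of one cycle's data:

* ``coverline`` — threshold = max BBT of days 1-10 plus a fixed offset
  (default 0.15 deg F); ovulatory iff any later temperature strictly
  exceeds it.
* ``three_over_six`` — ovulatory iff three consecutive temperatures
  each strictly exceed the maximum of the six preceding ones.
* ``nc_like`` — a documented approximation of a proprietary app
  detector: every day of a 3-day window must sit strictly above the
  pre-window (follicular) mean plus a rise margin (default 0.15 deg F,
  the scale of a genuine luteal rise rather than measurement noise),
  the window mean must strictly exceed that raised level and the
  whole-cycle mean, and it must lie within ``tau`` of the
  window-start-to-cycle-end (luteal) mean.
* ``lh`` — ovulatory iff any positive urinary LH test; indeterminate
  when the cycle has no tests.

All "exceeds/greater" comparisons are strict.  BBT detectors run on
the spline-completed series; windows touching imputed days are allowed
(and visible through the series' masks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import CompletedSeries

__all__ = [
    "OvulationCall",
    "detect_coverline",
    "detect_three_over_six",
    "detect_nc_like",
    "detect_lh",
    "detect_all",
]

METHODS = ("coverline", "three_over_six", "nc_like", "lh")
LABELS = ("ovulatory", "anovulatory", "indeterminate")


@dataclass(frozen=True)
class OvulationCall:
    method: str
    label: str
    evidence_day: int | None = None
    threshold_used: float | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def detect_coverline(series: CompletedSeries, offset: float = 0.15) -> OvulationCall:
    """Coverline rule: first-10-day max + ``offset``, strict exceedance after day 10."""
    bbt = series.bbt
    n = series.n_days
    if n < 11:
        return OvulationCall("coverline", "indeterminate")
    first10 = bbt[:10]
    later = bbt[10:]
    if (
        np.all(np.isnan(first10))
        or np.all(np.isnan(later))
        or np.count_nonzero(~np.isnan(bbt)) < 10
    ):
        return OvulationCall("coverline", "indeterminate")
    threshold = float(np.nanmax(first10)) + offset
    above = np.flatnonzero(np.nan_to_num(later, nan=-np.inf) > threshold)
    if above.size:
        return OvulationCall(
            "coverline", "ovulatory", evidence_day=int(above[0] + 11),
            threshold_used=threshold,
        )
    return OvulationCall("coverline", "anovulatory", threshold_used=threshold)


def detect_three_over_six(series: CompletedSeries) -> OvulationCall:
    """3-over-6 rule: three consecutive readings each above the prior six's max."""
    bbt = series.bbt
    n = series.n_days
    any_window = False
    for i in range(7, n - 1):  # 1-based window start i, needs days i-6..i+2
        window = bbt[i - 1 : i + 2]
        prior = bbt[i - 7 : i - 1]
        if np.any(np.isnan(window)) or np.any(np.isnan(prior)):
            continue
        any_window = True
        if np.all(window > prior.max()):
            return OvulationCall("three_over_six", "ovulatory", evidence_day=i)
    if not any_window:
        return OvulationCall("three_over_six", "indeterminate")
    return OvulationCall("three_over_six", "anovulatory")


def detect_nc_like(
    series: CompletedSeries, tau: float = 0.15, rise_margin: float = 0.15
) -> OvulationCall:
    """Three-day-window detector approximating the app's published description."""
    bbt = series.bbt
    n = series.n_days
    if np.count_nonzero(~np.isnan(bbt)) < 10:
        return OvulationCall("nc_like", "indeterminate")
    eps = 1e-9  # guards the strict mean comparisons against fp round-off
    cycle_mean = float(np.nanmean(bbt))
    for i in range(2, n - 1):  # window days i..i+2, needs >= 1 prior day
        window = bbt[i - 1 : i + 2]
        if np.any(np.isnan(window)):
            continue
        pre = bbt[: i - 1]
        if np.all(np.isnan(pre)):
            continue
        wmean = float(window.mean())
        pre_mean = float(np.nanmean(pre))
        luteal_mean = float(np.nanmean(bbt[i - 1 :]))
        if (
            np.all(window > pre_mean + rise_margin + eps)
            and wmean > pre_mean + rise_margin + eps
            and wmean > cycle_mean + eps
            and abs(wmean - luteal_mean) <= tau
        ):
            return OvulationCall("nc_like", "ovulatory", evidence_day=i)
    return OvulationCall("nc_like", "anovulatory")


def detect_lh(lh_results) -> OvulationCall:
    """LH-test rule on a cycle's day-ordered test codes (pos/neg/none)."""
    codes = list(lh_results)
    tested = [i for i, c in enumerate(codes) if c in ("pos", "neg")]
    if not tested:
        return OvulationCall("lh", "indeterminate")
    for i in tested:
        if codes[i] == "pos":
            return OvulationCall("lh", "ovulatory", evidence_day=i + 1)
    return OvulationCall("lh", "anovulatory")


def detect_all(
    series: CompletedSeries,
    lh_results,
    coverline_offset=0.15,
    nc_tau=0.15,
    nc_rise_margin=0.15,
):
    """Run all four detectors on one cycle; returns {method: OvulationCall}."""
    return {
        "coverline": detect_coverline(series, offset=coverline_offset),
        "three_over_six": detect_three_over_six(series),
        "nc_like": detect_nc_like(series, tau=nc_tau, rise_margin=nc_rise_margin),
        "lh": detect_lh(lh_results),
    }
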