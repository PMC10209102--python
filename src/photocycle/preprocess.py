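"""Cohort exclusion cascade and cubic-spline BBT imputation.

Exclusions mirror a cycle-tracking study's participant filter: users
declaring ovulation-disrupting preconditions are dropped entirely;
cycles longer than 40 days, or with fewer than 10 valid BBT readings
(after discarding readings flagged for illness/alcohol/sleep
deviations), are dropped; a miscarriage or emergency-contraception
event removes that cycle and the next, a pregnancy removes that cycle
and the two following; cycles without usable coordinates or without
ambient temperature are dropped.  Each removed cycle is counted once,
under the first matching reason in that order.

BBT gaps are filled with a natural cubic spline (zero second
derivative at the span ends) through the observed (day, temperature)
knots.  Observed values are reproduced exactly; no extrapolation
beyond the first/last observed day; series with fewer than 4
observations are passed through unimputed and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "ExclusionLog",
    "CompletedSeries",
    "apply_exclusions",
    "impute_bbt_spline",
    "complete_cycle_series",
]

EXCLUSION_REASONS = (
    "precondition_user",
    "cycle_gt_40d",
    "lt_10_bbt",
    "event_cycle",
    "post_event_cycle",
    "no_region",
    "no_temperature",
)

_KNOWN_EVENTS = {"none", "pregnancy", "miscarriage", "emergency_contraception"}


@dataclass
class ExclusionLog:
    counts: dict = field(default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS})
    n_input: int = 0
    n_retained: int = 0
    warnings: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "warnings": list(self.warnings),
        }


def apply_exclusions(users: pd.DataFrame, cycles: pd.DataFrame, daily: pd.DataFrame):
    """Apply the exclusion cascade; return (retained cycles, ExclusionLog).

    ``retained`` is the cycles frame restricted to surviving rows (in
    a canonical user/start-date order, so the result is invariant to
    input row order).  Event adjacency ("the cycle immediately
    following") is resolved on each user's full chronological cycle
    sequence before any other filter.
    """
    log = ExclusionLog(n_input=len(cycles))

    cycles = cycles.sort_values(["user_id", "start_date", "cycle_id"]).reset_index(
        drop=True
    )

    unknown = set(cycles["event"].fillna("none")) - _KNOWN_EVENTS
    if unknown:
        for ev in sorted(unknown):
            log.warnings.append(f"unknown event code {ev!r}; affected cycles rejected")

    # Valid BBT counts: logged readings not flagged for deviations.
    valid_bbt = (
        daily[daily["bbt_f"].notna() & (daily["bbt_excluded_flag"] == 0)]
        .groupby("cycle_id")
        .size()
    )

    users_idx = users.set_index("user_id")
    precondition_users = set(users_idx.index[users_idx["precondition_flag"] == 1])
    region_missing_users = set(
        users_idx.index[
            users_idx["latitude"].isna() | users_idx["longitude"].isna()
        ]
    )

    # Event shadow: cycles removed because a prior cycle had an event.
    event_reason = {}
    for _, grp in cycles.groupby("user_id", sort=False):
        ids = grp["cycle_id"].tolist()
        evs = grp["event"].fillna("none").tolist()
        for k, ev in enumerate(evs):
            if ev == "none":
                continue
            if ev not in _KNOWN_EVENTS:
                event_reason.setdefault(ids[k], "event_cycle")
                continue
            n_follow = 2 if ev == "pregnancy" else 1
            event_reason.setdefault(ids[k], "event_cycle")
            for j in range(k + 1, min(k + 1 + n_follow, len(ids))):
                event_reason.setdefault(ids[j], "post_event_cycle")

    keep = []
    for row in cycles.itertuples(index=False):
        if row.user_id in precondition_users:
            reason = "precondition_user"
        elif row.n_days > 40:
            reason = "cycle_gt_40d"
        elif valid_bbt.get(row.cycle_id, 0) < 10:
            reason = "lt_10_bbt"
        elif row.cycle_id in event_reason:
            reason = event_reason[row.cycle_id]
        elif row.user_id in region_missing_users:
            reason = "no_region"
        elif pd.isna(row.ambient_temp_c):
            reason = "no_temperature"
        else:
            keep.append(True)
            continue
        log.counts[reason] += 1
        keep.append(False)

    retained = cycles[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    log.n_retained = len(retained)
    assert log.n_retained + log.n_removed == log.n_input
    return retained, log


@dataclass
class CompletedSeries:
    """A cycle's BBT series after gap-filling.

    ``bbt`` is indexed by cycle day (``day_index[i]`` = 1-based day);
    NaN marks days that are neither observed nor imputable (leading/
    trailing gaps, or any gap when imputation was skipped).
    """

    day_index: np.ndarray
    bbt: np.ndarray
    observed_mask: np.ndarray
    imputed_mask: np.ndarray
    imputation_skipped: bool = False

    @property
    def n_days(self) -> int:
        return len(self.day_index)


def impute_bbt_spline(
    days, temps, n_days: int | None = None, cycle_id: str = "?"
) -> CompletedSeries:
    """Natural-cubic-spline imputation of one cycle's BBT series.

    ``days`` are the 1-based observed day indices, ``temps`` the
    observed temperatures (deg F); deviation-flagged readings must
    already be dropped.  Knots are reproduced exactly; interior gaps
    between the first and last observed day are interpolated; with
    fewer than 4 observations the series is returned unimputed with
    ``imputation_skipped`` set.
    """
    days = np.asarray(days, dtype=int)
    temps = np.asarray(temps, dtype=float)
    if days.size != temps.size:
        raise ValueError(f"cycle {cycle_id}: day/temperature length mismatch")
    if days.size and np.any(np.diff(days) <= 0):
        if np.any(np.diff(np.sort(days)) == 0):
            raise ValueError(f"cycle {cycle_id}: duplicate day indices")
        raise ValueError(f"cycle {cycle_id}: day indices must be increasing")

    n = int(n_days) if n_days is not None else (int(days.max()) if days.size else 0)
    idx = np.arange(1, n + 1)
    bbt = np.full(n, np.nan)
    observed = np.zeros(n, dtype=bool)
    if days.size:
        bbt[days - 1] = temps
        observed[days - 1] = True
    imputed = np.zeros(n, dtype=bool)

    if days.size < 4:
        return CompletedSeries(idx, bbt, observed, imputed, imputation_skipped=True)

    spline = CubicSpline(days, temps, bc_type="natural")
    span = (idx >= days[0]) & (idx <= days[-1]) & ~observed
    bbt[span] = spline(idx[span])
    imputed[span] = True
    return CompletedSeries(idx, bbt, observed, imputed)


def complete_cycle_series(daily: pd.DataFrame, cycles: pd.DataFrame) -> dict:
    """Build a {cycle_id: CompletedSeries} map for the given cycles.

    Deviation-flagged readings are dropped before splining, matching
    the valid-measurement definition of the exclusion filter.
    """
    n_days_by_cycle = dict(zip(cycles["cycle_id"], cycles["n_days"]))
    wanted = set(n_days_by_cycle)
    valid = daily[
        daily["cycle_id"].isin(wanted)
        & daily["bbt_f"].notna()
        & (daily["bbt_excluded_flag"] == 0)
    ]
    grouped = {cid: g for cid, g in valid.groupby("cycle_id")}
    out = {}
    for cid in n_days_by_cycle:
        g = grouped.get(cid)
        if g is None:
            out[cid] = impute_bbt_spline(
                [], [], n_days=n_days_by_cycle[cid], cycle_id=cid
            )
        else:
            g = g.sort_values("day_index")
            out[cid] = impute_bbt_spline(
                g["day_index"].to_numpy(),
                g["bbt_f"].to_numpy(),
                n_days=n_days_by_cycle[cid],
                cycle_id=cid,
            )
    return out
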