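"""Per-cycle aggregation of daily libido and sexual-behavior logs.

Daily logs are sparse: most days carry no libido or sex entry.  Sex
entries are collapsed to a binary "had sex" (protected or unprotected
-> 1, explicit no-sex -> 0); days without a log would score 0 and are
dropped before averaging, so that infrequent loggers are not pulled
toward zero.  A cycle with sex logged on 3 of its 4 logging days
therefore scores 3/4 = 0.75.  Libido is logged on a 1-3 scale
(0 is reserved for "unlogged" in the schema) and averaged over logged
days the same way.  A cycle with no logged days has no score and is
excluded from the corresponding model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CycleBehavior", "collapse_sex", "cycle_score", "aggregate_behavior"]

_SEX_MAP = {"unprotected": 1.0, "protected": 1.0, "no_sex": 0.0, "none_logged": None}


@dataclass(frozen=True)
class CycleBehavior:
    logged_libido: float | None
    logged_sex: float | None
    n_libido_days: int
    n_sex_log_days: int


def collapse_sex(code: str):
    """Collapse a daily sex code to binary had-sex; None when unlogged."""
    try:
        return _SEX_MAP[code]
    except KeyError:
        raise ValueError(f"unknown sex code {code!r}") from None


def cycle_score(values):
    """Average a cycle's daily values, ignoring missing (None/NaN) days.

    Returns None when nothing was logged: the drop-zero-days rule
    leaves no denominator, and the cycle is excluded from that model.
    """
    vals = [v for v in values if v is not None and not (isinstance(v, float) and np.isnan(v))]
    if not vals:
        return None
    return float(np.mean(vals))


def behavior_for_cycle(libido_values, sex_codes) -> CycleBehavior:
    libido_logged = [v for v in libido_values if v not in (0, None)]
    sex_binary = [collapse_sex(c) for c in sex_codes]
    sex_logged = [v for v in sex_binary if v is not None]
    return CycleBehavior(
        logged_libido=cycle_score(libido_logged),
        logged_sex=cycle_score(sex_logged),
        n_libido_days=len(libido_logged),
        n_sex_log_days=len(sex_logged),
    )


def aggregate_behavior(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-cycle behavior table from the daily-log frame.

    Returns columns user_id, cycle_id, logged_libido, logged_sex,
    n_libido_days, n_sex_log_days; scores are NaN when unlogged.
    """
    unknown = set(daily["sex"].unique()) - set(_SEX_MAP)
    if unknown:
        raise ValueError(f"unknown sex codes {sorted(unknown)}")
    work = pd.DataFrame(
        {
            "user_id": daily["user_id"],
            "cycle_id": daily["cycle_id"],
            "libido_val": daily["libido"].where(daily["libido"] > 0).astype(float),
            "sex_val": daily["sex"].map(
                {"unprotected": 1.0, "protected": 1.0, "no_sex": 0.0}
            ),
        }
    )
    g = work.groupby(["user_id", "cycle_id"], sort=True)
    out = g.agg(
        logged_libido=("libido_val", "mean"),
        logged_sex=("sex_val", "mean"),
        n_libido_days=("libido_val", "count"),
        n_sex_log_days=("sex_val", "count"),
    ).reset_index()
    return out[
        [
            "user_id",
            "cycle_id",
            "logged_libido",
            "logged_sex",
            "n_libido_days",
            "n_sex_log_days",
        ]
    ]
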