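"""Synthetic cycle-tracking cohort generator with known ground truth.

Real cycle-tracking app exports are private, so every downstream stage
is exercised on simulated cohorts whose statistical structure matches
what the analysis assumes and whose generating parameters are known
exactly.  Each user contributes 1-13 contiguous cycles of 15-40 days.
Per-cycle ovulation is drawn from a random-intercept logistic model

    logit p = b0 + u_user + b_age*age + b_bmi*bmi + b_len*len
              + b_dl*daylength(start) + equinox bump,

with ``u_user ~ N(0, sigma_user^2)``.  Ovulatory cycles receive a
biphasic basal-body-temperature trace: a follicular plateau followed by
a logistic-ramp luteal rise (drawn shift under 0.5 deg F, onset day
11-18, ramp spanning about two days) plus i.i.d. Gaussian measurement
noise; anovulatory cycles stay monophasic.  Daily fields are masked
independently at the configured logging sparsities, and LH tests, when
a cycle has them, are positive the day before the true shift day for
ovulatory cycles.

Ambient temperature is simulated as a hemisphere-aware sinusoid of
day-of-year plus noise, so it is seasonally correlated with day length
the way station weather would be.

Reproducibility: one seed; each user gets an independent substream
keyed by ``(seed, user index)``, so user k's data is identical whatever
``n_users`` is, and equal seed + config gives byte-identical CSVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .config import SimulationConfig
from .solar import (
    AUTUMN_EQUINOX_DOY,
    SPRING_EQUINOX_DOY,
    day_length_minutes_from_doy,
)

__all__ = ["GroundTruth", "generate_cohort", "write_cohort", "read_cohort"]

SEX_CODES = ("none_logged", "no_sex", "protected", "unprotected")
LH_CODES = ("none", "neg", "pos")
EVENT_CODES = ("none", "pregnancy", "miscarriage", "emergency_contraception")


@dataclass
class GroundTruth:
    """Generator-side truth for parameter-recovery checks.

    ``cycles`` has one row per cycle: the Bernoulli ovulation draw that
    shaped the BBT trace, the luteal shift-onset day, the linear
    predictor's probability, and the day length used.  ``betas`` is the
    true coefficient vector (day length in minutes).
    """

    user_intercepts: pd.DataFrame  # user_id, intercept
    cycles: pd.DataFrame  # user_id, cycle_id, ovulatory, shift_day, p_ovulate, day_length_min
    betas: dict
    sigma_user: float


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Inverse-CDF truncated normal draw (fast, stream-deterministic)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = rng.random(size)
    return mean + sd * ndtri(a + u * (b - a))


def _equinox_bump(doy, width):
    return np.exp(-0.5 * ((doy - SPRING_EQUINOX_DOY) / width) ** 2) + np.exp(
        -0.5 * ((doy - AUTUMN_EQUINOX_DOY) / width) ** 2
    )


def _ambient_temp(rng, lat, doy):
    """Seasonal sinusoid (deg C): warm mid-July north, mid-January south."""
    peak = np.where(lat >= 0, 196.0, 15.0)
    base = 25.0 - 0.4 * np.abs(lat)
    amp = 3.0 + 0.25 * np.abs(lat)
    t = base + amp * np.cos(2 * np.pi * (doy - peak) / 365.25)
    return t + rng.normal(0.0, 2.0, size=np.shape(doy))


def _day_of_year(dates64) -> np.ndarray:
    return (
        pd.DatetimeIndex(dates64).dayofyear.to_numpy().astype(float)
    )


def generate_cohort(config: SimulationConfig, make_daily: bool = True):
    """Draw a full cohort.

    Returns ``(users, cycles, daily, truth)``: three DataFrames in the
    users.csv / cycles.csv / daily_logs.csv schemas plus a
    :class:`GroundTruth`.

    ``make_daily=False`` skips synthesizing the per-day log frame and
    returns an empty ``daily``; user/cycle/truth draws are bit-identical
    either way (daily draws come last in each user's substream), so
    simulation studies that only consume cycle-level truth can use it
    without materializing hundreds of thousands of log rows.
    """
    config.validate()

    d0 = np.datetime64(str(config.start_date_window[0]))
    d1 = np.datetime64(str(config.start_date_window[1]))
    window_days = int((d1 - d0) / np.timedelta64(1, "D")) + 1

    users_rows = []
    intercepts = []
    # per-user numeric accumulators; string columns are built once at the end
    acc_cycle = {k: [] for k in ("start_date", "n_days", "event", "temp", "ovulatory",
                                 "shift_day", "p_ovulate", "day_length")}
    acc_daily = {k: [] for k in ("day_index", "date", "bbt", "deviation", "lh",
                                 "libido", "sex")}
    n_cycles_per_user = np.empty(config.n_users, dtype=int)
    n_days_per_user = np.empty(config.n_users, dtype=int)

    for u in range(config.n_users):
        rng = np.random.default_rng([int(config.seed) % (2**31), u])
        user_id = f"u{u:05d}"

        age = float(_truncated_normal(rng, 30.0, 7.0, *config.age_range, size=1)[0])
        bmi = float(_truncated_normal(rng, 25.0, 5.0, *config.bmi_range, size=1)[0])
        lat = float(rng.uniform(*config.latitude_range))
        lon = float(rng.uniform(*config.longitude_range))
        precondition = bool(rng.random() < config.p_precondition)
        region_missing = bool(rng.random() < config.p_missing_region)
        u_i = float(rng.normal(0.0, config.sigma_user))
        intercepts.append(u_i)

        lo, hi = config.cycles_per_user_range
        n_cycles = int(rng.integers(lo, hi + 1))
        lengths = np.rint(
            _truncated_normal(
                rng,
                config.cycle_length_mean,
                config.cycle_length_sd,
                15.0,
                40.0,
                size=n_cycles,
            )
        ).astype(int)

        first_start = d0 + np.timedelta64(int(rng.integers(0, window_days)), "D")
        starts = first_start + np.timedelta64(1, "D") * np.concatenate(
            ([0], np.cumsum(lengths[:-1]))
        )
        doy = _day_of_year(starts)
        day_len = day_length_minutes_from_doy(np.full(n_cycles, lat), doy)

        eta = (
            config.beta0
            + u_i
            + config.beta_age * age
            + config.beta_bmi * bmi
            + config.beta_cyclen * lengths
            + config.beta_daylength * day_len
            + config.equinox_peak_amplitude
            * _equinox_bump(doy, config.equinox_peak_width)
        )
        p_ov = expit(eta)
        ovulatory = rng.random(n_cycles) < p_ov

        shift_upper = np.minimum(18, lengths - 2)
        shift_day = rng.integers(11, shift_upper + 1)
        shift_day = np.where(ovulatory, shift_day, -1)

        events = np.where(
            rng.random(n_cycles) < config.event_rate,
            rng.choice([1, 2, 3], size=n_cycles, p=[0.4, 0.4, 0.2]),
            0,
        )
        temp_c = _ambient_temp(rng, lat, doy)
        temp_c = np.where(
            rng.random(n_cycles) < config.p_missing_temperature, np.nan, temp_c
        )

        n_cycles_per_user[u] = n_cycles
        n_days_per_user[u] = total = int(lengths.sum())
        acc_cycle["start_date"].append(starts)
        acc_cycle["n_days"].append(lengths)
        acc_cycle["event"].append(events)
        acc_cycle["temp"].append(np.round(temp_c, 2))
        acc_cycle["ovulatory"].append(ovulatory.astype(int))
        acc_cycle["shift_day"].append(shift_day)
        acc_cycle["p_ovulate"].append(p_ov)
        acc_cycle["day_length"].append(day_len)
        users_rows.append(
            {
                "user_id": user_id,
                "age": round(age, 2),
                "bmi_proxy": round(bmi, 2),
                "latitude": np.nan if region_missing else round(lat, 4),
                "longitude": np.nan if region_missing else round(lon, 4),
                "precondition_flag": int(precondition),
            }
        )
        if not make_daily:
            continue

        # --- daily traces, vectorized across this user's cycles ---
        day_index = np.concatenate([np.arange(1, L + 1) for L in lengths])
        dates = np.repeat(starts, lengths) + np.timedelta64(1, "D") * (day_index - 1)

        base = rng.normal(
            config.follicular_baseline_mean,
            config.follicular_baseline_sd,
            size=n_cycles,
        )
        shift_size = _truncated_normal(
            rng,
            config.luteal_shift_mean,
            config.luteal_shift_sd,
            0.05,
            0.5,
            size=n_cycles,
        )
        ramp = expit(3.0 * (day_index - (np.repeat(shift_day, lengths) + 0.5)))
        rise = np.where(
            np.repeat(ovulatory, lengths), np.repeat(shift_size, lengths) * ramp, 0.0
        )
        bbt = (
            np.repeat(base, lengths)
            + rise
            + rng.normal(0.0, config.bbt_noise_sd, size=total)
        )

        bbt_logged = rng.random(total) < config.p_bbt_logged
        deviation = bbt_logged & (rng.random(total) < config.deviation_rate)
        bbt_out = np.where(bbt_logged, bbt, np.nan)

        # behavioral logs carry user-level heterogeneity (a per-user libido
        # set-point and had-sex propensity), so the per-participant random
        # intercept of the behavior models is a real feature of the data
        libido_logged = rng.random(total) < config.p_libido_logged
        libido_mu = rng.normal(2.0, 0.5)
        libido_vals = np.clip(
            np.rint(libido_mu + rng.normal(0.0, 0.6, size=total)), 1, 3
        ).astype(int)
        libido = np.where(libido_logged, libido_vals, 0)

        sex_logged = rng.random(total) < config.p_sex_logged
        p_sex_u = rng.beta(3.0, 2.0)  # mean 0.6 had-sex share among logged days
        had_sex = rng.random(total) < p_sex_u
        unprotected = rng.random(total) < 0.42
        sex = np.where(
            sex_logged, np.where(had_sex, np.where(unprotected, 3, 2), 1), 0
        )

        lh = np.zeros(total, dtype=np.int8)  # codes into LH_CODES
        has_lh = rng.random(n_cycles) < config.p_lh_available
        offsets = np.concatenate(([0], np.cumsum(lengths[:-1])))
        for c in np.flatnonzero(has_lh):
            off = offsets[c]
            if ovulatory[c]:
                s = int(shift_day[c])
                for d in range(max(1, s - 4), s):
                    lh[off + d - 1] = 2 if d == s - 1 else 1
            else:
                for d in range(10, min(14, lengths[c]) + 1):
                    lh[off + d - 1] = 1

        acc_daily["day_index"].append(day_index)
        acc_daily["date"].append(dates)
        acc_daily["bbt"].append(np.round(bbt_out, 3))
        acc_daily["deviation"].append(deviation.astype(int))
        acc_daily["lh"].append(lh)
        acc_daily["libido"].append(libido.astype(int))
        acc_daily["sex"].append(sex.astype(np.int8))

    users = pd.DataFrame(users_rows)
    cat = {k: np.concatenate(v) for k, v in acc_cycle.items()}

    user_ids = users["user_id"].to_numpy()
    cyc_user = np.repeat(user_ids, n_cycles_per_user)
    within = np.concatenate([np.arange(1, n + 1) for n in n_cycles_per_user])
    cycle_ids = np.array(
        [f"{uid}_c{k:02d}" for uid, k in zip(cyc_user, within)], dtype=object
    )
    lengths_all = cat["n_days"]

    cycles = pd.DataFrame(
        {
            "user_id": cyc_user,
            "cycle_id": cycle_ids,
            "start_date": cat["start_date"],
            "n_days": lengths_all,
            "event": np.array(EVENT_CODES, dtype=object)[cat["event"]],
            "ambient_temp_c": cat["temp"],
        }
    )
    if make_daily:
        day = {k: np.concatenate(v) for k, v in acc_daily.items()}
        daily = pd.DataFrame(
            {
                "user_id": np.repeat(user_ids, n_days_per_user),
                "cycle_id": np.repeat(cycle_ids, lengths_all),
                "day_index": day["day_index"],
                "date": day["date"],
                "bbt_f": day["bbt"],
                "bbt_excluded_flag": day["deviation"],
                "lh_result": np.array(LH_CODES, dtype=object)[day["lh"]],
                "libido": day["libido"],
                "sex": np.array(SEX_CODES, dtype=object)[day["sex"]],
            }
        )
    else:
        daily = pd.DataFrame(
            columns=[
                "user_id",
                "cycle_id",
                "day_index",
                "date",
                "bbt_f",
                "bbt_excluded_flag",
                "lh_result",
                "libido",
                "sex",
            ]
        )
    truth = GroundTruth(
        user_intercepts=pd.DataFrame(
            {"user_id": users["user_id"], "intercept": intercepts}
        ),
        cycles=pd.DataFrame(
            {
                "user_id": cyc_user,
                "cycle_id": cycle_ids,
                "ovulatory": cat["ovulatory"],
                "shift_day": cat["shift_day"],
                "p_ovulate": cat["p_ovulate"],
                "day_length_min": cat["day_length"],
            }
        ),
        betas={
            "intercept": config.beta0,
            "age": config.beta_age,
            "bmi_proxy": config.beta_bmi,
            "cycle_length": config.beta_cyclen,
            "day_length": config.beta_daylength,
        },
        sigma_user=config.sigma_user,
    )
    return users, cycles, daily, truth


def write_cohort(users, cycles, daily, truth, out_dir) -> dict:
    """Write users.csv, cycles.csv, daily_logs.csv and truth.json.

    Returns a ``{name: path}`` map.  Output is byte-identical for equal
    inputs (fixed column order, ISO dates, default float repr).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    cycles = cycles.copy()
    cycles["start_date"] = pd.DatetimeIndex(cycles["start_date"]).strftime("%Y-%m-%d")
    daily = daily.copy()
    daily["date"] = pd.DatetimeIndex(daily["date"]).strftime("%Y-%m-%d")

    for name, df in (("users", users), ("cycles", cycles), ("daily_logs", daily)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    if truth is not None:
        p = out / "truth.json"
        payload = {
            "betas": truth.betas,
            "sigma_user": truth.sigma_user,
            "user_intercepts": dict(
                zip(truth.user_intercepts["user_id"], truth.user_intercepts["intercept"])
            ),
            "cycles": truth.cycles.to_dict(orient="records"),
        }
        p.write_text(json.dumps(payload, sort_keys=True))
        paths["truth"] = p
    return paths


def read_cohort(in_dir):
    """Read back the cohort CSVs written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    users = pd.read_csv(in_dir / "users.csv")
    cycles = pd.read_csv(in_dir / "cycles.csv", parse_dates=["start_date"])
    daily = pd.read_csv(in_dir / "daily_logs.csv", parse_dates=["date"])
    return users, cycles, daily
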