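"""Model-ready table assembly and the mixed-effects model suite.

One analysis row per retained cycle: covariates (age, BMI proxy,
cycle length in days, day length in minutes at the cycle start date,
ambient temperature in deg C at the cycle start) and six outcomes —
four binary ovulation labels (coverline, 3-over-6, NC-like, LH) and
two continuous behavior scores (logged libido, logged sex).  Binary
outcomes are fit with the in-package random-intercept logistic GLMM;
continuous outcomes with a random-intercept linear mixed model
(statsmodels MixedLM, ML).  P-values are two-sided Wald z-tests.

Four model variants mirror a target-plus-robustness design:

* ``target`` — age, BMI proxy, cycle length, day length;
* ``temperature`` — adds ambient temperature;
* ``fertile_age`` — restricts to ages 18-45 inclusive, keeping the
  temperature covariate;
* ``standardized`` — replaces day length in minutes by half-hour
  units (0-48), so its range matches the other covariates'.

The equinox check fits, by least squares, a constant plus Gaussian
bumps centered on the two equinoxes to the daily outcome rate as a
function of day-of-year, and reports R^2; it also compares outcome
levels between the 12 h / 11-13 h / other day-length strata with
two-proportion z-tests (binary) or Welch t-tests (continuous).
Missing outcomes are dropped listwise per outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .glmm import SeparationError, fit_logistic_ri
from .solar import (
    AUTUMN_EQUINOX_DOY,
    SPRING_EQUINOX_DOY,
    day_length_minutes_from_doy,
    equinox_stratum,
)

__all__ = [
    "VARIANTS",
    "BINARY_OUTCOMES",
    "CONTINUOUS_OUTCOMES",
    "FitResult",
    "EquinoxResult",
    "assemble_table",
    "variant_transform",
    "fit_binary_mixed_model",
    "fit_gaussian_mixed_model",
    "equinox_tests",
]

VARIANTS = ("target", "temperature", "fertile_age", "standardized")
BINARY_OUTCOMES = ("ovul_coverline", "ovul_3over6", "ovul_nc", "ovul_lh")
CONTINUOUS_OUTCOMES = ("logged_libido", "logged_sex")

_LABEL_TO_NUM = {"ovulatory": 1.0, "anovulatory": 0.0, "indeterminate": np.nan}
_METHOD_TO_COL = {
    "coverline": "ovul_coverline",
    "three_over_six": "ovul_3over6",
    "nc_like": "ovul_nc",
    "lh": "ovul_lh",
}


@dataclass
class FitResult:
    """Per-covariate estimates for one outcome under one model variant."""

    outcome: str
    variant: str
    terms: dict  # name -> {"b":, "se":, "p":}
    random_intercept_var: float
    n_users: int
    n_cycles: int
    converged: bool
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "variant": self.variant,
            "terms": {
                k: {kk: (None if vv is None or not np.isfinite(vv) else float(vv))
                    for kk, vv in v.items()}
                for k, v in self.terms.items()
            },
            "random_intercept_var": float(self.random_intercept_var),
            "n_users": self.n_users,
            "n_cycles": self.n_cycles,
            "converged": self.converged,
            "note": self.note,
        }


@dataclass
class EquinoxResult:
    outcome: str
    r2: float
    peak_params: dict
    strata: dict = field(default_factory=dict)  # label -> {"n":, "level":}
    pairwise_p: dict = field(default_factory=dict)  # "a_vs_b" -> p or None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "r2": float(self.r2),
            "peak_params": {k: float(v) for k, v in self.peak_params.items()},
            "strata": {
                k: {"n": int(v["n"]), "level": float(v["level"])}
                for k, v in self.strata.items()
            },
            "pairwise_p": {
                k: (None if v is None else float(v)) for k, v in self.pairwise_p.items()
            },
        }


def assemble_table(
    users: pd.DataFrame,
    retained_cycles: pd.DataFrame,
    calls: pd.DataFrame,
    behavior: pd.DataFrame,
    daylength_at: str = "start_date",
) -> pd.DataFrame:
    """Join all stages into one model-ready row per retained cycle.

    ``calls`` is the long ovulation_calls frame (user_id, cycle_id,
    method, label, evidence_day).  Day length is evaluated at the
    cycle start date (or averaged over the cycle span when
    ``daylength_at="cycle_mean"``).
    """
    rows = retained_cycles.merge(
        users[["user_id", "age", "bmi_proxy", "latitude", "longitude"]],
        on="user_id",
        how="left",
        validate="many_to_one",
    )
    missing = rows["age"].isna()
    if missing.any():
        bad = rows.loc[missing, "user_id"].unique()[:5]
        raise ValueError(f"cycles reference unknown users, e.g. {list(bad)}")

    start = pd.DatetimeIndex(rows["start_date"])
    doy = start.dayofyear.to_numpy().astype(float)
    lat = rows["latitude"].to_numpy(dtype=float)
    if daylength_at == "start_date":
        day_len = day_length_minutes_from_doy(lat, doy)
    elif daylength_at == "cycle_mean":
        n_days = rows["n_days"].to_numpy()
        day_len = np.array(
            [
                day_length_minutes_from_doy(
                    np.full(n, la),
                    ((d - 1 + np.arange(n)) % 365) + 1,
                ).mean()
                for la, d, n in zip(lat, doy, n_days)
            ]
        )
    else:
        raise ValueError(f"daylength_at={daylength_at!r} not recognized")

    out = pd.DataFrame(
        {
            "user_id": rows["user_id"],
            "cycle_id": rows["cycle_id"],
            "start_date": rows["start_date"],
            "day_of_year": doy.astype(int),
            "age": rows["age"].astype(float),
            "bmi_proxy": rows["bmi_proxy"].astype(float),
            "cycle_length": rows["n_days"].astype(float),
            "day_length": day_len,
            "day_length_halfhours": day_len / 30.0,
            "temperature": rows["ambient_temp_c"].astype(float),
        }
    )

    wide = (
        calls.assign(value=calls["label"].map(_LABEL_TO_NUM))
        .pivot_table(index="cycle_id", columns="method", values="value", dropna=False)
        .rename(columns=_METHOD_TO_COL)
    )
    out = out.merge(wide, left_on="cycle_id", right_index=True, how="left")
    for col in BINARY_OUTCOMES:
        if col not in out:
            out[col] = np.nan

    out = out.merge(
        behavior[["cycle_id", "logged_libido", "logged_sex"]],
        on="cycle_id",
        how="left",
    )
    return out


def variant_transform(rows: pd.DataFrame, variant: str):
    """Apply a model variant; returns (rows, covariate name list)."""
    base = ["age", "bmi_proxy", "cycle_length"]
    if variant == "target":
        return rows, base + ["day_length"]
    if variant == "temperature":
        return rows, base + ["day_length", "temperature"]
    if variant == "fertile_age":
        kept = rows[(rows["age"] >= 18.0) & (rows["age"] <= 45.0)]
        if kept.empty:
            raise ValueError("fertile_age restriction leaves no rows")
        return kept, base + ["day_length", "temperature"]
    if variant == "standardized":
        return rows, base + ["day_length_halfhours"]
    raise ValueError(f"unknown variant {variant!r}")


def _design(rows, outcome, covariates):
    cols = [outcome] + covariates
    df = rows.dropna(subset=cols)
    y = df[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates])
    names = ["intercept"] + list(covariates)
    return df, y, X, names


def fit_binary_mixed_model(
    rows: pd.DataFrame,
    outcome: str,
    covariates=None,
    variant: str = "target",
    n_quad: int = 25,
) -> FitResult:
    """Random-intercept logistic fit of a binary ovulation outcome."""
    rows, default_covs = variant_transform(rows, variant)
    covariates = list(covariates) if covariates is not None else default_covs
    df, y, X, names = _design(rows, outcome, covariates)
    if len(df) == 0:
        raise SeparationError(f"{outcome}: no non-missing rows to fit")
    if y.min() == y.max():
        raise SeparationError(
            f"{outcome}: outcome is single-class (all {int(y[0])})"
        )
    note = ""
    if df["user_id"].nunique() < 2:
        note = "single user: random-intercept variance not identified"
        warnings.warn(note)
    res = fit_logistic_ri(y, X, df["user_id"].to_numpy(), exog_names=names, n_quad=n_quad)
    terms = {
        nm: {"b": res.beta[j], "se": res.se[j], "p": res.pvalues[j]}
        for j, nm in enumerate(names)
    }
    return FitResult(
        outcome=outcome,
        variant=variant,
        terms=terms,
        random_intercept_var=res.sigma_u**2,
        n_users=int(df["user_id"].nunique()),
        n_cycles=len(df),
        converged=res.converged,
        note=note,
    )


def fit_gaussian_mixed_model(
    rows: pd.DataFrame,
    outcome: str,
    covariates=None,
    variant: str = "target",
) -> FitResult:
    """Random-intercept linear fit of a continuous behavior outcome."""
    import statsmodels.api as sm

    rows, default_covs = variant_transform(rows, variant)
    covariates = list(covariates) if covariates is not None else default_covs
    df, y, X, names = _design(rows, outcome, covariates)
    if len(df) == 0:
        raise ValueError(f"{outcome}: no non-missing rows to fit")

    if np.ptp(y) == 0.0:
        # constant outcome: slopes are zero, residual variance degenerate
        terms = {nm: {"b": (y[0] if nm == "intercept" else 0.0), "se": np.nan, "p": np.nan}
                 for nm in names}
        return FitResult(
            outcome=outcome,
            variant=variant,
            terms=terms,
            random_intercept_var=0.0,
            n_users=int(df["user_id"].nunique()),
            n_cycles=len(df),
            converged=False,
            note="constant outcome: residual variance ~0",
        )

    note = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=df["user_id"].to_numpy())
            fit = model.fit(reml=False)
        terms = {
            nm: {"b": fit.fe_params[j], "se": fit.bse_fe[j], "p": fit.pvalues[j]}
            for j, nm in enumerate(names)
        }
        re_var = float(np.asarray(fit.cov_re)[0, 0])
        converged = bool(fit.converged)
    except np.linalg.LinAlgError:
        # random-intercept variance on the zero boundary: the mixed model
        # collapses to ordinary least squares
        fit = sm.OLS(y, X).fit()
        terms = {
            nm: {"b": fit.params[j], "se": fit.bse[j], "p": fit.pvalues[j]}
            for j, nm in enumerate(names)
        }
        re_var = 0.0
        converged = True
        note = "random-intercept variance ~0; ordinary least squares fallback"
    return FitResult(
        outcome=outcome,
        variant=variant,
        terms=terms,
        random_intercept_var=re_var,
        n_users=int(df["user_id"].nunique()),
        n_cycles=len(df),
        converged=converged,
        note=note,
    )


def _peak_model(params, doy, width_bounds=None):
    c, a1, a2, s = params
    return (
        c
        + a1 * np.exp(-0.5 * ((doy - SPRING_EQUINOX_DOY) / s) ** 2)
        + a2 * np.exp(-0.5 * ((doy - AUTUMN_EQUINOX_DOY) / s) ** 2)
    )


def fit_equinox_peak_model(doy, level, weights=None):
    """Least-squares fit of constant + two equinox Gaussian bumps.

    ``level`` is the per-day-of-year outcome rate (or mean); returns
    (params dict, weighted R^2).
    """
    doy = np.asarray(doy, dtype=float)
    level = np.asarray(level, dtype=float)
    w = np.ones_like(level) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    def resid(params):
        return sw * (_peak_model(params, doy) - level)

    mean0 = float(np.average(level, weights=w))
    x0 = np.array([mean0, 0.0, 0.0, 15.0])
    fit = least_squares(
        resid,
        x0,
        bounds=([-np.inf, -np.inf, -np.inf, 2.0], [np.inf, np.inf, np.inf, 60.0]),
    )
    ss_res = float(np.sum(fit.fun**2))
    ss_tot = float(np.sum(w * (level - mean0) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    params = dict(zip(("constant", "amp_spring", "amp_autumn", "width_days"), fit.x))
    return params, r2


def equinox_tests(
    rows: pd.DataFrame, outcome: str, twelve_hour_tol: float = 5.0
) -> EquinoxResult:
    """Peak-model R^2 and day-length-stratum comparisons for one outcome."""
    from scipy.stats import ttest_ind
    from statsmodels.stats.proportion import proportions_ztest

    df = rows.dropna(subset=[outcome, "day_length", "day_of_year"])
    binary = outcome in BINARY_OUTCOMES

    by_doy = df.groupby("day_of_year")[outcome].agg(["mean", "size"])
    params, r2 = fit_equinox_peak_model(
        by_doy.index.to_numpy(), by_doy["mean"].to_numpy(), weights=by_doy["size"].to_numpy()
    )

    strata_labels = df["day_length"].map(
        lambda dl: equinox_stratum(dl, twelve_hour_tol=twelve_hour_tol)
    )
    strata = {}
    values = {}
    for label in ("twelve_hour", "near_equinox", "other"):
        v = df.loc[strata_labels == label, outcome].to_numpy(dtype=float)
        values[label] = v
        if v.size:
            strata[label] = {"n": int(v.size), "level": float(v.mean())}

    pairwise = {}
    pairs = (
        ("twelve_hour", "near_equinox"),
        ("twelve_hour", "other"),
        ("near_equinox", "other"),
    )
    for a, b in pairs:
        key = f"{a}_vs_{b}"
        va, vb = values[a], values[b]
        if va.size == 0 or vb.size == 0:
            pairwise[key] = None
            continue
        if binary:
            count = np.array([va.sum(), vb.sum()])
            nobs = np.array([va.size, vb.size])
            if np.all(count == nobs) or np.all(count == 0):
                pairwise[key] = 1.0  # identical degenerate proportions
            else:
                _, pval = proportions_ztest(count, nobs)
                pairwise[key] = float(pval)
        else:
            if va.size < 2 or vb.size < 2:
                pairwise[key] = None
            else:
                pairwise[key] = float(ttest_ind(va, vb, equal_var=False).pvalue)

    return EquinoxResult(
        outcome=outcome, r2=r2, peak_params=params, strata=strata, pairwise_p=pairwise
    )
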