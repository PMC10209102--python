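"""Run configuration: simulation and analysis parameter blocks.

A run is configured by two dataclasses.  :class:`SimulationConfig`
parameterizes the synthetic cohort generator — cohort composition,
logging sparsity, the biphasic BBT trace, and the ground-truth logistic
model for per-cycle ovulation.  :class:`AnalysisConfig` carries the
knobs of the downstream pipeline (detector thresholds, equinox-window
tolerance, quadrature order).  Both can be loaded from one YAML/JSON
file with top-level ``simulation:`` and ``analysis:`` keys.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["SimulationConfig", "AnalysisConfig", "load_config", "config_hash"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cycle-tracking cohort.

    Defaults emulate the cohort structure the analysis assumes: 1-13
    cycles per user, cycle lengths truncated to 15-40 days, BBT logged
    about 5 days out of 7, libido/sex daily logs present on only
    4%/18% of days, LH tests available for 31% of cycles, and a luteal
    BBT rise averaging under half a degree Fahrenheit.  Per-cycle
    ovulation is drawn from a random-intercept logistic model on age,
    BMI proxy, cycle length and day length (minutes at cycle start),
    plus an optional Gaussian bump at the equinoxes (0 = no
    equinox-specific effect).
    """

    n_users: int = 750
    cycles_per_user_range: tuple[int, int] = (1, 13)
    age_range: tuple[float, float] = (17.0, 64.0)
    bmi_range: tuple[float, float] = (13.0, 56.0)
    cycle_length_mean: float = 29.0
    cycle_length_sd: float = 3.5
    follicular_baseline_mean: float = 97.2  # deg F
    follicular_baseline_sd: float = 0.3
    luteal_shift_mean: float = 0.4  # deg F, < 0.5 by construction
    luteal_shift_sd: float = 0.07
    bbt_noise_sd: float = 0.1  # deg F per-day measurement noise
    p_bbt_logged: float = 5.0 / 7.0
    p_libido_logged: float = 0.04
    p_sex_logged: float = 0.18
    p_lh_available: float = 0.31  # per cycle
    beta0: float = 3.4
    beta_age: float = -0.02  # per year
    beta_bmi: float = -0.03  # per index unit
    beta_cyclen: float = -0.02  # per day
    beta_daylength: float = 0.001  # per minute of day length
    equinox_peak_amplitude: float = 0.0  # logit units; 0 = null
    equinox_peak_width: float = 15.0  # days (sd of the Gaussian bump)
    sigma_user: float = 0.5  # random-intercept sd, logit units
    latitude_range: tuple[float, float] = (25.0, 49.0)
    longitude_range: tuple[float, float] = (-124.0, -67.0)
    start_date_window: tuple[str, str] = ("2021-01-01", "2022-12-31")
    deviation_rate: float = 0.02  # illness/alcohol/sleep flags per logged day
    event_rate: float = 0.005  # pregnancy/miscarriage/EC events per cycle
    p_precondition: float = 0.02  # users with ovulation-disrupting preconditions
    p_missing_region: float = 0.01  # users without usable coordinates
    p_missing_temperature: float = 0.02  # cycles without ambient temperature
    seed: int = 0

    def validate(self) -> None:
        if self.n_users <= 0:
            raise ValueError("n_users must be positive")
        lo, hi = self.cycles_per_user_range
        if not (1 <= lo <= hi):
            raise ValueError("cycles_per_user_range must satisfy 1 <= min <= max")
        for name in (
            "p_bbt_logged",
            "p_libido_logged",
            "p_sex_logged",
            "p_lh_available",
            "deviation_rate",
            "event_rate",
            "p_precondition",
            "p_missing_region",
            "p_missing_temperature",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability")
        if self.luteal_shift_mean <= 0 or self.luteal_shift_mean >= 0.5:
            raise ValueError("luteal_shift_mean must lie in (0, 0.5) deg F")
        if self.cycle_length_sd < 0 or self.bbt_noise_sd < 0 or self.sigma_user < 0:
            raise ValueError("scale parameters must be non-negative")
        d0, d1 = (str(self.start_date_window[0]), str(self.start_date_window[1]))
        if d0 > d1:
            raise ValueError(f"degenerate start_date_window {self.start_date_window}")
        if not (-90 <= self.latitude_range[0] <= self.latitude_range[1] <= 90):
            raise ValueError("latitude_range must be ordered and within [-90, 90]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in (
            "cycles_per_user_range",
            "age_range",
            "bmi_range",
            "latitude_range",
            "longitude_range",
            "start_date_window",
        ):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the detection and inference stages."""

    coverline_offset: float = 0.15  # deg F added to the first-10-day max
    nc_tau: float = 0.15  # deg F luteal-consistency tolerance, NC-like detector
    nc_rise_margin: float = 0.15  # deg F rise above follicular mean, NC-like
    twelve_hour_tol_min: float = 5.0  # minutes around 720 for the 12 h stratum
    daylength_at: str = "start_date"  # or "cycle_mean"
    n_quad: int = 25  # Gauss-Hermite nodes for the logistic GLMM

    def validate(self) -> None:
        if self.daylength_at not in ("start_date", "cycle_mean"):
            raise ValueError(f"daylength_at={self.daylength_at!r} not recognized")
        if self.n_quad < 3:
            raise ValueError("n_quad must be at least 3")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path) -> tuple[SimulationConfig, AnalysisConfig]:
    """Load ``simulation:`` and ``analysis:`` blocks from a YAML/JSON file."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    sim = SimulationConfig.from_dict(data.get("simulation", {}))
    ana = AnalysisConfig.from_dict(data.get("analysis", {}))
    return sim, ana


def config_hash(sim: SimulationConfig, ana: AnalysisConfig) -> str:
    """Stable sha256 over the canonical JSON form of both config blocks."""
    import hashlib

    payload = json.dumps(
        {
            "simulation": dataclasses.asdict(sim),
            "analysis": dataclasses.asdict(ana),
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()
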