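"""End-to-end orchestration: simulate -> preprocess -> detect -> behavior
-> fit -> equinox, with plain-file handoff between stages.

Every stage reads and writes CSV/JSON artifacts in the run directory,
so each is independently testable from fixtures and re-running a stage
never mutates an upstream artifact.  A run manifest records the config
hash, seed, stage timings, output digests and the exclusion summary;
identical config + seed gives identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from .behavior import aggregate_behavior
from .config import AnalysisConfig, SimulationConfig, config_hash
from .detect import detect_all
from .inference import (
    BINARY_OUTCOMES,
    CONTINUOUS_OUTCOMES,
    VARIANTS,
    assemble_table,
    equinox_tests,
    fit_binary_mixed_model,
    fit_gaussian_mixed_model,
)
from .glmm import SeparationError
from .preprocess import apply_exclusions, complete_cycle_series
from .synthetic import generate_cohort, write_cohort

__all__ = ["run_all", "detect_cohort", "RunManifest"]


def detect_cohort(daily: pd.DataFrame, retained_cycles: pd.DataFrame, ana: AnalysisConfig):
    """Run all four detectors over the retained cycles.

    Returns the long ovulation_calls frame: one row per cycle per
    method with label and evidence day.
    """
    series_map = complete_cycle_series(daily, retained_cycles)
    lh_by_cycle = {
        cid: g.sort_values("day_index")["lh_result"].tolist()
        for cid, g in daily[daily["cycle_id"].isin(series_map)].groupby("cycle_id")
    }
    rows = []
    for row in retained_cycles.itertuples(index=False):
        calls = detect_all(
            series_map[row.cycle_id],
            lh_by_cycle.get(row.cycle_id, []),
            coverline_offset=ana.coverline_offset,
            nc_tau=ana.nc_tau,
            nc_rise_margin=ana.nc_rise_margin,
        )
        for method, call in calls.items():
            rows.append(
                {
                    "user_id": row.user_id,
                    "cycle_id": row.cycle_id,
                    "method": method,
                    "label": call.label,
                    "evidence_day": call.evidence_day,
                }
            )
    return pd.DataFrame(rows, columns=["user_id", "cycle_id", "method", "label", "evidence_day"])


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seconds: dict
    digests: dict
    exclusions: dict
    n_rows: int

    def to_dict(self):
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_all(
    sim: SimulationConfig,
    ana: AnalysisConfig,
    out_dir,
    seed: int | None = None,
    variants=VARIANTS,
    fit_models: bool = True,
) -> RunManifest:
    """Execute the full pipeline into ``out_dir``; returns the manifest."""
    sim = dataclasses.replace(sim, seed=int(seed) if seed is not None else sim.seed)
    sim.validate()
    ana.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, *a):
                timings[name] = round(time.perf_counter() - self_.t0, 3)

        return _T()

    with timed("simulate"):
        users, cycles, daily, truth = generate_cohort(sim)
        write_cohort(users, cycles, daily, truth, out)

    with timed("preprocess"):
        retained, excl = apply_exclusions(users, cycles, daily)
        _write_json(out / "exclusions.json", excl.to_dict())

    with timed("detect"):
        calls = detect_cohort(daily, retained, ana)
        calls.to_csv(out / "ovulation_calls.csv", index=False)

    with timed("behavior"):
        behav = aggregate_behavior(daily[daily["cycle_id"].isin(set(retained["cycle_id"]))])
        behav.to_csv(out / "behavior.csv", index=False)

    with timed("assemble"):
        rows = assemble_table(users, retained, calls, behav, daylength_at=ana.daylength_at)
        rows.to_csv(out / "analysis_rows.csv", index=False)

    results = {}
    if fit_models:
        with timed("fit"):
            for variant in variants:
                results[variant] = {}
                for outcome in BINARY_OUTCOMES:
                    try:
                        fr = fit_binary_mixed_model(
                            rows, outcome, variant=variant, n_quad=ana.n_quad
                        )
                        results[variant][outcome] = fr.to_dict()
                    except SeparationError as e:
                        results[variant][outcome] = {"error": str(e)}
                for outcome in CONTINUOUS_OUTCOMES:
                    try:
                        fr = fit_gaussian_mixed_model(rows, outcome, variant=variant)
                        results[variant][outcome] = fr.to_dict()
                    except ValueError as e:
                        results[variant][outcome] = {"error": str(e)}
            _write_json(out / "results.json", results)

        with timed("equinox"):
            eq = {}
            for outcome in ("ovul_3over6", "ovul_coverline", "logged_libido", "logged_sex"):
                eq[outcome] = equinox_tests(
                    rows, outcome, twelve_hour_tol=ana.twelve_hour_tol_min
                ).to_dict()
            _write_json(out / "equinox.json", eq)

    digests = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.suffix in (".csv", ".json") and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=config_hash(sim, ana),
        seed=sim.seed,
        stage_seconds=timings,
        digests=digests,
        exclusions=excl.to_dict(),
        n_rows=len(rows),
    )
    _write_json(out / "manifest.json", manifest.to_dict())
    return manifest
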