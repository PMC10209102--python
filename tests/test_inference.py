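"""Analysis-table assembly, model variants, mixed-model fits, equinox tests."""

import numpy as np
import pandas as pd
import pytest

from photocycle import SimulationConfig, generate_cohort
from photocycle.behavior import aggregate_behavior
from photocycle.config import AnalysisConfig
from photocycle.glmm import SeparationError
from photocycle.inference import (
    assemble_table,
    equinox_tests,
    fit_binary_mixed_model,
    fit_equinox_peak_model,
    fit_gaussian_mixed_model,
    variant_transform,
)
from photocycle.pipeline import detect_cohort
from photocycle.preprocess import apply_exclusions


@pytest.fixture(scope="module")
def assembled(small_cohort):
    _, users, cycles, daily, truth = small_cohort
    retained, log = apply_exclusions(users, cycles, daily)
    calls = detect_cohort(daily, retained, AnalysisConfig())
    behav = aggregate_behavior(daily)
    rows = assemble_table(users, retained, calls, behav)
    return users, cycles, retained, log, rows, truth


def _truth_rows(cfg_kwargs, seed):
    """Model-ready rows built from generator truth (no detection stage)."""
    cfg = SimulationConfig(seed=seed, **cfg_kwargs)
    users, cycles, _, truth = generate_cohort(cfg, make_daily=False)
    tc = truth.cycles.merge(users, on="user_id")
    return pd.DataFrame(
        {
            "user_id": tc["user_id"],
            "day_of_year": pd.DatetimeIndex(cycles["start_date"]).dayofyear,
            "age": tc["age"],
            "bmi_proxy": tc["bmi_proxy"],
            "cycle_length": cycles["n_days"].astype(float),
            "day_length": tc["day_length_min"],
            "day_length_halfhours": tc["day_length_min"] / 30.0,
            "temperature": cycles["ambient_temp_c"],
            "ovul_truth": tc["ovulatory"].astype(float),
        }
    )


class TestAssembleTable:
    def test_one_row_per_retained_cycle(self, assembled):
        _, _, retained, log, rows, _ = assembled
        assert len(rows) == log.n_retained == len(retained)

    def test_halfhours_is_day_length_over_30(self, assembled):
        rows = assembled[4]
        np.testing.assert_allclose(
            rows["day_length_halfhours"], rows["day_length"] / 30.0
        )
        assert rows["day_length_halfhours"].between(0, 48).all()

    def test_equinox_start_at_lat40_near_720(self):
        users = pd.DataFrame(
            {
                "user_id": ["u1"],
                "age": [30.0],
                "bmi_proxy": [24.0],
                "latitude": [40.0],
                "longitude": [-75.0],
                "precondition_flag": [0],
            }
        )
        cycles = pd.DataFrame(
            {
                "user_id": ["u1"],
                "cycle_id": ["c1"],
                "start_date": [pd.Timestamp("2022-03-20")],
                "n_days": [28],
                "event": ["none"],
                "ambient_temp_c": [10.0],
            }
        )
        calls = pd.DataFrame(
            {
                "user_id": ["u1"],
                "cycle_id": ["c1"],
                "method": ["lh"],
                "label": ["indeterminate"],
                "evidence_day": [None],
            }
        )
        behav = pd.DataFrame(
            {
                "user_id": ["u1"],
                "cycle_id": ["c1"],
                "logged_libido": [np.nan],
                "logged_sex": [np.nan],
                "n_libido_days": [0],
                "n_sex_log_days": [0],
            }
        )
        rows = assemble_table(users, cycles, calls, behav)
        assert rows["day_length"].iloc[0] == pytest.approx(720.0, abs=10.0)
        assert rows["day_length_halfhours"].iloc[0] == pytest.approx(24.0, abs=0.35)
        assert np.isnan(rows["ovul_lh"].iloc[0])

    def test_lh_missing_iff_no_tests(self, assembled, small_cohort):
        _, _, _, daily, _ = small_cohort
        rows = assembled[4]
        tested = set(daily.loc[daily["lh_result"] != "none", "cycle_id"])
        has_lh = rows["ovul_lh"].notna()
        assert set(rows.loc[has_lh, "cycle_id"]).issubset(tested)
        assert not set(rows.loc[~has_lh, "cycle_id"]) & tested


class TestVariantTransform:
    def test_target_is_identity(self, assembled):
        rows = assembled[4]
        out, covs = variant_transform(rows, "target")
        assert out is rows
        assert covs == ["age", "bmi_proxy", "cycle_length", "day_length"]

    def test_temperature_adds_covariate(self, assembled):
        _, covs = variant_transform(assembled[4], "temperature")
        assert covs[-1] == "temperature"

    def test_fertile_age_boundary(self):
        rows = pd.DataFrame(
            {"age": [17.9, 18.0, 45.0, 46.0], "x": range(4)}
        )
        kept, covs = variant_transform(rows, "fertile_age")
        assert list(kept["age"]) == [18.0, 45.0]
        assert "temperature" in covs

    def test_standardized_swaps_day_length(self, assembled):
        _, covs = variant_transform(assembled[4], "standardized")
        assert "day_length_halfhours" in covs and "day_length" not in covs

    def test_empty_restriction_errors(self):
        rows = pd.DataFrame({"age": [50.0, 60.0]})
        with pytest.raises(ValueError, match="no rows"):
            variant_transform(rows, "fertile_age")

    def test_unknown_variant_rejected(self, assembled):
        with pytest.raises(ValueError):
            variant_transform(assembled[4], "bootstrap")


class TestBinaryMixedModel:
    def test_recovers_planted_daylength_sign(self):
        rows = _truth_rows(dict(n_users=800, cycles_per_user_range=(8, 8)), seed=31)
        fr = fit_binary_mixed_model(rows, "ovul_truth", variant="target")
        term = fr.terms["day_length"]
        assert term["b"] > 0
        assert abs(term["b"] - 0.001) < 2 * term["se"]
        assert fr.converged
        assert fr.n_cycles == len(rows)

    def test_all_ones_outcome_errors(self, assembled):
        rows = assembled[4].copy()
        rows["ovul_3over6"] = 1.0
        with pytest.raises(SeparationError, match="ovul_3over6"):
            fit_binary_mixed_model(rows, "ovul_3over6", variant="target")

    def test_listwise_deletion_per_outcome(self, assembled):
        rows = assembled[4]
        fr = fit_binary_mixed_model(rows, "ovul_lh", variant="target")
        assert fr.n_cycles == rows["ovul_lh"].notna().sum() < len(rows)


class TestGaussianMixedModel:
    @staticmethod
    def _with_planted_sex_score(seed=41, slope=0.002):
        rows = _truth_rows(dict(n_users=250, cycles_per_user_range=(5, 5)), seed=seed)
        rng = np.random.default_rng(seed)
        uids, inv = np.unique(rows["user_id"], return_inverse=True)
        u = rng.normal(0, 0.05, len(uids))[inv]
        rows["logged_sex"] = np.clip(
            0.3 + slope * (rows["day_length"] - 720) + u + rng.normal(0, 0.1, len(rows)),
            0,
            1,
        )
        return rows

    def test_recovers_planted_positive_effect(self):
        rows = self._with_planted_sex_score()
        fr = fit_gaussian_mixed_model(rows, "logged_sex", variant="target")
        term = fr.terms["day_length"]
        assert term["b"] > 0
        assert term["p"] < 0.05

    def test_constant_outcome_flagged(self):
        rows = self._with_planted_sex_score()
        rows["logged_sex"] = 0.5
        fr = fit_gaussian_mixed_model(rows, "logged_sex", variant="target")
        assert not fr.converged
        assert "constant" in fr.note
        assert fr.terms["day_length"]["b"] == 0.0

    def test_dropping_missing_outcome_reduces_n(self, assembled):
        rows = assembled[4]
        fr = fit_gaussian_mixed_model(rows, "logged_libido", variant="target")
        assert fr.n_cycles == rows["logged_libido"].notna().sum() < len(rows)


class TestEquinox:
    def test_null_generator_gives_small_r2_and_flat_strata(self):
        rows = _truth_rows(
            dict(n_users=500, equinox_peak_amplitude=0.0), seed=17
        )
        res = equinox_tests(rows, "ovul_truth")
        assert res.r2 < 0.05
        ps = [p for p in res.pairwise_p.values() if p is not None]
        assert ps and min(ps) > 0.01  # no spurious stratum separation

    def test_planted_bump_lifts_r2_above_null(self):
        null_rows = _truth_rows(dict(n_users=500, equinox_peak_amplitude=0.0), seed=17)
        bump_rows = _truth_rows(dict(n_users=500, equinox_peak_amplitude=1.5), seed=17)
        r2_null = equinox_tests(null_rows, "ovul_truth").r2
        res = equinox_tests(bump_rows, "ovul_truth")
        assert res.r2 > max(0.05, 5 * r2_null)
        assert res.peak_params["amp_spring"] > 0
        assert res.peak_params["amp_autumn"] > 0

    def test_single_stratum_reports_absent_comparisons(self):
        rows = pd.DataFrame(
            {
                "user_id": ["u1"] * 40,
                "day_of_year": np.arange(1, 41),
                "day_length": np.full(40, 500.0),  # all 'other'
                "ovul_truth": np.tile([0.0, 1.0], 20),
            }
        )
        res = equinox_tests(rows, "ovul_truth")
        assert set(res.strata) == {"other"}
        assert all(p is None for p in res.pairwise_p.values())

    def test_peak_model_exact_on_noiseless_bump(self):
        doy = np.arange(1, 366)
        level = 0.8 + 0.1 * np.exp(-0.5 * ((doy - 79) / 15.0) ** 2)
        params, r2 = fit_equinox_peak_model(doy, level)
        assert r2 > 0.99
        assert params["amp_spring"] == pytest.approx(0.1, abs=0.01)
        assert params["amp_autumn"] == pytest.approx(0.0, abs=0.01)
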