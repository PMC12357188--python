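import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import logit

import candrift as cd
from candrift.scoring import CoefficientTable
from candrift.shift import RetrainError, flagged_by_category

prevalences = st.floats(0.01, 0.99)


class TestSmd:
    def test_equal_prevalences_give_zero(self):
        assert cd.smd_from_prevalences(0.4, 0.4) == 0.0

    def test_direct_formula_evaluation(self):
        # (0.6 - 0.5) / sqrt((0.25 + 0.24) / 2)
        expected = 0.1 / math.sqrt(0.245)
        assert cd.smd_from_prevalences(0.5, 0.6) == pytest.approx(expected)
        assert expected == pytest.approx(0.2020, abs=5e-4)

    @given(prevalences, prevalences)
    def test_antisymmetry(self, p_a, p_b):
        assert cd.smd_from_prevalences(p_a, p_b) == pytest.approx(
            -cd.smd_from_prevalences(p_b, p_a)
        )

    def test_degenerate_prevalences_return_zero(self):
        assert cd.smd_from_prevalences(0.0, 0.0) == 0.0
        assert cd.smd_from_prevalences(1.0, 1.0) == 0.0

    def test_panel_plug_in_matches_prevalence_formula(self):
        panel = pd.DataFrame(
            {
                "patient_id": np.arange(200),
                "year": [2016] * 100 + [2020] * 100,
                "x": [1] * 30 + [0] * 70 + [1] * 55 + [0] * 45,
                "outcome": 0,
            }
        )
        assert cd.smd(panel, "x", 2016, 2020) == pytest.approx(
            cd.smd_from_prevalences(0.3, 0.55)
        )

    def test_missing_covariate_fails(self):
        panel = pd.DataFrame({"patient_id": [1], "year": [2016], "outcome": [0]})
        with pytest.raises(KeyError):
            cd.smd(panel, "ghost", 2016, 2020)


class TestScreen:
    @staticmethod
    def _table(rows):
        frame = pd.DataFrame(
            rows, columns=["covariate", "category", "smd", "original_or"]
        )
        frame["flagged_by_smd"] = (frame["smd"] >= 0.1) | (frame["smd"] < -0.1)
        frame["flagged_by_or"] = (frame["original_or"] >= 1.5) | (
            frame["original_or"] < 0.5
        )
        frame["flagged"] = frame["flagged_by_smd"] | frame["flagged_by_or"]
        return frame

    def test_null_covariate_not_flagged(self):
        table = self._table([("x", "diagnostic", 0.0, 1.0)])
        assert cd.screen(table).empty

    def test_smd_only_flagging(self):
        table = self._table([("x", "utilization", 0.15, 1.0)])
        out = cd.screen(table)
        assert list(out["covariate"]) == ["x"]
        assert out["flagged_by_smd"].iloc[0] and not out["flagged_by_or"].iloc[0]

    def test_or_band_is_half_open(self):
        table = self._table(
            [("lo", "diagnostic", 0.0, 0.49), ("edge", "diagnostic", 0.0, 0.5),
             ("hi", "diagnostic", 0.0, 1.5)]
        )
        assert set(cd.screen(table)["covariate"]) == {"lo", "hi"}

    def test_sorted_by_absolute_smd_and_idempotent(self):
        table = self._table(
            [("a", "utilization", 0.12, 1.0), ("b", "laboratory_vitals", -0.3, 1.0),
             ("c", "demographic", 0.2, 1.0)]
        )
        out = cd.screen(table)
        assert list(out["covariate"]) == ["b", "c", "a"]
        pd.testing.assert_frame_equal(cd.screen(out), out)
        shuffled = table.sample(frac=1, random_state=0).reset_index(drop=True)
        assert list(cd.screen(shuffled)["covariate"]) == ["b", "c", "a"]


class TestShiftTableOnGeneratedCohort:
    def test_injected_shifts_recovered_within_tolerance(self, default_cohort):
        config, panel, truth = default_cohort
        table = cd.shift_table(panel, truth, 2016, 2020).set_index("covariate")
        baseline = {c.name: c.prevalence for c in config.covariates}
        shifted = {s.name: s.prevalence for s in config.shifts}
        for name, new_p in shifted.items():
            analytic = cd.smd_from_prevalences(baseline[name], new_p)
            assert table.loc[name, "smd"] == pytest.approx(analytic, abs=0.02)
        unshifted = set(baseline) - set(shifted)
        assert (table.loc[sorted(unshifted), "smd"].abs() < 0.02).all()


class TestRetrain:
    def test_intercept_only_model_is_logit_of_prevalence(self):
        config = cd.recovery_scenario(n_patients=20_000, seed=1)
        panel, truth = cd.generate_cohort(config)
        fit = cd.retrain(panel, 2016, exclude=truth.names)
        prevalence = panel["outcome"].mean()
        assert fit.intercept == pytest.approx(float(logit(prevalence)), abs=1e-6)
        assert fit.names == []

    def test_deterministic_to_ten_decimal_places(self):
        config = cd.recovery_scenario(n_patients=5000, seed=2)
        panel, _ = cd.generate_cohort(config)
        a = cd.retrain(panel, 2016)
        b = cd.retrain(panel, 2016)
        for name in a.names:
            assert abs(a.coefficients[name] - b.coefficients[name]) < 1e-10

    def test_rank_deficiency_names_collinear_column(self):
        config = cd.recovery_scenario(n_patients=2000, seed=3)
        panel, _ = cd.generate_cohort(config)
        panel = panel.copy()
        panel["x_dup"] = panel["x_demo"]
        with pytest.raises(RetrainError, match="x_dup"):
            cd.retrain(panel, 2016)

    def test_unknown_exclusion_fails(self):
        config = cd.recovery_scenario(n_patients=1000, seed=4)
        panel, _ = cd.generate_cohort(config)
        with pytest.raises(ValueError, match="ghost"):
            cd.retrain(panel, 2016, exclude=["ghost"])

    def test_sibling_levels_dropped_together(self):
        config = cd.default_scenario(n_patients=4000, seed=5)
        panel, truth = cd.generate_cohort(config)
        groups = {c.name: c.group for c in config.covariates if c.group}
        fit = cd.retrain(panel, 2016, exclude=["age_lt_55"],
                         covariates=truth.names, groups=groups)
        assert not any(name.startswith("age_") for name in fit.names)
        # with sibling dropping disabled only the named level leaves
        fit_single = cd.retrain(panel, 2016, exclude=["age_lt_55"],
                                covariates=truth.names, groups=groups,
                                drop_siblings=False)
        assert "age_55_64" in fit_single.names


@pytest.fixture(scope="module")
def prevalence_only_cohort():
    """Drift driven solely by a prevalence drop: no covariate shift."""
    base = cd.default_scenario(n_patients=40_000, seed=6)
    config = cd.SimConfig(
        n_patients=base.n_patients,
        years=base.years,
        covariates=base.covariates,
        coefficients=base.coefficients,
        intercept=base.intercept,
        shifts=(),
        prevalence_targets=base.prevalence_targets,
        frailty_sd=base.frailty_sd,
        seed=6,
    )
    return config, *cd.generate_cohort(config)


class TestAblationCompare:
    def test_original_variant_reproduces_main_drift_table(
        self, prevalence_only_cohort
    ):
        _, panel, truth = prevalence_only_cohort
        periods = [cd.DriftPeriod(2016, 2020)]
        table = cd.ablation_compare(panel, truth, periods, flagged=["chf"])
        original = table[table["variant"] == "original"]
        scored = cd.score_panel(panel, truth)
        by_year = cd.metrics_by_year_from_scored(scored, 90)
        for _, row in original.iterrows():
            expected = cd.drift(by_year, periods[0], row["metric"], 90)
            assert row["absolute_change_pp"] == pytest.approx(
                expected.absolute_change_pp, nan_ok=True
            )

    def test_ablation_does_not_alleviate_prevalence_driven_drift(
        self, prevalence_only_cohort
    ):
        # flag the high-OR covariates (the screen's OR arm) and retrain
        # without them: the PPV drift must persist, because the mechanism is
        # the outcome-prevalence drop, not any covariate
        _, panel, truth = prevalence_only_cohort
        quadrant = cd.shift_table(panel, truth, 2016, 2020)
        flagged = list(cd.screen(quadrant)["covariate"])
        assert flagged  # OR-flagged covariates exist by construction
        periods = [cd.DriftPeriod(2016, 2020)]
        table = cd.ablation_compare(panel, truth, periods, flagged=flagged)
        ppv = table[table["metric"] == "ppv"].set_index("variant")
        original = ppv.loc["original", "absolute_change_pp"]
        ablated = ppv.loc["retrain_excluding_flagged", "absolute_change_pp"]
        assert original < -0.5  # real downward drift
        assert ablated < original / 3  # exclusion does not remove it

    def test_per_category_exclusions_produce_one_table_each(
        self, prevalence_only_cohort
    ):
        _, panel, truth = prevalence_only_cohort
        quadrant = cd.shift_table(panel, truth, 2016, 2020)
        by_cat = flagged_by_category(cd.screen(quadrant))
        table = cd.ablation_compare(
            panel, truth, [cd.DriftPeriod(2016, 2020)], flagged=["chf"],
            extra_exclusions=by_cat,
        )
        for category in by_cat:
            assert f"retrain_excluding_{category}" in set(table["variant"])
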