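import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import chi2_contingency

import candrift as cd
from candrift.simulate import (
    CovariateSpec,
    ShiftSpec,
    SimConfig,
    UnreachablePrevalenceError,
)


def _minimal_config(**overrides):
    base = dict(
        n_patients=2000,
        years=[2016, 2017],
        covariates=(CovariateSpec("x", "diagnostic", 0.3),),
        coefficients={"x": 0.5},
        intercept=float(logit(0.1)),
        seed=1,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestConfigValidation:
    def test_years_must_be_strictly_increasing(self):
        with pytest.raises(ValueError):
            _minimal_config(years=[2017, 2016])

    def test_shift_must_reference_known_covariate(self):
        with pytest.raises(ValueError):
            _minimal_config(shifts=(ShiftSpec("ghost", 2017, 0.5),))

    def test_prevalence_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            CovariateSpec("x", "diagnostic", 1.0)

    def test_grouped_prevalences_must_leave_reference_mass(self):
        covs = (
            CovariateSpec("a", "demographic", 0.6, group="g"),
            CovariateSpec("b", "demographic", 0.5, group="g"),
        )
        with pytest.raises(ValueError):
            _minimal_config(covariates=covs, coefficients={})


class TestGenerateCohort:
    def test_identical_seed_gives_bit_identical_panel(self):
        config = cd.default_scenario(n_patients=1500, seed=9)
        panel_a, truth_a = cd.generate_cohort(config)
        panel_b, truth_b = cd.generate_cohort(config)
        pd.testing.assert_frame_equal(panel_a, panel_b)
        assert dict(truth_a.coefficients) == dict(truth_b.coefficients)

    def test_one_row_per_patient_per_year(self):
        config = _minimal_config()
        panel, _ = cd.generate_cohort(config)
        assert len(panel) == 2 * config.n_patients
        assert not panel.duplicated(["patient_id", "year"]).any()

    def test_null_model_prevalence_is_half(self):
        config = _minimal_config(
            n_patients=20_000, coefficients={"x": 0.0}, intercept=0.0
        )
        panel, _ = cd.generate_cohort(config)
        # binomial tolerance: 5 sigma at n = 40 000 rows
        assert panel["outcome"].mean() == pytest.approx(0.5, abs=5 * 0.5 / 200)

    def test_zero_coefficient_covariate_independent_of_outcome(self):
        rejections = 0
        for seed in range(20):
            config = _minimal_config(
                n_patients=5000, years=[2016], coefficients={"x": 0.0}, seed=seed
            )
            panel, _ = cd.generate_cohort(config)
            table = pd.crosstab(panel["x"], panel["outcome"])
            p = chi2_contingency(table)[1]
            rejections += p < 0.01
        # ~0.2 expected rejections at alpha = 0.01 over 20 seeds
        assert rejections <= 2

    def test_prevalence_targets_hit_within_two_per_mille(self):
        config = _minimal_config(
            n_patients=200_000,
            years=[2016, 2020],
            prevalence_targets={2016: 0.038, 2020: 0.030},
            frailty_sd=0.5,
        )
        panel, _ = cd.generate_cohort(config)
        realized = panel.groupby("year")["outcome"].mean()
        assert realized[2016] == pytest.approx(0.038, abs=0.002)
        assert realized[2020] == pytest.approx(0.030, abs=0.002)

    def test_unreachable_prevalence_target_reports_error(self):
        with pytest.raises(UnreachablePrevalenceError):
            cd.generate_cohort(
                _minimal_config(prevalence_targets={2016: 1e-25, 2017: 0.1})
            )

    def test_grouped_levels_are_mutually_exclusive(self):
        covs = (
            CovariateSpec("lvl_a", "demographic", 0.3, group="g"),
            CovariateSpec("lvl_b", "demographic", 0.4, group="g"),
        )
        config = _minimal_config(covariates=covs, coefficients={}, n_patients=5000)
        panel, _ = cd.generate_cohort(config)
        assert (panel["lvl_a"] + panel["lvl_b"]).max() <= 1
        assert panel["lvl_a"].mean() == pytest.approx(0.3, abs=0.02)

    def test_palliative_visit_positively_associated_with_risk(self):
        config = cd.default_scenario(n_patients=20_000, seed=3)
        panel, truth = cd.generate_cohort(config)
        scored = cd.compute_raw_probability(panel, truth)
        visited = scored.loc[scored["palliative_visit"] == 1, "raw_probability"]
        not_visited = scored.loc[scored["palliative_visit"] == 0, "raw_probability"]
        assert visited.mean() > not_visited.mean()


class TestFrailtyCorrelation:
    @staticmethod
    def _year_to_year_outcome_correlation(frailty_sd: float, seed: int) -> float:
        config = _minimal_config(
            n_patients=40_000,
            years=[2016, 2017],
            intercept=float(logit(0.3)),
            frailty_sd=frailty_sd,
            seed=seed,
        )
        panel, _ = cd.generate_cohort(config)
        wide = panel.pivot(index="patient_id", columns="year", values="outcome")
        return float(wide[2016].corr(wide[2017]))

    def test_frailty_induces_positive_within_individual_correlation(self):
        assert self._year_to_year_outcome_correlation(1.5, seed=5) > 0.05

    def test_no_frailty_gives_near_zero_correlation(self):
        assert abs(self._year_to_year_outcome_correlation(0.0, seed=5)) < 0.02


class TestDefaultScenario:
    def test_has_five_years_and_five_categories(self):
        config = cd.default_scenario()
        assert len(config.years) == 5
        categories = {c.category for c in config.covariates}
        assert categories == set(cd.scoring.CATEGORIES)
        assert len(config.covariates) >= 20

    def test_outcome_prevalence_declines_from_38_to_30_per_mille(self):
        config = cd.default_scenario()
        targets = [config.prevalence_targets[y] for y in config.years]
        assert targets[0] == 0.038 and targets[-1] == 0.030
        assert all(b < a for a, b in zip(targets, targets[1:]))

    def test_shifts_confined_to_final_two_years_and_spare_diag_pharm(self):
        config = cd.default_scenario()
        shift_years = {s.year for s in config.shifts}
        assert shift_years == set(config.years[-2:])
        category = {c.name: c.category for c in config.covariates}
        shifted_categories = {category[s.name] for s in config.shifts}
        assert "diagnostic" not in shifted_categories
        assert "pharmacy" not in shifted_categories

    def test_injected_shifts_have_analytic_smd_at_least_point_one(self):
        config = cd.default_scenario()
        baseline = {c.name: c.prevalence for c in config.covariates}
        for s in config.shifts:
            value = cd.smd_from_prevalences(baseline[s.name], s.prevalence)
            assert abs(value) >= 0.1
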