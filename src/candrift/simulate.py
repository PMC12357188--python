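"""Synthetic longitudinal cohorts with scripted temporal shifts.

No public release of the underlying national EHR panel exists, so the
pipeline is exercised on simulated cohorts that reproduce its statistical
structure: a fixed roster of patients scored once per year; ~5 categories of
binary covariate indicators (dummy levels with explicit reference groups);
a logistic outcome model with a per-patient latent frailty term that makes
repeated yearly outcomes positively correlated within individual; an
outcome-prevalence decline across years; and pandemic-style prevalence
shifts confined to utilization and laboratory/vital-sign indicators in the
final two years, while diagnosis and pharmacy indicators stay put.

Because the generator owns the ground truth (coefficients, injected shift
sizes, per-year outcome prevalence), every downstream estimate — refit
coefficients, standardized mean differences, drift in classification
metrics — can be checked against known values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .scoring import CATEGORIES, CoefficientTable


@dataclass(frozen=True)
class CovariateSpec:
    """One binary indicator: name, category, baseline prevalence.

    Covariates sharing a non-None ``group`` are mutually exclusive levels of
    one categorical (their prevalences must sum to < 1; the remainder is the
    implicit reference level).  Ungrouped covariates are independent
    Bernoulli draws.
    """

    name: str
    category: str
    prevalence: float
    group: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not in {CATEGORIES}"
            )
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")


@dataclass(frozen=True)
class ShiftSpec:
    """Override one covariate's prevalence in one scoring year."""

    name: str
    year: int
    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to generate one cohort reproducibly.

    Parameters
    ----------
    n_patients
        Roster size; every patient appears in every year.
    years
        Strictly increasing scoring years.
    covariates
        Indicator definitions (see :class:`CovariateSpec`).
    coefficients
        Ground-truth log-odds per covariate name.
    intercept
        Baseline log-odds intercept; overridden per year when
        ``prevalence_targets`` is given.
    shifts
        Per-year prevalence overrides.
    prevalence_targets
        Optional year -> target outcome prevalence; the intercept is
        recalibrated each year by root finding so the cohort's mean
        predicted probability equals the target.
    frailty_sd
        SD of the patient-level latent logit offset drawn once per patient
        and reused every year (induces within-individual outcome
        correlation).  0 disables it.
    visit_intercept, visit_slope
        Two-parameter logistic link from the outcome-model linear predictor
        to the probability of a palliative-care visit, so the visit flag is
        positively associated with true risk.
    seed
        Seed for all randomness in the generator.
    """

    n_patients: int
    years: Sequence[int]
    covariates: Sequence[CovariateSpec]
    coefficients: Mapping[str, float]
    intercept: float = -3.0
    shifts: Sequence[ShiftSpec] = field(default_factory=tuple)
    prevalence_targets: Mapping[int, float] | None = None
    frailty_sd: float = 0.0
    visit_intercept: float = -1.8
    visit_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        years = list(self.years)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        unknown = set(self.coefficients) - set(names)
        if unknown:
            raise ValueError(f"coefficients for unknown covariates: {sorted(unknown)}")
        for s in self.shifts:
            if s.name not in names:
                raise ValueError(f"shift references unknown covariate {s.name!r}")
            if s.year not in years:
                raise ValueError(f"shift references unknown year {s.year}")
        if self.prevalence_targets is not None:
            for year, p in self.prevalence_targets.items():
                if year not in years:
                    raise ValueError(f"prevalence target for unknown year {year}")
                if not 0.0 < p < 1.0:
                    raise ValueError(f"prevalence target must be in (0,1), got {p}")
        if self.frailty_sd < 0:
            raise ValueError("frailty_sd must be nonnegative")
        # grouped levels must leave room for a reference level
        totals: dict[str, float] = {}
        for c in self.covariates:
            if c.group is not None:
                totals[c.group] = totals.get(c.group, 0.0) + c.prevalence
        for group, total in totals.items():
            if total >= 1.0:
                raise ValueError(
                    f"grouped prevalences for {group!r} sum to {total} >= 1"
                )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    def coefficient_table(self) -> CoefficientTable:
        return CoefficientTable(
            intercept=self.intercept,
            coefficients={c.name: float(self.coefficients.get(c.name, 0.0))
                          for c in self.covariates},
            categories={c.name: c.category for c in self.covariates},
        )

    def prevalence_in_year(self, name: str, year: int) -> float:
        """Generating prevalence of a covariate in a year (shift-aware)."""
        for s in self.shifts:
            if s.name == name and s.year == year:
                return s.prevalence
        for c in self.covariates:
            if c.name == name:
                return c.prevalence
        raise KeyError(name)


class UnreachablePrevalenceError(RuntimeError):
    """Raised when no intercept can reach the requested outcome prevalence."""


def _calibrate_intercept(offset: np.ndarray, target: float) -> float:
    """Solve mean(expit(a + offset)) = target for the intercept ``a``."""

    def gap(a: float) -> float:
        return float(expit(a + offset).mean() - target)

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise UnreachablePrevalenceError(
            f"target prevalence {target} not reachable by intercept adjustment"
        )
    return float(brentq(gap, lo, hi, xtol=1e-12))


def _draw_covariates(
    rng: np.random.Generator,
    config: SimConfig,
    year: int,
) -> np.ndarray:
    """Indicator matrix (n_patients x n_covariates) for one year."""
    n = config.n_patients
    names = [c.name for c in config.covariates]
    X = np.zeros((n, len(names)), dtype=np.int64)
    col = {name: j for j, name in enumerate(names)}
    groups: dict[str, list[CovariateSpec]] = {}
    for c in config.covariates:
        if c.group is None:
            p = config.prevalence_in_year(c.name, year)
            X[:, col[c.name]] = rng.random(n) < p
        else:
            groups.setdefault(c.group, []).append(c)
    for members in groups.values():
        probs = [config.prevalence_in_year(c.name, year) for c in members]
        total = sum(probs)
        if total >= 1.0:
            raise ValueError("shifted grouped prevalences sum to >= 1")
        # categorical draw over levels + implicit reference
        u = rng.random(n)
        edges = np.cumsum(probs)
        level = np.searchsorted(edges, u)  # == len(members) -> reference
        for j, c in enumerate(members):
            X[:, col[c.name]] = level == j
    return X


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, CoefficientTable]:
    """Simulate the longitudinal panel and return it with its ground truth.

    One row per patient per year.  Each patient's frailty is drawn once and
    added to the logit every year; covariates are redrawn each year at that
    year's prevalence.  When prevalence targets are set, the intercept is
    recalibrated per year on the realized covariates and frailties, so the
    expected outcome prevalence matches the target exactly and the realized
    one differs only by binomial noise.

    Returns
    -------
    (panel, truth)
        ``panel`` is a long-format DataFrame with columns ``patient_id``,
        ``year``, one column per covariate, ``outcome`` and
        ``palliative_visit``.  ``truth`` is the generating
        :class:`~candrift.scoring.CoefficientTable` (baseline intercept).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    names = [c.name for c in config.covariates]
    beta = np.asarray([config.coefficients.get(name, 0.0) for name in names])
    frailty = (
        rng.normal(0.0, config.frailty_sd, size=n)
        if config.frailty_sd > 0
        else np.zeros(n)
    )
    patient_ids = np.arange(1, n + 1, dtype=np.int64)

    frames = []
    for year in config.years:
        X = _draw_covariates(rng, config, year)
        offset = X @ beta + frailty
        if config.prevalence_targets and year in config.prevalence_targets:
            intercept = _calibrate_intercept(offset, config.prevalence_targets[year])
        else:
            intercept = config.intercept
        linear = intercept + offset
        p_outcome = expit(linear)
        outcome = (rng.random(n) < p_outcome).astype(np.int64)
        p_visit = expit(config.visit_intercept + config.visit_slope * linear)
        visit = (rng.random(n) < p_visit).astype(np.int64)
        frame = pd.DataFrame({"patient_id": patient_ids, "year": year})
        for j, name in enumerate(names):
            frame[name] = X[:, j]
        frame["outcome"] = outcome
        frame["palliative_visit"] = visit
        frames.append(frame)

    panel = pd.concat(frames, ignore_index=True)
    return panel, config.coefficient_table()


# ---------------------------------------------------------------------------
# Default study scenario


def default_scenario(n_patients: int = 200_000, seed: int = 0) -> SimConfig:
    """The package's reference cohort scenario.

    Five scoring years; 22 indicators over the five covariate categories
    with an age categorical carried as mutually exclusive dummy levels;
    outcome prevalence declining linearly from 3.8% to 3.0%; and prevalence
    shifts injected into utilization and laboratory/vital-sign indicators
    (plus one demographic priority level) in the final two years, each with
    analytic |SMD| >= 0.1.  Diagnosis and pharmacy indicators keep their
    baseline prevalence throughout, mirroring the observed pattern that
    pandemic-era shifts concentrated in care-utilization and lab-measurement
    variables.
    """
    years = [2016, 2017, 2018, 2019, 2020]

    covs = [
        # demographic ------------------------------------------------------
        CovariateSpec("female", "demographic", 0.09),
        CovariateSpec("age_lt_55", "demographic", 0.25, group="age"),
        CovariateSpec("age_55_64", "demographic", 0.25, group="age"),
        CovariateSpec("age_65_74", "demographic", 0.30, group="age"),
        CovariateSpec("priority_low", "demographic", 0.40),
        # diagnostic (stable) ----------------------------------------------
        CovariateSpec("chf", "diagnostic", 0.05),
        CovariateSpec("dementia", "diagnostic", 0.04),
        CovariateSpec("metastatic_cancer", "diagnostic", 0.08),
        CovariateSpec("copd", "diagnostic", 0.12),
        # laboratory & vitals (shifted in final two years) -----------------
        CovariateSpec("albumin_normal", "laboratory_vitals", 0.55),
        CovariateSpec("bun_normal", "laboratory_vitals", 0.50),
        CovariateSpec("pulse_normal", "laboratory_vitals", 0.70),
        CovariateSpec("resp_normal", "laboratory_vitals", 0.75),
        CovariateSpec("bp_normal", "laboratory_vitals", 0.60),
        # pharmacy (stable) ------------------------------------------------
        CovariateSpec("opioid_rx", "pharmacy", 0.15),
        CovariateSpec("insulin_rx", "pharmacy", 0.08),
        CovariateSpec("diuretic_rx", "pharmacy", 0.18),
        CovariateSpec("anticoag_rx", "pharmacy", 0.07),
        # utilization (shifted in final two years) -------------------------
        CovariateSpec("admissions_0", "utilization", 0.90),
        CovariateSpec("bed_days_0", "utilization", 0.88),
        CovariateSpec("office_visits_high", "utilization", 0.30),
        CovariateSpec("telehealth_use", "utilization", 0.10),
    ]

    # ground-truth log-odds; protective "zero-utilization" levels get OR < 0.5
    coefficients = {
        "female": -0.10,
        "age_lt_55": -1.20,
        "age_55_64": -0.80,
        "age_65_74": -0.50,
        "priority_low": -0.20,
        "chf": math.log(2.2),
        "dementia": math.log(2.0),
        "metastatic_cancer": math.log(2.5),
        "copd": 0.35,
        "albumin_normal": -0.60,
        "bun_normal": -0.40,
        "pulse_normal": -0.30,
        "resp_normal": -0.30,
        "bp_normal": -0.20,
        "opioid_rx": 0.30,
        "insulin_rx": 0.25,
        "diuretic_rx": 0.30,
        "anticoag_rx": 0.35,
        "admissions_0": math.log(0.40),
        "bed_days_0": math.log(0.45),
        "office_visits_high": 0.25,
        "telehealth_use": 0.10,
    }

    # pandemic-style prevalence overrides for the final two years; every
    # injected |SMD| is >= 0.12 analytically (pooled-Bernoulli SD form)
    shifted = {
        "priority_low": 0.48,
        "albumin_normal": 0.47,
        "bun_normal": 0.43,
        "pulse_normal": 0.64,
        "resp_normal": 0.69,
        "bp_normal": 0.54,
        "admissions_0": 0.94,
        "bed_days_0": 0.92,
        "office_visits_high": 0.22,
        "telehealth_use": 0.30,
    }
    shifts = tuple(
        ShiftSpec(name, year, p)
        for name, p in shifted.items()
        for year in years[-2:]
    )

    prevalence_targets = {
        year: p for year, p in zip(years, (0.038, 0.036, 0.034, 0.032, 0.030))
    }

    return SimConfig(
        n_patients=n_patients,
        years=years,
        covariates=tuple(covs),
        coefficients=coefficients,
        intercept=float(logit(0.038)),
        shifts=shifts,
        prevalence_targets=prevalence_targets,
        frailty_sd=0.5,
        seed=seed,
    )


def recovery_scenario(n_patients: int = 100_000, seed: int = 0) -> SimConfig:
    """A single-year, frailty-free scenario sized for coefficient recovery.

    Moderate outcome prevalence (~30%) and common covariates keep every
    coefficient's maximum-likelihood standard error at n = 100 000 well
    below 0.02, so a refit can be required to land within +-0.05 log-odds of
    the truth.  At a 3-4% outcome prevalence the standard error of a rare
    indicator's coefficient is several times larger, which is why the
    reference scenario above is not used for recovery checks.
    """
    covs = [
        CovariateSpec("x_demo", "demographic", 0.40),
        CovariateSpec("x_diag_a", "diagnostic", 0.25),
        CovariateSpec("x_diag_b", "diagnostic", 0.30),
        CovariateSpec("x_lab", "laboratory_vitals", 0.50),
        CovariateSpec("x_pharm", "pharmacy", 0.35),
        CovariateSpec("x_util_a", "utilization", 0.45),
        CovariateSpec("x_util_b", "utilization", 0.20),
    ]
    coefficients = {
        "x_demo": -0.40,
        "x_diag_a": 0.70,
        "x_diag_b": 0.50,
        "x_lab": -0.60,
        "x_pharm": 0.30,
        "x_util_a": -0.50,
        "x_util_b": 0.80,
    }
    return SimConfig(
        n_patients=n_patients,
        years=[2016],
        covariates=tuple(covs),
        coefficients=coefficients,
        intercept=float(logit(0.30)),
        frailty_sd=0.0,
        seed=seed,
    )
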