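"""Covariate-shift screening and ablation retraining.

Distributional shift of each binary covariate between two scoring years is
measured by the standardized mean difference (SMD) of its prevalences,
using the pooled-Bernoulli-variance denominator standard in covariate
balance diagnostics.  Covariates with |SMD| >= 0.1, and/or with large
original effect sizes (odds ratio >= 1.5 or < 0.5), are screened as
candidate drift drivers.  The ablation then refits the logistic model on
the baseline year with flagged covariates removed and reruns the drift
analysis, to ask whether removing shifted inputs alleviates drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .drift import DriftPeriod, drift, metrics_by_year_from_scored
from .metrics import METRIC_NAMES
from .scoring import UNSPECIFIED, CoefficientTable, score_panel


def smd_from_prevalences(p_a: float, p_b: float) -> float:
    """Analytic SMD of two Bernoulli prevalences (later minus earlier).

    ``(p_b - p_a) / sqrt((p_a(1-p_a) + p_b(1-p_b)) / 2)``; defined as 0 when
    both variances vanish (both prevalences 0, or both 1).
    """
    var = (p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0
    if var == 0.0:
        return 0.0
    return (p_b - p_a) / float(np.sqrt(var))


def smd(panel: pd.DataFrame, covariate: str, year_a: int, year_b: int) -> float:
    """Plug-in SMD of a covariate's prevalence between two scoring years."""
    if covariate not in panel.columns:
        raise KeyError(f"covariate {covariate!r} not in panel")
    years = panel["year"]
    p = []
    for year in (year_a, year_b):
        mask = years == year
        if not mask.any():
            raise ValueError(f"year {year} not present in panel")
        p.append(float(panel.loc[mask, covariate].mean()))
    return smd_from_prevalences(p[0], p[1])


@dataclass(frozen=True)
class ShiftRecord:
    """One covariate's shift and effect-size screen result."""

    covariate: str
    category: str
    smd: float
    original_or: float
    flagged_by_smd: bool
    flagged_by_or: bool

    @property
    def flagged(self) -> bool:
        return self.flagged_by_smd or self.flagged_by_or


def shift_table(
    panel: pd.DataFrame,
    coefficients: CoefficientTable,
    year_a: int,
    year_b: int,
    smd_cut: float = 0.1,
    or_low: float = 0.5,
    or_high: float = 1.5,
) -> pd.DataFrame:
    """Per-covariate SMD vs original OR: the quadrant-plot table.

    One row per model covariate with its category, SMD between the two
    years, original odds ratio, and the screen flags.  This is the data
    behind the SMD-vs-OR quadrant display; rows outside the horizontal SMD
    band or the vertical OR band are candidate drift drivers.
    """
    odds = coefficients.odds_ratios()
    rows = []
    for name in coefficients.names:
        value = smd(panel, name, year_a, year_b)
        orr = float(odds[name])
        rows.append(
            {
                "covariate": name,
                "category": coefficients.category_of(name),
                "smd": value,
                "original_or": orr,
                "flagged_by_smd": bool(value >= smd_cut or value < -smd_cut),
                "flagged_by_or": bool(orr >= or_high or orr < or_low),
            }
        )
    table = pd.DataFrame(rows)
    table["flagged"] = table["flagged_by_smd"] | table["flagged_by_or"]
    return table


def screen(table: pd.DataFrame) -> pd.DataFrame:
    """Flagged subset of a shift table, sorted by |SMD| descending.

    Pure threshold function of the precomputed flags: permutation invariant
    and idempotent.
    """
    flagged = table.loc[table["flagged"]].copy()
    flagged = flagged.iloc[np.argsort(-flagged["smd"].abs().to_numpy(), kind="stable")]
    return flagged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Retraining


class RetrainError(RuntimeError):
    pass


def _expand_siblings(
    exclude: Iterable[str],
    groups: Mapping[str, str] | None,
) -> set[str]:
    """Dropping one dummy level of a categorical silently re-defines its
    reference, so by default all sibling levels leave together."""
    exclude = set(exclude)
    if not groups:
        return exclude
    hit_groups = {groups[name] for name in exclude if name in groups}
    for name, group in groups.items():
        if group in hit_groups:
            exclude.add(name)
    return exclude


def retrain(
    panel: pd.DataFrame,
    train_year: int,
    exclude: Iterable[str] = (),
    covariates: Sequence[str] | None = None,
    categories: Mapping[str, str] | None = None,
    groups: Mapping[str, str] | None = None,
    drop_siblings: bool = True,
) -> CoefficientTable:
    """Maximum-likelihood logistic refit on one year, minus excluded columns.

    Parameters
    ----------
    covariates
        Candidate design columns; defaults to every panel column that is
        not ``patient_id``/``year``/``outcome``/``palliative_visit``.
    categories
        Optional name -> category mapping carried into the result (refit
        coefficients default to the ``"unspecified"`` category).
    groups, drop_siblings
        Optional name -> group mapping of mutually exclusive dummy levels;
        when ``drop_siblings`` is True (default), excluding any level of a
        group excludes all its siblings.

    Convergence is by IRLS with relative log-likelihood tolerance 1e-8 and
    at most 100 iterations; the fit is deterministic.
    """
    reserved = {"patient_id", "year", "outcome", "palliative_visit",
                "raw_probability", "can_score"}
    if covariates is None:
        covariates = [c for c in panel.columns if c not in reserved]
    exclude = _expand_siblings(exclude, groups) if drop_siblings else set(exclude)
    unknown = exclude - set(covariates)
    if unknown:
        raise ValueError(f"excluded covariates not in panel: {sorted(unknown)}")
    keep = [c for c in covariates if c not in exclude]

    mask = panel["year"] == train_year
    if not mask.any():
        raise ValueError(f"train_year {train_year} not present in panel")
    y = panel.loc[mask, "outcome"].to_numpy(dtype=float)
    X = panel.loc[mask, keep].to_numpy(dtype=float) if keep else np.empty((mask.sum(), 0))
    design = np.column_stack([np.ones(len(y)), X])

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns via incremental rank checks
        bad = []
        base = design[:, :1]
        for j, name in enumerate(keep):
            cand = np.column_stack([base, design[:, j + 1]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(name)
            else:
                base = cand
        raise RetrainError(f"design matrix rank deficient; collinear columns: {bad}")

    try:
        model = sm.GLM(y, design, family=sm.families.Binomial())
        result = model.fit(maxiter=100, tol=1e-8, tol_criterion="deviance")
    except Exception as exc:  # pragma: no cover - statsmodels-internal failures
        raise RetrainError(f"logistic refit failed: {exc}") from exc
    if not result.converged:
        raise RetrainError("logistic refit did not converge within 100 iterations")

    params = np.asarray(result.params, dtype=float)
    categories = categories or {}
    return CoefficientTable(
        intercept=float(params[0]),
        coefficients=dict(zip(keep, params[1:])),
        categories={n: categories.get(n, UNSPECIFIED) for n in keep},
    )


# ---------------------------------------------------------------------------
# Ablation comparison


def _drift_table_for(
    panel: pd.DataFrame,
    coefficients: CoefficientTable,
    periods: Sequence[DriftPeriod],
    thresholds: Sequence[int],
) -> pd.DataFrame:
    scored = score_panel(panel, coefficients)
    rows = []
    for threshold in thresholds:
        by_year = metrics_by_year_from_scored(scored, threshold)
        for period in periods:
            for name in METRIC_NAMES:
                r = drift(by_year, period, name, threshold)
                rows.append(
                    {
                        "threshold": threshold,
                        "period": period.label,
                        "metric": name,
                        "baseline_pct": r.baseline_pct,
                        "final_pct": r.final_pct,
                        "absolute_change_pp": r.absolute_change_pp,
                    }
                )
    return pd.DataFrame(rows)


def ablation_compare(
    panel: pd.DataFrame,
    coefficients: CoefficientTable,
    periods: Sequence[DriftPeriod],
    flagged: Iterable[str],
    thresholds: Sequence[int] = (90,),
    train_year: int | None = None,
    full_retrain_years: Sequence[int] = (),
    groups: Mapping[str, str] | None = None,
    extra_exclusions: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Side-by-side drift tables for the ablation variants.

    Variants: the original fixed coefficients; a baseline-year refit with
    the flagged covariates excluded; optional full-covariate refits on
    later years; and optional named extra exclusion sets (e.g. one per
    covariate category).  Every variant runs the identical
    score -> percentile -> metrics -> drift pipeline, so the ``original``
    variant reproduces the main drift table exactly.
    """
    flagged = list(flagged)
    train_year = train_year if train_year is not None else min(
        p.baseline_year for p in periods
    )
    variants: dict[str, CoefficientTable] = {"original": coefficients}
    variants["retrain_excluding_flagged"] = retrain(
        panel,
        train_year,
        exclude=flagged,
        covariates=coefficients.names,
        categories=dict(coefficients.categories),
        groups=groups,
    )
    for year in full_retrain_years:
        variants[f"retrain_{year}_full"] = retrain(
            panel,
            year,
            covariates=coefficients.names,
            categories=dict(coefficients.categories),
        )
    for label, names in (extra_exclusions or {}).items():
        variants[f"retrain_excluding_{label}"] = retrain(
            panel,
            train_year,
            exclude=names,
            covariates=coefficients.names,
            categories=dict(coefficients.categories),
            groups=groups,
        )

    tables = []
    for label, table in variants.items():
        frame = _drift_table_for(panel, table, periods, thresholds)
        frame.insert(0, "variant", label)
        tables.append(frame)
    return pd.concat(tables, ignore_index=True)


def flagged_by_category(screened: pd.DataFrame) -> dict[str, list[str]]:
    """Flagged covariate names grouped by category, for per-category runs."""
    out: dict[str, list[str]] = {}
    for _, row in screened.iterrows():
        out.setdefault(row["category"], []).append(row["covariate"])
    return out
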