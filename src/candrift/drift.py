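"""Drift point estimates, affected-individual counts, and the
individual-level bootstrap.

Drift for a metric is the signed absolute change in percentage points
between a period's baseline and final scoring years (final minus baseline).
Confidence intervals come from bootstrap resampling *patients* with
replacement: a patient drawn k times contributes every one of their yearly
rows k times, which preserves within-individual correlation across repeated
longitudinal measures.  Model coefficients stay fixed across replicates
(the deployed algorithm is never refit), but the 0-99 percentile transform
is recomputed inside each replicate so the score always ranks the replicate
cohort itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES, MetricSet, compute_metrics, confusion
from .scoring import classify, to_percentile


@dataclass(frozen=True)
class DriftPeriod:
    """Baseline and final scoring years of one drift period."""

    baseline_year: int
    final_year: int

    def __post_init__(self) -> None:
        if self.baseline_year >= self.final_year:
            raise ValueError("baseline_year must precede final_year")

    @property
    def label(self) -> str:
        """Display convention: scoring years (outcome-measurement years)."""
        return (
            f"{self.baseline_year} to {self.final_year} "
            f"({self.baseline_year + 1}-{self.final_year + 1})"
        )


@dataclass(frozen=True)
class DriftResult:
    """Signed change of one metric over one period, in percentage points."""

    metric: str
    threshold_percentile: int
    period: DriftPeriod
    baseline_pct: float
    final_pct: float
    absolute_change_pp: float
    ci_lower_pp: float = math.nan
    ci_upper_pp: float = math.nan


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling design: patients per replicate, replicate count, seed.

    The deployed-scale analysis used 1 000 000 patients x 2000 replicates;
    the package default is a desk-scale 10 000 x 500.  Sampling fewer
    patients than the cohort holds makes the intervals conservatively wide.
    """

    n_individuals_per_replicate: int = 10_000
    n_replicates: int = 500
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_individuals_per_replicate <= 0 or self.n_replicates <= 0:
            raise ValueError("replicate sizes must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


def drift(
    metrics_by_year: Mapping[int, MetricSet],
    period: DriftPeriod,
    metric_name: str,
    threshold_percentile: int = 90,
) -> DriftResult:
    """Point estimate: metric(final year) - metric(baseline year), in pp."""
    if metric_name not in METRIC_NAMES:
        raise KeyError(metric_name)
    for year in (period.baseline_year, period.final_year):
        if year not in metrics_by_year:
            raise KeyError(f"no metrics for year {year}")
    baseline = metrics_by_year[period.baseline_year][metric_name] * 100.0
    final = metrics_by_year[period.final_year][metric_name] * 100.0
    return DriftResult(
        metric=metric_name,
        threshold_percentile=threshold_percentile,
        period=period,
        baseline_pct=baseline,
        final_pct=final,
        absolute_change_pp=final - baseline,
    )


def affected_counts(
    delta_tpr: float,
    delta_fpr: float,
    n_cases_final: int,
    n_controls_final: int,
) -> tuple[int, int]:
    """Individuals whose classification the drift implies changed.

    ``|delta TPR| x final-year cases`` and ``|delta FPR| x final-year
    controls``, rounded to whole persons.  Deltas are proportions, not
    percentage points.
    """
    if n_cases_final < 0 or n_controls_final < 0:
        raise ValueError("counts must be nonnegative")
    case_count = int(round(abs(delta_tpr) * n_cases_final))
    control_count = int(round(abs(delta_fpr) * n_controls_final))
    return case_count, control_count


# ---------------------------------------------------------------------------
# Individual-level bootstrap


class BootstrapUndefinedError(RuntimeError):
    """Raised when the statistic is undefined in too many replicates."""


def _patient_row_index(panel: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group row positions by patient: (row order, start offsets, lengths)."""
    codes, _ = pd.factorize(panel["patient_id"], sort=False)
    order = np.argsort(codes, kind="stable")
    counts = np.bincount(codes)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return order, starts, counts


def _resample_rows(
    order: np.ndarray,
    starts: np.ndarray,
    counts: np.ndarray,
    chosen: np.ndarray,
) -> np.ndarray:
    """Row positions for the chosen patients, whole patients at a time."""
    lens = counts[chosen]
    total = int(lens.sum())
    offsets = np.concatenate(([0], np.cumsum(lens)[:-1]))
    flat = np.arange(total)
    # position within each chosen patient's block, then into original rows
    within = flat - np.repeat(offsets, lens)
    return order[np.repeat(starts[chosen], lens) + within]


def bootstrap_ci(
    panel: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float | Mapping[str, float]],
    config: BootstrapConfig,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CIs with the patient as the resampling unit.

    Each replicate draws ``n_individuals_per_replicate`` patient ids with
    replacement and stacks *all* their yearly rows (k draws -> k copies of
    every row).  ``statistic`` may return a scalar or a mapping of named
    scalars; the CI per statistic is the (2.5th, 97.5th) percentile pair of
    its replicate distribution at the default 95% level.

    Raises
    ------
    BootstrapUndefinedError
        If the statistic is NaN in more than 10% of replicates.
    """
    if "patient_id" not in panel.columns:
        raise KeyError("panel needs a patient_id column")
    order, starts, counts = _patient_row_index(panel)
    n_patients = counts.size
    rng = np.random.default_rng(config.seed)

    draws: list[dict[str, float]] = []
    for _ in range(config.n_replicates):
        chosen = rng.integers(0, n_patients, size=config.n_individuals_per_replicate)
        rows = _resample_rows(order, starts, counts, chosen)
        value = statistic(panel.take(rows))
        if isinstance(value, Mapping):
            draws.append({k: float(v) for k, v in value.items()})
        else:
            draws.append({"statistic": float(value)})

    names = list(draws[0])
    alpha = 1.0 - config.ci_level
    out: dict[str, tuple[float, float]] = {}
    for name in names:
        values = np.asarray([d[name] for d in draws])
        n_bad = int(np.isnan(values).sum())
        if n_bad > 0.1 * config.n_replicates:
            raise BootstrapUndefinedError(
                f"statistic {name!r} undefined in {n_bad}/{config.n_replicates} "
                "replicates"
            )
        good = values[~np.isnan(values)]
        out[name] = (
            float(np.quantile(good, alpha / 2)),
            float(np.quantile(good, 1 - alpha / 2)),
        )
    return out


def metrics_by_year_from_scored(
    scored: pd.DataFrame, threshold_percentile: int
) -> dict[int, MetricSet]:
    """Six-metric set per scoring year at one percentile threshold."""
    flags = classify(scored, threshold_percentile)
    out: dict[int, MetricSet] = {}
    for year, idx in scored.groupby("year", sort=True).indices.items():
        c = confusion(
            flags[idx],
            scored["outcome"].to_numpy()[idx],
            year=int(year),
            threshold_percentile=threshold_percentile,
        )
        out[int(year)] = compute_metrics(c)
    return out


def drift_statistic(
    period: DriftPeriod,
    threshold_percentile: int,
    metric_names: tuple[str, ...] = METRIC_NAMES,
) -> Callable[[pd.DataFrame], dict[str, float]]:
    """Statistic factory for :func:`bootstrap_ci`: per-metric drift in pp.

    Expects a panel that already carries ``raw_probability`` (coefficients
    are fixed, so probabilities survive resampling); the percentile rank is
    recomputed within the replicate before metrics are taken.
    """

    def stat(sub: pd.DataFrame) -> dict[str, float]:
        ranked = to_percentile(sub)
        by_year = metrics_by_year_from_scored(ranked, threshold_percentile)
        out = {}
        for name in metric_names:
            out[name] = drift(by_year, period, name, threshold_percentile).absolute_change_pp
        return out

    return stat
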