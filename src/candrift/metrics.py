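"""Classification metrics for one scoring year at one percentile threshold.

Six metrics are tracked: true positive rate (sensitivity), false positive
rate (1 - specificity), positive and negative predictive values, F1 (the
harmonic mean of TPR and PPV) and accuracy, plus outcome prevalence.
Metrics with a zero denominator are *undefined* and reported as NaN, never
as 0 — a silent zero would fabricate drift downstream.

All ratio metrics are scale invariant, so a :class:`ConfusionSummary` may
hold either integer counts or printed proportions (e.g. a published
classification-rate table) and yield identical metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import rankdata

METRIC_NAMES = ("tpr", "fpr", "ppv", "npv", "f1", "accuracy", "prevalence")


@dataclass(frozen=True)
class ConfusionSummary:
    """Four-way classification tally for one year x threshold.

    ``tp``/``fp``/``tn``/``fn`` may be integer counts or nonnegative real
    pseudo-counts (proportions); only their ratios matter.
    """

    year: int
    threshold_percentile: int
    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n == 0:
            raise ValueError("empty confusion summary")

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    def proportions(self) -> dict[str, float]:
        return {k: getattr(self, k) / self.n for k in ("tp", "fp", "tn", "fn")}


@dataclass(frozen=True)
class MetricSet:
    """The six performance metrics plus prevalence, as proportions in [0, 1].

    Undefined entries (zero denominator) are NaN.
    """

    tpr: float
    fpr: float
    ppv: float
    npv: float
    f1: float
    accuracy: float
    prevalence: float

    def __getitem__(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_percent(self, decimals: int | None = None) -> dict[str, float]:
        out = {k: self[k] * 100.0 for k in METRIC_NAMES}
        if decimals is not None:
            out = {k: round(v, decimals) for k, v in out.items()}
        return out


def confusion(
    flags: np.ndarray,
    outcomes: np.ndarray,
    year: int = 0,
    threshold_percentile: int = 0,
) -> ConfusionSummary:
    """Tally true/false positives/negatives from binary flag and outcome vectors."""
    flags = np.asarray(flags)
    outcomes = np.asarray(outcomes)
    if flags.shape != outcomes.shape:
        raise ValueError("flags and outcomes must have equal length")
    if flags.size == 0:
        raise ValueError("empty input")
    for name, arr in (("flags", flags), ("outcomes", outcomes)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    flags = flags.astype(bool)
    outcomes = outcomes.astype(bool)
    return ConfusionSummary(
        year=year,
        threshold_percentile=threshold_percentile,
        tp=int(np.sum(flags & outcomes)),
        fp=int(np.sum(flags & ~outcomes)),
        tn=int(np.sum(~flags & ~outcomes)),
        fn=int(np.sum(~flags & outcomes)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionSummary) -> MetricSet:
    """Derive the metric set from a confusion tally (counts or proportions)."""
    tpr = _ratio(c.tp, c.tp + c.fn)
    fpr = _ratio(c.fp, c.fp + c.tn)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    # 2tp/(2tp+fp+fn) is the harmonic mean of TPR and PPV whenever tp > 0,
    # and stays well defined when one of them is 0/0.
    f1 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    accuracy = _ratio(c.tp + c.tn, c.n)
    prevalence = _ratio(c.tp + c.fn, c.n)
    return MetricSet(tpr, fpr, ppv, npv, f1, accuracy, prevalence)


def calibration_by_decile(
    probabilities: np.ndarray, outcomes: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Observed outcome rate vs mean predicted probability in risk deciles.

    Rows are sorted by predicted probability (ties broken by stable input
    order) and split into ``n_bins`` equal-count bins; bin sizes differ by at
    most one row.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    outcomes = np.asarray(outcomes)
    if probabilities.shape != outcomes.shape:
        raise ValueError("probabilities and outcomes must have equal length")
    if probabilities.size < n_bins:
        raise ValueError(f"need at least {n_bins} rows for {n_bins} bins")
    order = np.argsort(probabilities, kind="stable")
    rows = []
    for d, chunk in enumerate(np.array_split(order, n_bins)):
        rows.append(
            {
                "decile": d + 1,
                "n": chunk.size,
                "mean_predicted": float(probabilities[chunk].mean()),
                "observed_rate": float(np.asarray(outcomes)[chunk].mean()),
            }
        )
    return pd.DataFrame(rows)


def auc(probabilities: np.ndarray, outcomes: np.ndarray) -> float:
    """Rank-sum (Mann-Whitney) AUC: P(random case outranks random control).

    Ties get half credit.  NaN when only one class is present.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    outcomes = np.asarray(outcomes).astype(bool)
    n_cases = int(outcomes.sum())
    n_controls = outcomes.size - n_cases
    if n_cases == 0 or n_controls == 0:
        return math.nan
    ranks = rankdata(probabilities)  # average ranks -> half-credit ties
    rank_sum = float(ranks[outcomes].sum())
    return (rank_sum - n_cases * (n_cases + 1) / 2.0) / (n_cases * n_controls)


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial CI via beta-distribution quantiles."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper
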