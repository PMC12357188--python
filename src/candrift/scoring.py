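"""Fixed-coefficient logistic scoring and the 0-99 percentile (CAN) transform.

The deployed risk score applies a frozen logistic regression to a panel of
binary covariate indicators, then converts each scoring year's raw predicted
probabilities into integer percentile ranks 0-99.  Classification at a
percentile threshold (e.g. >= 90) flags the top fraction of patients as high
risk.  Coefficients are never refit here; see :mod:`candrift.shift` for
retraining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

#: The five covariate categories used throughout the analysis.
CATEGORIES = (
    "demographic",
    "diagnostic",
    "laboratory_vitals",
    "pharmacy",
    "utilization",
)

#: Sentinel category for refit coefficients whose provenance is unknown.
UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class CoefficientTable:
    """A frozen logistic model: intercept plus per-covariate log-odds.

    Parameters
    ----------
    intercept
        Model intercept on the log-odds scale.
    coefficients
        Mapping covariate name -> log-odds coefficient.
    categories
        Mapping covariate name -> category label (one of
        :data:`CATEGORIES`, or ``"unspecified"`` for refits).
    """

    intercept: float
    coefficients: Mapping[str, float]
    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.coefficients)
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        allowed = set(CATEGORIES) | {UNSPECIFIED}
        for name in names:
            cat = self.categories.get(name, UNSPECIFIED)
            if cat not in allowed:
                raise ValueError(
                    f"unknown category {cat!r} for covariate {name!r}; "
                    f"expected one of {sorted(allowed)}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.coefficients)

    def values(self) -> np.ndarray:
        return np.asarray([self.coefficients[n] for n in self.names], dtype=float)

    def category_of(self, name: str) -> str:
        return self.categories.get(name, UNSPECIFIED)

    def odds_ratios(self) -> pd.Series:
        """OR = exp(coefficient), indexed by covariate name."""
        return pd.Series(np.exp(self.values()), index=self.names, name="odds_ratio")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.names,
                "category": [self.category_of(n) for n in self.names],
                "coefficient": self.values(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        intercept_row = pd.DataFrame(
            {"covariate": ["(intercept)"], "category": [UNSPECIFIED],
             "coefficient": [self.intercept]}
        )
        pd.concat([intercept_row, frame], ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoefficientTable":
        frame = pd.read_csv(path, comment="#")
        required = {"covariate", "category", "coefficient"}
        if not required.issubset(frame.columns):
            raise ValueError(f"coefficient CSV needs columns {sorted(required)}")
        mask = frame["covariate"] == "(intercept)"
        if mask.sum() != 1:
            raise ValueError("coefficient CSV must contain exactly one (intercept) row")
        intercept = float(frame.loc[mask, "coefficient"].iloc[0])
        rest = frame.loc[~mask]
        return cls(
            intercept=intercept,
            coefficients=dict(zip(rest["covariate"], rest["coefficient"].astype(float))),
            categories=dict(zip(rest["covariate"], rest["category"])),
        )

    def replace(self, intercept: float | None = None) -> "CoefficientTable":
        return CoefficientTable(
            intercept=self.intercept if intercept is None else intercept,
            coefficients=dict(self.coefficients),
            categories=dict(self.categories),
        )


def _indicator_matrix(panel: pd.DataFrame, names: Iterable[str]) -> np.ndarray:
    names = list(names)
    missing = [n for n in names if n not in panel.columns]
    if missing:
        raise KeyError(f"covariates missing from panel: {missing}")
    X = panel[names].to_numpy(dtype=float)
    bad = ~np.isin(X, (0.0, 1.0))
    if bad.any():
        rows, cols = np.nonzero(bad)
        raise ValueError(
            f"non-binary covariate value in column {names[cols[0]]!r} "
            f"at row {int(rows[0])}"
        )
    return X


def compute_raw_probability(
    panel: pd.DataFrame, coefficients: CoefficientTable
) -> pd.DataFrame:
    """Add ``raw_probability`` = inverse-logit(intercept + X @ beta) per row.

    Every covariate named in *coefficients* must be present in *panel* as a
    fully dummy-encoded 0/1 column; missingness is expected to be encoded as
    explicit indicator levels upstream, so no imputation happens here.
    """
    X = _indicator_matrix(panel, coefficients.names)
    linear = coefficients.intercept + X @ coefficients.values()
    out = panel.copy()
    out["raw_probability"] = expit(linear)
    return out


def _percentile_scores(probabilities: np.ndarray) -> np.ndarray:
    n = probabilities.shape[0]
    # rankdata(method="min") - 1 == count of strictly smaller values; ties share.
    smaller = rankdata(probabilities, method="min") - 1
    return (100 * smaller) // n


def to_percentile(scored: pd.DataFrame, year_col: str = "year") -> pd.DataFrame:
    """Add integer ``can_score`` in 0-99, ranked within each scoring year.

    The score is ``floor(100 * (# rows with strictly smaller raw probability)
    / n_rows)`` computed separately per year, so cohort-size changes in one
    year cannot leak into another year's ranking.  Tied probabilities share a
    score.
    """
    if "raw_probability" not in scored.columns:
        raise KeyError("panel has no raw_probability column; score it first")
    if len(scored) == 0:
        raise ValueError("cannot rank an empty panel")
    out = scored.copy()
    out["can_score"] = (
        out.groupby(year_col, sort=False)["raw_probability"]
        .transform(lambda s: _percentile_scores(s.to_numpy()))
        .astype(np.int64)
    )
    return out


def classify(scored: pd.DataFrame, threshold_percentile: int) -> np.ndarray:
    """Binary high-risk flag: 1 iff ``can_score >= threshold`` (inclusive)."""
    if not 0 <= threshold_percentile <= 99:
        raise ValueError(f"threshold must be in [0, 99], got {threshold_percentile}")
    if "can_score" not in scored.columns:
        raise KeyError("panel has no can_score column; apply to_percentile first")
    return (scored["can_score"].to_numpy() >= threshold_percentile).astype(np.int64)


def score_panel(panel: pd.DataFrame, coefficients: CoefficientTable) -> pd.DataFrame:
    """Convenience: raw probabilities followed by the per-year percentile rank."""
    return to_percentile(compute_raw_probability(panel, coefficients))
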