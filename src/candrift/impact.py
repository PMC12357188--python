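"""Clinical-impact endpoints: reliability of a palliative-care quality metric.

The quality metric is the proportion of high-risk patients (score at or
above the percentile threshold) who received a palliative-care visit in the
year.  Two companion endpoints measure how drift erodes the metric's
denominator: the share of false positives among all flagged patients
(exactly 1 - PPV on the same rows), and the share of false positives among
flagged patients who received a visit.  Each endpoint carries a
Clopper-Pearson exact binomial CI and its numerator/denominator, so every
reported proportion is recomputable.
"""

from __future__ import annotations

import math

import pandas as pd

from .metrics import binomial_ci
from .scoring import classify

ENDPOINTS = ("quality_metric", "fp_share_flagged", "fp_share_flagged_with_visit")


def _endpoint_row(k: int, n: int) -> dict[str, float]:
    if n == 0:
        return {"value": math.nan, "ci_lower": math.nan, "ci_upper": math.nan,
                "numerator": k, "denominator": n}
    lo, hi = binomial_ci(k, n)
    return {"value": k / n, "ci_lower": lo, "ci_upper": hi,
            "numerator": k, "denominator": n}


def quality_endpoints(scored: pd.DataFrame, threshold_percentile: int) -> pd.DataFrame:
    """The three impact endpoints per scoring year at one threshold.

    Returns a tidy frame with one row per (year, endpoint):
    ``value`` (proportion), exact binomial ``ci_lower``/``ci_upper``, and
    the ``numerator``/``denominator`` pair behind it.
    """
    if "palliative_visit" not in scored.columns:
        raise KeyError("panel has no palliative_visit column")
    flags = classify(scored, threshold_percentile).astype(bool)
    rows = []
    for year, idx in scored.groupby("year", sort=True).indices.items():
        sub = scored.iloc[idx]
        flagged = sub[flags[idx]]
        n_flagged = len(flagged)
        if n_flagged == 0:
            raise ValueError(f"no flagged rows in year {year} at threshold "
                             f"{threshold_percentile}")
        visit = flagged["palliative_visit"].to_numpy().astype(bool)
        fp = flagged["outcome"].to_numpy() == 0
        measures = {
            "quality_metric": (int(visit.sum()), n_flagged),
            "fp_share_flagged": (int(fp.sum()), n_flagged),
            "fp_share_flagged_with_visit": (int((fp & visit).sum()), int(visit.sum())),
        }
        for endpoint, (k, n) in measures.items():
            rows.append(
                {"year": int(year), "threshold": threshold_percentile,
                 "endpoint": endpoint, **_endpoint_row(k, n)}
            )
    return pd.DataFrame(rows)


def impact_trend(
    scored: pd.DataFrame, thresholds: tuple[int, ...] = (90, 98, 99)
) -> pd.DataFrame:
    """Endpoints x years x thresholds, for trend tables across the study.

    Requires at least two scoring years; the primary threshold (90) is
    complemented by the operationally relevant 98th and 99th percentiles by
    default.
    """
    if scored["year"].nunique() < 2:
        raise ValueError("impact trend needs at least two scoring years")
    frames = [quality_endpoints(scored, t) for t in thresholds]
    return pd.concat(frames, ignore_index=True)
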