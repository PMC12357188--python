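"""Published operating characteristics of the deployed VA CAN v2.5 score.

Classification rates at the 90th percentile threshold and cohort totals, by
scoring year, as reported for the nationally deployed algorithm (scoring
years 2016-2020, outcomes measured the following year).  Rates are printed
percentages of the yearly cohort; because the performance metrics are
ratios, these proportions can be fed straight into
:func:`candrift.metrics.compute_metrics` as pseudo-counts.

These values are reference *inputs* (like a printed table), not outputs of
this package; they anchor the metric, drift and affected-count computations
to the deployed system's published operating point.
"""

from __future__ import annotations

import pandas as pd

from .metrics import ConfusionSummary

#: Printed classification rates (% of yearly cohort) at the CAN >= 90 cut.
CLASSIFICATION_RATES_PCT = pd.DataFrame(
    {
        "year": [2016, 2017, 2018, 2019, 2020],
        "tp": [1.82, 1.87, 1.84, 1.57, 1.42],
        "tn": [88.05, 87.98, 87.95, 88.43, 88.45],
        "fp": [8.17, 8.13, 8.15, 8.42, 8.57],
        "fn": [1.94, 2.01, 2.04, 1.56, 1.54],
        "outcome_prevalence": [3.76, 3.88, 3.89, 3.13, 2.97],
    }
).set_index("year")

#: Yearly cohort sizes (number of scored veterans).
COHORT_TOTALS = {
    2016: 5_583_397,
    2017: 5_600_275,
    2018: 5_519_660,
    2019: 5_594_791,
    2020: 5_489_029,
}

#: Reported net increase in false positives, 2016 -> 2020 scoring years.
REPORTED_INCREASED_FALSE_POSITIVES_2016_2020 = 18_288


def published_confusions(threshold_percentile: int = 90) -> dict[int, ConfusionSummary]:
    """Printed rate rows as proportion-valued :class:`ConfusionSummary` objects."""
    out = {}
    for year, row in CLASSIFICATION_RATES_PCT.iterrows():
        out[int(year)] = ConfusionSummary(
            year=int(year),
            threshold_percentile=threshold_percentile,
            tp=row["tp"] / 100.0,
            tn=row["tn"] / 100.0,
            fp=row["fp"] / 100.0,
            fn=row["fn"] / 100.0,
        )
    return out


def controls_in_year(year: int) -> int:
    """Final-year control count implied by the printed total and prevalence."""
    prevalence = CLASSIFICATION_RATES_PCT.loc[year, "outcome_prevalence"] / 100.0
    return int(round(COHORT_TOTALS[year] * (1.0 - prevalence)))


def cases_in_year(year: int) -> int:
    prevalence = CLASSIFICATION_RATES_PCT.loc[year, "outcome_prevalence"] / 100.0
    return int(round(COHORT_TOTALS[year] * prevalence))
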