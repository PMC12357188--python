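"""End-to-end orchestration: score -> metrics -> drift -> shift -> impact.

``run_all`` executes the whole analysis on one panel + coefficient table
and writes a report bundle: a cohort summary, a per-year classification
rate table with exact binomial CIs, per-year metric/calibration/AUC
tables, a drift table with bootstrap CIs and affected counts, the SMD-OR
shift quadrant table, the ablation comparison, the quality-impact trend,
and a machine-readable JSON holding every number at full precision.  Each
CSV is stamped with the configuration hash so any report line can be tied
back to the exact run that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .drift import (
    BootstrapConfig,
    affected_counts,
    bootstrap_ci,
    drift,
    drift_statistic,
    metrics_by_year_from_scored,
)
from .impact import impact_trend
from .io import RunConfig, covariate_columns, read_panel, write_panel
from .metrics import METRIC_NAMES, auc, binomial_ci, calibration_by_decile, confusion
from .scoring import CoefficientTable, classify, compute_raw_probability, to_percentile
from .shift import ablation_compare, screen, shift_table

logger = logging.getLogger(__name__)


def _year_label(year: int) -> str:
    """Scoring year (outcome-measurement year) display convention."""
    return f"{year} ({year + 1})"


def _write_csv(frame: pd.DataFrame, path: Path, config_hash: str) -> None:
    with path.open("w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, index=False)


def cohort_summary(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-year cohort size, outcome prevalence and covariate prevalences (%)."""
    rows = []
    for year, grp in panel.groupby("year", sort=True):
        row: dict[str, float] = {
            "year": int(year),
            "year_label": _year_label(int(year)),
            "n": len(grp),
            "outcome_prevalence_pct": 100.0 * grp["outcome"].mean(),
        }
        if "palliative_visit" in grp.columns:
            row["palliative_visit_pct"] = 100.0 * grp["palliative_visit"].mean()
        for cov in covariate_columns(panel):
            row[f"{cov}_pct"] = 100.0 * grp[cov].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def classification_rate_table(
    scored: pd.DataFrame, threshold_percentile: int
) -> pd.DataFrame:
    """Per-year TP/TN/FP/FN shares (%) with Clopper-Pearson CIs."""
    flags = classify(scored, threshold_percentile)
    rows = []
    for year, idx in scored.groupby("year", sort=True).indices.items():
        c = confusion(flags[idx], scored["outcome"].to_numpy()[idx],
                      year=int(year), threshold_percentile=threshold_percentile)
        row = {"year": int(year), "year_label": _year_label(int(year)),
               "threshold": threshold_percentile, "n": int(c.n)}
        for name in ("tp", "tn", "fp", "fn"):
            k = int(getattr(c, name))
            lo, hi = binomial_ci(k, int(c.n))
            row[f"{name}_pct"] = 100.0 * k / c.n
            row[f"{name}_ci_lower_pct"] = 100.0 * lo
            row[f"{name}_ci_upper_pct"] = 100.0 * hi
        k_out = int(c.tp + c.fn)
        lo, hi = binomial_ci(k_out, int(c.n))
        row["outcome_prevalence_pct"] = 100.0 * k_out / c.n
        row["outcome_prevalence_ci_lower_pct"] = 100.0 * lo
        row["outcome_prevalence_ci_upper_pct"] = 100.0 * hi
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_table(scored: pd.DataFrame, thresholds) -> pd.DataFrame:
    rows = []
    for threshold in thresholds:
        by_year = metrics_by_year_from_scored(scored, threshold)
        for year, mset in sorted(by_year.items()):
            row = {"year": year, "threshold": threshold}
            row.update({f"{k}_pct": v for k, v in mset.as_percent().items()})
            rows.append(row)
    return pd.DataFrame(rows)


def discrimination_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-year AUC and calibration-by-decile (supplementary metrics)."""
    rows = []
    for year, grp in scored.groupby("year", sort=True):
        probs = grp["raw_probability"].to_numpy()
        outcomes = grp["outcome"].to_numpy()
        value = auc(probs, outcomes)
        calib = calibration_by_decile(probs, outcomes)
        for _, crow in calib.iterrows():
            rows.append(
                {"year": int(year), "auc": value, "decile": int(crow["decile"]),
                 "n": int(crow["n"]),
                 "mean_predicted": crow["mean_predicted"],
                 "observed_rate": crow["observed_rate"]}
            )
    return pd.DataFrame(rows)


def drift_table(
    scored: pd.DataFrame,
    config: RunConfig,
    bootstrap: BootstrapConfig | None = None,
) -> pd.DataFrame:
    """Drift point estimates at the primary threshold, with bootstrap CIs
    and affected counts for TPR/FPR."""
    bootstrap = bootstrap or config.bootstrap
    threshold = config.primary_threshold
    by_year = metrics_by_year_from_scored(scored, threshold)
    rows = []
    for i, period in enumerate(config.periods):
        stat = drift_statistic(period, threshold)
        cis = bootstrap_ci(
            scored,
            stat,
            dataclasses.replace(bootstrap, seed=bootstrap.seed + i),
        )
        final = scored[scored["year"] == period.final_year]
        n_cases = int(final["outcome"].sum())
        n_controls = int(len(final) - n_cases)
        for name in METRIC_NAMES:
            r = drift(by_year, period, name, threshold)
            lo, hi = cis[name]
            row = {
                "period": period.label,
                "baseline_year": period.baseline_year,
                "final_year": period.final_year,
                "metric": name,
                "threshold": threshold,
                "baseline_pct": r.baseline_pct,
                "final_pct": r.final_pct,
                "absolute_change_pp": r.absolute_change_pp,
                "ci_lower_pp": lo,
                "ci_upper_pp": hi,
            }
            if name in ("tpr", "fpr"):
                delta = r.absolute_change_pp / 100.0
                cases, controls = affected_counts(
                    delta if name == "tpr" else 0.0,
                    delta if name == "fpr" else 0.0,
                    n_cases,
                    n_controls,
                )
                row["affected_count"] = cases if name == "tpr" else controls
            rows.append(row)
    return pd.DataFrame(rows)


def run_all(
    config: RunConfig,
    panel: pd.DataFrame | None = None,
    coefficients: CoefficientTable | None = None,
) -> dict:
    """Execute the full analysis and write the report bundle.

    ``panel`` / ``coefficients`` may be passed in-memory; otherwise they
    are read from the paths in *config*.  Returns the machine-readable
    results dict (also written to ``results.json``); identical
    seed/config give byte-identical JSON.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_hash = config.config_hash()
    logger.info("run_all: seed=%s config_hash=%s candrift=%s numpy=%s pandas=%s",
                config.seed, config_hash, __version__,
                np.__version__, pd.__version__)

    stage = "load"
    try:
        if panel is None:
            panel = read_panel(config.panel)
        if coefficients is None:
            coefficients = CoefficientTable.from_csv(config.coefficients)

        stage = "score"
        scored = to_percentile(compute_raw_probability(panel, coefficients))

        stage = "metrics"
        summary = cohort_summary(panel)
        rates = classification_rate_table(scored, config.primary_threshold)
        per_metric = metrics_table(scored, config.thresholds)
        discrimination = discrimination_table(scored)

        stage = "drift"
        drifts = drift_table(scored, config)

        stage = "shift"
        years = sorted(panel["year"].unique())
        quadrant = shift_table(panel, coefficients, int(years[0]), int(years[-1]),
                               smd_cut=config.smd_cut, or_low=config.or_low,
                               or_high=config.or_high)
        screened = screen(quadrant)

        stage = "ablation"
        ablation = None
        if config.run_ablation:
            ablation = ablation_compare(
                panel, coefficients, list(config.periods),
                flagged=list(screened["covariate"]),
                thresholds=(config.primary_threshold,),
                full_retrain_years=config.full_retrain_years,
            )

        stage = "impact"
        impact = None
        if "palliative_visit" in panel.columns:
            impact = impact_trend(scored)
        else:
            logger.warning("panel has no palliative_visit column; "
                           "impact stage skipped")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    # report bundle: rounded CSVs + full-precision JSON
    _write_csv(summary.round(2), out_dir / "cohort_summary.csv", config_hash)
    _write_csv(rates.round(2), out_dir / "classification_rates.csv", config_hash)
    _write_csv(per_metric.round(1), out_dir / "metrics_by_year.csv", config_hash)
    _write_csv(discrimination.round(4), out_dir / "calibration_auc.csv", config_hash)
    _write_csv(drifts.round(4), out_dir / "drift.csv", config_hash)
    _write_csv(quadrant.round(4), out_dir / "shift_quadrant.csv", config_hash)
    if ablation is not None:
        _write_csv(ablation.round(4), out_dir / "ablation.csv", config_hash)
    if impact is not None:
        _write_csv(impact.round(4), out_dir / "impact.csv", config_hash)
    write_panel(scored, out_dir / "scored_panel.csv", header_comment=f"config_hash={config_hash}")

    def _records(frame: pd.DataFrame | None):
        if frame is None:
            return None
        clean = frame.astype(object).where(frame.notna(), None)
        return clean.to_dict(orient="records")

    results = {
        "seed": config.seed,
        "config_hash": config_hash,
        "versions": {
            "candrift": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "cohort_summary": _records(summary),
        "classification_rates": _records(rates),
        "metrics_by_year": _records(per_metric),
        "calibration_auc": _records(discrimination),
        "drift": _records(drifts),
        "shift_quadrant": _records(quadrant),
        "ablation": _records(ablation),
        "impact": _records(impact),
    }
    with (out_dir / "results.json").open("w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, allow_nan=False)
    return results
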