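"""Panel and configuration I/O with schema validation.

A cohort panel is a long-format CSV: one row per patient-year with columns
``patient_id``, ``year``, one 0/1 column per covariate, a binary
``outcome``, and (optionally) a binary ``palliative_visit`` flag.
Validation is strict: duplicate (patient, year) rows and non-binary
indicator values are rejected with the offending location, because a
silently coerced panel would corrupt every downstream rate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .drift import BootstrapConfig, DriftPeriod

REQUIRED_COLUMNS = ("patient_id", "year", "outcome")
RESERVED_COLUMNS = set(REQUIRED_COLUMNS) | {"palliative_visit", "raw_probability",
                                            "can_score"}

DEFAULT_THRESHOLDS = (50, 70, 90, 95, 98, 99)


class PanelSchemaError(ValueError):
    pass


def covariate_columns(panel: pd.DataFrame) -> list[str]:
    return [c for c in panel.columns if c not in RESERVED_COLUMNS]


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check the panel contract; return the panel unchanged on success."""
    missing = [c for c in REQUIRED_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelSchemaError(f"panel missing required columns: {missing}")
    dup = panel.duplicated(subset=["patient_id", "year"])
    if dup.any():
        row = panel.loc[dup].iloc[0]
        raise PanelSchemaError(
            "duplicate (patient_id, year) row: "
            f"({row['patient_id']}, {row['year']})"
        )
    binary_cols = covariate_columns(panel) + ["outcome"]
    if "palliative_visit" in panel.columns:
        binary_cols.append("palliative_visit")
    for col in binary_cols:
        values = panel[col]
        bad = ~values.isin((0, 1))
        if bad.any():
            idx = int(bad.idxmax())
            raise PanelSchemaError(
                f"non-binary value {values.loc[idx]!r} in column {col!r} "
                f"at row {idx}"
            )
    return panel


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort panel CSV (``#`` lines are comments)."""
    panel = pd.read_csv(path, comment="#")
    return validate_panel(panel)


def write_panel(panel: pd.DataFrame, path: str | Path,
                header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        panel.to_csv(fh, index=False)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    ``panel`` and ``coefficients`` are file paths; ``output_dir`` receives
    the report bundle.  Defaults follow the primary analysis: 90th
    percentile as the main threshold with 50/70/95/98/99 sensitivity cuts,
    three drift periods, SMD cut 0.1 and OR band [0.5, 1.5) for the shift
    screen.
    """

    panel: str
    coefficients: str
    output_dir: str
    periods: Sequence[DriftPeriod] = ()
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS
    primary_threshold: int = 90
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    smd_cut: float = 0.1
    or_low: float = 0.5
    or_high: float = 1.5
    run_ablation: bool = True
    full_retrain_years: Sequence[int] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for t in tuple(self.thresholds) + (self.primary_threshold,):
            if not 0 <= t <= 99:
                raise ValueError(f"threshold {t} outside [0, 99]")

    def config_hash(self) -> str:
        """Stable short hash of the configuration, stamped on every output."""
        payload = {
            "panel": self.panel,
            "coefficients": self.coefficients,
            "periods": [(p.baseline_year, p.final_year) for p in self.periods],
            "thresholds": list(self.thresholds),
            "primary_threshold": self.primary_threshold,
            "bootstrap": [
                self.bootstrap.n_individuals_per_replicate,
                self.bootstrap.n_replicates,
                self.bootstrap.seed,
                self.bootstrap.ci_level,
            ],
            "smd_cut": self.smd_cut,
            "or_low": self.or_low,
            "or_high": self.or_high,
            "run_ablation": self.run_ablation,
            "full_retrain_years": list(self.full_retrain_years),
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        periods = tuple(
            DriftPeriod(int(p["baseline_year"]), int(p["final_year"]))
            for p in raw.get("periods", [])
        )
        bootstrap = BootstrapConfig(**raw.get("bootstrap", {}))
        kwargs = {
            k: raw[k]
            for k in (
                "panel", "coefficients", "output_dir", "thresholds",
                "primary_threshold", "smd_cut", "or_low", "or_high",
                "run_ablation", "full_retrain_years", "seed",
            )
            if k in raw
        }
        return cls(periods=periods, bootstrap=bootstrap, **kwargs)
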