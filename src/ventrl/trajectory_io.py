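"""Trajectory-table schema, validated I/O, and run configuration.

The pipeline operates on binned ICU time series: one row per
(stay_id, time_bin), where a time bin is a half-open 4-hour interval.
Bins are indexed 0..18 and cover -4 h to +72 h around ventilation
onset (bin 0 = [-4 h, 0 h)).  Besides the per-feature "data
fingerprint" columns, every row carries the raw ventilator settings
(set tidal volume in mL, PEEP in cmH2O, FiO2 in %), patient
demographics, event-boundary flags, and the stay-level outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ventrl")

#: number of 4-h bins in the analysis window (-4 h .. +72 h)
N_TIME_BINS = 19
#: index of the bin in which ventilation starts ([0 h, 4 h) is bin 1)
ONSET_BIN = 1

SETTING_COLUMNS = ("vt_set_ml", "peep_cmh2o", "fio2_pct")
EVENT_FLAG_COLUMNS = ("extubation", "niv_start", "suppl_o2", "withdrawal")
STATIC_COLUMNS = ("height_cm", "sex", "age_years", "outcome")
KEY_COLUMNS = ("stay_id", "time_bin")

OUTCOME_SURVIVED = "survived"
OUTCOME_DIED = "died"
SEXES = ("male", "female")


class SchemaError(ValueError):
    """A mandatory column is missing or mistyped."""


class IntegrityError(ValueError):
    """Row keys or per-stay invariants are violated."""


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str  # continuous | binary | ordinal
    aggregation: str  # mean | sum | last
    unit: str


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered list of time-series features forming the patient fingerprint.

    The default manifest below is a documented 44-feature stand-in
    (demograph-adjacent vitals, blood gases, chemistry, hematology,
    fluid balance and the Glasgow Coma Scale); any manifest with unique
    names may be substituted.
    """

    entries: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("manifest must contain at least one feature")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        for e in self.entries:
            if e.kind not in ("continuous", "binary", "ordinal"):
                raise ValueError(f"unknown feature kind {e.kind!r}")
            if e.aggregation not in ("mean", "sum", "last"):
                raise ValueError(f"unknown aggregation {e.aggregation!r}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def default(cls) -> "FeatureManifest":
        return DEFAULT_MANIFEST


def _vital(name: str, unit: str) -> FeatureSpec:
    return FeatureSpec(name, "continuous", "mean", unit)


def _fluid(name: str) -> FeatureSpec:
    return FeatureSpec(name, "continuous", "sum", "mL")


_DEFAULT_ENTRIES: tuple[FeatureSpec, ...] = (
    # vitals
    _vital("heart_rate", "bpm"),
    _vital("sbp", "mmHg"),
    _vital("dbp", "mmHg"),
    _vital("mean_bp", "mmHg"),
    _vital("resp_rate", "breaths/min"),
    _vital("spo2", "%"),
    _vital("temp_c", "degC"),
    _vital("cvp", "mmHg"),
    # blood gas / oxygenation
    _vital("ph_arterial", "pH"),
    _vital("pao2", "mmHg"),
    _vital("paco2", "mmHg"),
    _vital("hco3", "mEq/L"),
    _vital("base_excess", "mEq/L"),
    _vital("lactate", "mmol/L"),
    _vital("pao2_fio2_ratio", "mmHg"),
    _vital("sao2", "%"),
    # chemistry
    _vital("sodium", "mEq/L"),
    _vital("potassium", "mEq/L"),
    _vital("chloride", "mEq/L"),
    _vital("calcium", "mg/dL"),
    _vital("ionized_calcium", "mmol/L"),
    _vital("magnesium", "mg/dL"),
    _vital("phosphate", "mg/dL"),
    _vital("glucose", "mg/dL"),
    _vital("bun", "mg/dL"),
    _vital("creatinine", "mg/dL"),
    _vital("total_bilirubin", "mg/dL"),
    _vital("albumin", "g/dL"),
    _vital("alt", "IU/L"),
    _vital("ast", "IU/L"),
    # hematology / coagulation
    _vital("wbc", "K/uL"),
    _vital("hemoglobin", "g/dL"),
    _vital("hematocrit", "%"),
    _vital("platelets", "K/uL"),
    _vital("inr", "ratio"),
    _vital("pt", "s"),
    _vital("ptt", "s"),
    _vital("fibrinogen", "mg/dL"),
    # fluid balance (summed per bin)
    _fluid("fluid_input_4h"),
    _fluid("fluid_output_4h"),
    _fluid("urine_output_4h"),
    _fluid("cumulative_balance"),
    # scores / support
    FeatureSpec("gcs", "ordinal", "last", "points"),
    _vital("vasopressor_rate", "ug/kg/min"),
)

DEFAULT_MANIFEST = FeatureManifest(_DEFAULT_ENTRIES)
assert len(DEFAULT_MANIFEST) == 44


@dataclass
class TrajectoryTable:
    """Validated cohort table: one row per (stay_id, time_bin)."""

    df: pd.DataFrame
    manifest: FeatureManifest

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        required = (
            list(KEY_COLUMNS)
            + self.manifest.names
            + list(SETTING_COLUMNS)
            + list(STATIC_COLUMNS)
            + list(EVENT_FLAG_COLUMNS)
        )
        for col in required:
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column: {col}")
        if df.duplicated(subset=list(KEY_COLUMNS)).any():
            raise IntegrityError("duplicate (stay_id, time_bin) rows")
        # strictly increasing time bins within each stay
        tb = df.groupby("stay_id", sort=False)["time_bin"]
        if not (tb.diff().dropna() > 0).all():
            raise IntegrityError("time_bin must be strictly increasing within a stay")
        # one outcome per stay
        per_stay = df.groupby("stay_id")["outcome"].nunique(dropna=True)
        if (per_stay > 1).any():
            bad = per_stay[per_stay > 1].index[0]
            raise IntegrityError(f"stay {bad!r} has conflicting outcomes")
        bad_outcome = set(df["outcome"].dropna().unique()) - {OUTCOME_SURVIVED, OUTCOME_DIED}
        if bad_outcome:
            raise SchemaError(f"unknown outcome labels: {sorted(bad_outcome)}")
        for col in SETTING_COLUMNS:
            vals = pd.to_numeric(df[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise IntegrityError(f"negative values in {col}")

    @property
    def stay_ids(self) -> list:
        return list(self.df["stay_id"].unique())

    def stay(self, stay_id) -> pd.DataFrame:
        return self.df[self.df["stay_id"] == stay_id]

    def __len__(self) -> int:
        return len(self.df)


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str]) -> int:
    """Coerce columns to float in place; returns count of newly-missing cells."""
    n_bad = 0
    for col in columns:
        before = df[col].notna().sum() if col in df else 0
        df[col] = pd.to_numeric(df[col], errors="coerce")
        n_bad += int(before - df[col].notna().sum())
    return n_bad


def read_cohort(path: str | Path, manifest: FeatureManifest | None = None) -> TrajectoryTable:
    """Read a cohort table from delimited text (.csv) or parquet.

    Unparseable cells in numeric columns become missing (logged); schema
    violations raise :class:`SchemaError` / :class:`IntegrityError`.
    """
    manifest = manifest or DEFAULT_MANIFEST
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".parquet", ".pq"):
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    numeric = list(manifest.names) + list(SETTING_COLUMNS) + ["height_cm", "age_years"]
    numeric = [c for c in numeric if c in df.columns]
    n_bad = _coerce_numeric(df, numeric)
    if n_bad:
        logger.info("read_cohort: %d unparseable cells set to missing", n_bad)
    for col in EVENT_FLAG_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return TrajectoryTable(df=df.reset_index(drop=True), manifest=manifest)


def write_cohort(table: TrajectoryTable, path: str | Path) -> Path:
    """Write a cohort table as CSV or parquet by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".parquet", ".pq"):
        table.df.to_parquet(path, index=False)
    else:
        table.df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class RunConfig:
    """Resolved pipeline configuration with documented defaults.

    gamma            discount factor of the MDP (dimensionless, in (0, 1]).
    n_states         number of physiologic k-means states (terminal
                     survival/death states are appended on top).
    n_models         size of the model ensemble searched during selection.
    split fractions  per-model train / validation / test stay split.
    n_bootstrap      trajectory-bootstrap resamples for WIS bounds.
    select_level     lower-bound confidence level used for model selection.
    epsilon          softening mass spread over non-greedy eligible actions
                     when turning the greedy policy into a stochastic one.
    min_action_count minimum visits N(s, a) for an action to be eligible.
    hold_fallback    sample-and-hold limit (bins) for features too sparse
                     to estimate an inter-measurement interval.
    discard_threshold  maximum tolerated post-hold missing fraction.
    """

    gamma: float = 0.99
    n_states: int = 650
    n_models: int = 500
    train_frac: float = 0.6
    val_frac: float = 0.2
    test_frac: float = 0.2
    n_bootstrap: int = 1000
    select_level: float = 0.95
    report_levels: tuple[float, ...] = (0.90, 0.95)
    epsilon: float = 0.01
    min_action_count: int = 5
    hold_fallback: int = 2
    discard_threshold: float = 0.5
    imputation: str = "knn"  # knn | svd | mean
    knn_k: int = 3
    svd_rank: int | None = None
    tukey_k: float = 1.5
    estimator: str = "stepwise"  # stepwise | trajectory
    solver: str = "vi"  # vi | qlearn
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError(f"gamma must lie in (0, 1], got {self.gamma}")
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if not 0 < self.select_level < 1:
            raise ValueError("select_level must lie in (0, 1)")
        for lv in self.report_levels:
            if not 0 < lv < 1:
                raise ValueError("report levels must lie in (0, 1)")
        if self.n_states < 1 or self.n_models < 1:
            raise ValueError("n_states and n_models must be positive")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must lie in [0, 1)")
        if self.imputation not in ("knn", "svd", "mean"):
            raise ValueError(f"unknown imputation mode {self.imputation!r}")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML key-value config; unset keys take the documented defaults.

    The fully resolved configuration is echoed to the log.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain key-value pairs")
            data.update(loaded)
    data.update(overrides)
    valid = {f.name for f in fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "report_levels" in data:
        data["report_levels"] = tuple(data["report_levels"])
    cfg = RunConfig(**data)
    logger.info("resolved config: %s", cfg)
    return cfg


def with_overrides(cfg: RunConfig, **overrides) -> RunConfig:
    return replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# report writing

def _round_trip_json(obj):
    import json

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(f"not serializable: {type(o)}")

    return json.dumps(obj, indent=2, sort_keys=True, default=default)


def write_report(results: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write analysis artifacts to ``out_dir``.

    ``results`` maps artifact names to either DataFrames (written as CSV)
    or JSON-serializable objects (written as .json).  Returns the manifest
    of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            obj.to_csv(p, index=False)
        else:
            p = out_dir / f"{name}.json"
            p.write_text(_round_trip_json(obj))
        written[name] = p
        logger.info("wrote %s", p)
    return written
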