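"""Cohort preprocessing: ventilation-event definition, outlier removal,
sample-and-hold gap filling, imputation, and missingness diagnostics.

The raw table is turned into clean, fully imputed ventilation events:

1. univariate outlier removal per feature (Tukey fences, optionally a
   central-90% frequency filter) — flagged cells become missing;
2. ventilation-event definition from the documented ventilator settings
   and event flags, with cohort inclusion filters;
3. per-feature sample-and-hold with a hold limit estimated from the
   cohort's measurement frequency;
4. discard of events still >50% missing, then kNN (default), mean, or
   iterative low-rank SVD imputation of the remaining gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

from .trajectory_io import (
    N_TIME_BINS,
    ONSET_BIN,
    OUTCOME_DIED,
    OUTCOME_SURVIVED,
    FeatureManifest,
    RunConfig,
    TrajectoryTable,
)

logger = logging.getLogger("ventrl")

#: a setting documented within this many bins continues the event (8 h)
CONTINUATION_BINS = 2
#: minimum event duration: 24 h = 6 post-onset 4-h bins
MIN_EVENT_BINS = 6
MIN_AGE_YEARS = 18


@dataclass
class VentilationEvent:
    """One mechanical-ventilation event, clipped to the -4 h..+72 h window.

    ``features`` has one row per bin (manifest order); ``missing_mask``
    records pre-imputation missingness.  Settings arrays are aligned with
    ``bins`` and may contain NaN before hold/imputation.
    """

    stay_id: object
    onset_bin: int
    bins: np.ndarray  # absolute time-bin indices, increasing
    features: np.ndarray  # (n_bins, n_features)
    vt_set_ml: np.ndarray
    peep_cmh2o: np.ndarray
    fio2_pct: np.ndarray
    outcome: str
    ibw_kg: float
    missing_mask: np.ndarray = field(default=None)  # True where missing pre-imputation

    def __post_init__(self) -> None:
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.features)
        if self.outcome not in (OUTCOME_SURVIVED, OUTCOME_DIED):
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_post_onset_bins(self) -> int:
        return int(np.sum(self.bins >= self.onset_bin))

    @property
    def died(self) -> bool:
        return self.outcome == OUTCOME_DIED


def ideal_body_weight(sex: str, height_cm: float) -> float:
    """Predicted ideal body weight (kg) from sex and height.

    Male: 50 + 0.91 * (height_cm - 152.4); female intercept 45.5.
    """
    if not np.isfinite(height_cm) or height_cm <= 0:
        raise ValueError(f"height must be positive, got {height_cm}")
    if sex == "male":
        return 50.0 + 0.91 * (height_cm - 152.4)
    if sex == "female":
        return 45.5 + 0.91 * (height_cm - 152.4)
    raise ValueError(f"unknown sex {sex!r}")


# ---------------------------------------------------------------------------
# outlier filtering

def tukey_outlier_filter(
    values: np.ndarray, k: float = 1.5, frequency_interval: bool = False
) -> np.ndarray:
    """Mask of cells outside the Tukey fences [Q1 - k*IQR, Q3 + k*IQR].

    With ``frequency_interval`` the central 90% empirical interval is
    applied as an additional mask.  Missing cells are never flagged.
    """
    values = np.asarray(values, dtype=float)
    observed = values[~np.isnan(values)]
    flagged = np.zeros(values.shape, dtype=bool)
    if observed.size == 0:
        logger.warning("tukey filter: all-missing feature, no-op")
        return flagged
    if observed.size < 4:
        return flagged
    q1, q3 = np.percentile(observed, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    with np.errstate(invalid="ignore"):
        flagged = (values < lo) | (values > hi)
    if frequency_interval:
        p5, p95 = np.percentile(observed, [5, 95])
        with np.errstate(invalid="ignore"):
            flagged |= (values < p5) | (values > p95)
    flagged &= ~np.isnan(values)
    return flagged


def apply_outlier_filter(
    table: TrajectoryTable, k: float = 1.5, frequency_interval: bool = False
) -> TrajectoryTable:
    """Set outlying feature cells to missing, cohort-wide per feature."""
    df = table.df.copy()
    n_flagged = 0
    for name in table.manifest.names:
        mask = tukey_outlier_filter(df[name].to_numpy(float), k, frequency_interval)
        n_flagged += int(mask.sum())
        df.loc[mask, name] = np.nan
    logger.info("outlier filter flagged %d cells", n_flagged)
    return TrajectoryTable(df=df, manifest=table.manifest)


# ---------------------------------------------------------------------------
# event definition

def _first_event_window(stay: pd.DataFrame) -> tuple[int, int] | None:
    """Locate the first ventilation event in a single stay.

    Returns (onset_bin, end_bin) inclusive, in absolute bin indices, or
    None if the stay has no documented event.  The event starts at the
    first documented set tidal volume; it continues while any of the
    three settings is documented within CONTINUATION_BINS sample periods;
    extubation / NIV / supplemental-oxygen records end it.
    """
    bins = stay["time_bin"].to_numpy(int)
    vt = stay["vt_set_ml"].to_numpy(float)
    setting_present = (
        ~np.isnan(vt)
        | ~np.isnan(stay["peep_cmh2o"].to_numpy(float))
        | ~np.isnan(stay["fio2_pct"].to_numpy(float))
    )
    stop_flag = (
        stay["extubation"].to_numpy(bool)
        | stay["niv_start"].to_numpy(bool)
        | stay["suppl_o2"].to_numpy(bool)
    )
    onset_pos = None
    for i, v in enumerate(vt):
        if not np.isnan(v):
            onset_pos = i
            break
    if onset_pos is None:
        return None
    end_pos = onset_pos
    last_seen_bin = bins[onset_pos]
    for i in range(onset_pos + 1, len(bins)):
        if stop_flag[i]:
            break
        if bins[i] - last_seen_bin > CONTINUATION_BINS:
            break
        if setting_present[i]:
            last_seen_bin = bins[i]
            end_pos = i
    return bins[onset_pos], bins[end_pos]


def define_ventilation_events(table: TrajectoryTable) -> list[VentilationEvent]:
    """Extract the first qualifying ventilation event per stay.

    Inclusion filters: age > 18, no treatment-withdrawal flag inside the
    window, documented outcome, and duration of at least 24 h (6
    post-onset bins).  Stays failing a filter are dropped with a logged
    reason; the event is clipped to the -4 h..+72 h window.
    """
    events: list[VentilationEvent] = []
    drop_reasons: dict[str, int] = {}

    def drop(reason: str) -> None:
        drop_reasons[reason] = drop_reasons.get(reason, 0) + 1

    feat_names = table.manifest.names
    for stay_id, stay in table.df.groupby("stay_id", sort=False):
        window = _first_event_window(stay)
        if window is None:
            drop("no documented vt_set")
            continue
        onset, end = window
        end = min(end, N_TIME_BINS - 1)
        age = stay["age_years"].dropna()
        if len(age) == 0 or age.iloc[0] <= MIN_AGE_YEARS:
            drop("age <= 18 or undocumented")
            continue
        outcome = stay["outcome"].dropna()
        if len(outcome) == 0:
            drop("outcome undocumented")
            continue
        in_window = stay[(stay["time_bin"] >= max(0, onset - 1)) & (stay["time_bin"] <= end)]
        if in_window["withdrawal"].any():
            drop("treatment withdrawal in window")
            continue
        if end - onset + 1 < MIN_EVENT_BINS:
            drop("duration < 24 h")
            continue
        height = stay["height_cm"].dropna()
        sex = stay["sex"].dropna()
        if len(height) == 0 or len(sex) == 0:
            drop("height or sex undocumented")
            continue
        ibw = ideal_body_weight(sex.iloc[0], float(height.iloc[0]))
        sel = in_window
        bins = sel["time_bin"].to_numpy(int)
        events.append(
            VentilationEvent(
                stay_id=stay_id,
                onset_bin=int(onset),
                bins=bins,
                features=sel[feat_names].to_numpy(float),
                vt_set_ml=sel["vt_set_ml"].to_numpy(float),
                peep_cmh2o=sel["peep_cmh2o"].to_numpy(float),
                fio2_pct=sel["fio2_pct"].to_numpy(float),
                outcome=str(outcome.iloc[0]),
                ibw_kg=ibw,
            )
        )
    if drop_reasons:
        logger.info("event definition dropped stays: %s", drop_reasons)
    return events


# ---------------------------------------------------------------------------
# sample-and-hold

def estimate_hold_limits(
    table: TrajectoryTable, manifest: FeatureManifest | None = None, fallback: int = 2
) -> dict[str, int]:
    """Per-feature hold limit: median gap (bins) between consecutive
    observations within stays; features with fewer than two observations
    anywhere take the fallback limit."""
    if len(table.df) == 0:
        raise ValueError("empty table")
    manifest = manifest or table.manifest
    limits: dict[str, int] = {}
    grouped = list(table.df.groupby("stay_id", sort=False))
    for name in manifest.names:
        gaps: list[int] = []
        for _, stay in grouped:
            obs_bins = stay.loc[stay[name].notna(), "time_bin"].to_numpy(int)
            if len(obs_bins) >= 2:
                gaps.extend(np.diff(obs_bins).tolist())
        limits[name] = int(np.median(gaps)) if gaps else int(fallback)
    return limits


def sample_and_hold(series: np.ndarray, limit: int) -> np.ndarray:
    """Forward-propagate each observation for at most ``limit`` bins.

    Bins before the first observation stay missing.
    """
    if limit < 1:
        raise ValueError("hold limit must be >= 1")
    out = np.asarray(series, dtype=float).copy()
    last_val = np.nan
    last_idx = -np.inf
    for i in range(len(out)):
        if not np.isnan(out[i]):
            last_val, last_idx = out[i], i
        elif i - last_idx <= limit:
            out[i] = last_val
    return out


def hold_event(event: VentilationEvent, limits: dict[str, int], feat_names: list[str],
               setting_limit: int = CONTINUATION_BINS) -> VentilationEvent:
    """Apply sample-and-hold to features (per-feature limits) and to the
    ventilator settings (continuation-horizon limit)."""
    feats = event.features.copy()
    for j, name in enumerate(feat_names):
        feats[:, j] = sample_and_hold(feats[:, j], limits.get(name, setting_limit))
    return VentilationEvent(
        stay_id=event.stay_id,
        onset_bin=event.onset_bin,
        bins=event.bins,
        features=feats,
        vt_set_ml=sample_and_hold(event.vt_set_ml, setting_limit),
        peep_cmh2o=sample_and_hold(event.peep_cmh2o, setting_limit),
        fio2_pct=sample_and_hold(event.fio2_pct, setting_limit),
        outcome=event.outcome,
        ibw_kg=event.ibw_kg,
        missing_mask=np.isnan(feats),
    )


# ---------------------------------------------------------------------------
# imputation

def svd_complete(
    matrix: np.ndarray, rank: int, max_iter: int = 50, tol: float = 1e-4
) -> np.ndarray:
    """Iterative low-rank completion: mean-fill, truncated SVD, refill
    missing entries from the rank-``rank`` reconstruction, repeat until the
    relative change of imputed entries drops below ``tol``."""
    x = np.asarray(matrix, dtype=float).copy()
    missing = np.isnan(x)
    if not missing.any():
        return x
    col_means = np.nanmean(np.where(np.isnan(matrix), np.nan, matrix), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    x[missing] = np.broadcast_to(col_means, x.shape)[missing]
    prev = x[missing].copy()
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        r = min(rank, len(s))
        recon = (u[:, :r] * s[:r]) @ vt[:r]
        x[missing] = recon[missing]
        cur = x[missing]
        denom = np.linalg.norm(prev) or 1.0
        if np.linalg.norm(cur - prev) / denom < tol:
            break
        prev = cur.copy()
    return x


@dataclass
class ImputationDiagnostics:
    n_events_in: int
    n_events_discarded: int
    imputed_fraction_per_feature: dict[str, float]


def impute(
    events: list[VentilationEvent],
    manifest: FeatureManifest,
    method: str = "knn",
    knn_k: int = 3,
    svd_rank: int | None = None,
    discard_threshold: float = 0.5,
    knn_donor_cap: int = 2000,
) -> tuple[list[VentilationEvent], ImputationDiagnostics]:
    """Fill remaining gaps after sample-and-hold.

    Events whose post-hold missing fraction exceeds ``discard_threshold``
    are discarded.  ``knn`` imputes each missing cell from the k nearest
    rows (Euclidean distance over z-scored observed coordinates, pooled
    across the cohort), falling back to the column mean; ``svd`` runs
    iterative low-rank completion on the pooled matrix; ``mean`` is the
    plain column-mean fill.  Observed cells are never altered.

    Nearest-neighbor search against every cohort row is quadratic, so
    beyond ``knn_donor_cap`` rows the donor pool is a deterministic
    strided subsample of the cohort (queries still cover every row).
    """
    kept: list[VentilationEvent] = []
    n_discarded = 0
    for ev in events:
        frac = float(np.isnan(ev.features).mean())
        if frac > discard_threshold or frac == 1.0:
            n_discarded += 1
            logger.info("discarding event %s: %.0f%% missing", ev.stay_id, 100 * frac)
            continue
        kept.append(ev)
    if not kept:
        return [], ImputationDiagnostics(len(events), n_discarded, {})

    pooled = np.vstack([ev.features for ev in kept])
    missing = np.isnan(pooled)
    col_means = np.nanmean(pooled, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)

    if method == "mean":
        filled = pooled.copy()
        filled[missing] = np.broadcast_to(col_means, pooled.shape)[missing]
    elif method == "svd":
        d = pooled.shape[1]
        rank = svd_rank if svd_rank is not None else max(1, min(10, d // 4))
        filled = svd_complete(pooled, rank=rank)
    elif method == "knn":
        scale = np.nanstd(pooled, axis=0)
        scale = np.where((scale == 0) | np.isnan(scale), 1.0, scale)
        z = (pooled - col_means) / scale
        imputer = KNNImputer(n_neighbors=knn_k, weights="uniform")
        n_rows = z.shape[0]
        if n_rows > knn_donor_cap:
            stride = int(np.ceil(n_rows / knn_donor_cap))
            imputer.fit(z[::stride])
            out = imputer.transform(z)
        else:
            out = imputer.fit_transform(z)
        filled = out * scale + col_means
        if filled.shape[1] != pooled.shape[1]:  # all-missing columns dropped by sklearn
            filled_full = pooled.copy()
            keep_cols = ~np.all(missing, axis=0)
            filled_full[:, keep_cols] = filled
            filled_full[:, ~keep_cols] = 0.0
            filled = filled_full
        filled[~missing] = pooled[~missing]
    else:
        raise ValueError(f"unknown imputation method {method!r}")

    imputed_frac = {
        name: float(missing[:, j].mean()) for j, name in enumerate(manifest.names)
    }
    out: list[VentilationEvent] = []
    row = 0
    for ev in kept:
        n = ev.n_bins
        out.append(
            VentilationEvent(
                stay_id=ev.stay_id,
                onset_bin=ev.onset_bin,
                bins=ev.bins,
                features=filled[row : row + n],
                vt_set_ml=ev.vt_set_ml,
                peep_cmh2o=ev.peep_cmh2o,
                fio2_pct=ev.fio2_pct,
                outcome=ev.outcome,
                ibw_kg=ev.ibw_kg,
                missing_mask=ev.missing_mask,
            )
        )
        row += n
    assert not any(np.isnan(e.features).any() for e in out)
    return out, ImputationDiagnostics(len(events), n_discarded, imputed_frac)


# ---------------------------------------------------------------------------
# missingness diagnostic

def missingness_diagnostic(table: TrajectoryTable) -> pd.DataFrame:
    """Association between each feature's missingness and the rest of the data.

    For every feature with both missing and observed cells, each other
    feature's observed values are compared between missing and non-missing
    rows with a Mann-Whitney rank test; the per-feature p-value is the
    Bonferroni-corrected minimum over the other features.  Small p-values
    indicate missingness that depends on observed data (MAR rather than
    MCAR).  Fully observed (or fully missing) features are marked
    not-applicable with a NaN p-value.
    """
    names = table.manifest.names
    rows = []
    data = table.df[names]
    for name in names:
        miss = data[name].isna().to_numpy()
        if miss.all() or not miss.any():
            rows.append({"feature": name, "p_value": np.nan, "applicable": False,
                         "most_associated": None})
            continue
        pvals = {}
        for other in names:
            if other == name:
                continue
            vals = data[other].to_numpy(float)
            a = vals[miss & ~np.isnan(vals)]
            b = vals[~miss & ~np.isnan(vals)]
            if len(a) < 2 or len(b) < 2:
                continue
            try:
                _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            except ValueError:
                continue
            pvals[other] = p
        if not pvals:
            rows.append({"feature": name, "p_value": np.nan, "applicable": False,
                         "most_associated": None})
            continue
        best = min(pvals, key=pvals.get)
        p_adj = min(1.0, pvals[best] * len(pvals))
        rows.append({"feature": name, "p_value": p_adj, "applicable": True,
                     "most_associated": best})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline

def preprocess_cohort(
    table: TrajectoryTable, config: RunConfig | None = None
) -> tuple[list[VentilationEvent], ImputationDiagnostics]:
    """Full preprocessing pipeline: outliers -> events -> hold -> impute."""
    config = config or RunConfig()
    filtered = apply_outlier_filter(table, k=config.tukey_k)
    events = define_ventilation_events(filtered)
    if not events:
        return [], ImputationDiagnostics(0, 0, {})
    limits = estimate_hold_limits(filtered, fallback=config.hold_fallback)
    held = [hold_event(ev, limits, table.manifest.names) for ev in events]
    return impute(
        held,
        table.manifest,
        method=config.imputation,
        knn_k=config.knn_k,
        svd_rank=config.svd_rank,
        discard_threshold=config.discard_threshold,
    )
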