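"""Policy-comparison analytics.

Given the learned policy and the held-out test trajectories, these
routines reproduce the standard comparisons between the learned and the
clinician policy: per-dimension action-frequency tables (absolute and
relative deltas), per-time-step action-change dynamics, random-forest
out-of-bag feature importance for each action dimension, the
return-vs-mortality curve, and the state-versus-time correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .mdp_policy import PolicyTable, Trajectory
from .state_action import ActionGrid

logger = logging.getLogger("ventrl")

#: sentinel for a relative change with zero clinician baseline
UNDEFINED_RELATIVE = float("nan")


def action_frequency_comparison(
    trajectories: list[Trajectory],
    policy_ai: PolicyTable,
    grid: ActionGrid,
    reporting_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-dimension, per-bin comparison of clinician vs learned actions.

    For every decision instance the clinician's observed action and the
    learned policy's greedy action at the same state are binned along
    each grid dimension.  The table reports counts, the absolute delta,
    the delta as a percentage of total decision instances, and the
    relative percent change (AI - clinician) / clinician * 100 (NaN and
    ``below_threshold`` marking when the clinician count is zero /
    |delta| is under the reporting threshold).
    """
    n_total = sum(len(tr) for tr in trajectories)
    shape = grid.shape
    dims = grid.dims
    clin_counts = {d: np.zeros(n, dtype=int) for d, n in zip(dims, shape)}
    ai_counts = {d: np.zeros(n, dtype=int) for d, n in zip(dims, shape)}
    for tr in trajectories:
        ai_actions = [policy_ai.greedy_action(s) for s in tr.states]
        for a_clin, a_ai in zip(tr.actions, ai_actions):
            for d, b in zip(dims, grid.unflatten(int(a_clin))):
                clin_counts[d][b] += 1
            for d, b in zip(dims, grid.unflatten(int(a_ai))):
                ai_counts[d][b] += 1
    rows = []
    for d in dims:
        for b in range(len(grid.edges[d])):
            lo, hi = grid.bin_range(d, b)
            c, a = int(clin_counts[d][b]), int(ai_counts[d][b])
            delta = a - c
            rel = (delta / c * 100.0) if c > 0 else UNDEFINED_RELATIVE
            rows.append(
                {
                    "dimension": d,
                    "bin": b,
                    "range_low": lo,
                    "range_high": hi,
                    "clinician_count": c,
                    "ai_count": a,
                    "delta": delta,
                    "delta_pct_of_total": delta / n_total * 100.0 if n_total else 0.0,
                    "relative_pct_change": rel,
                    "below_threshold": abs(delta) < reporting_threshold * n_total,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["total_decision_instances"] = n_total
    return out


def action_changes_per_step(
    clin_sequences: list[np.ndarray], ai_sequences: list[np.ndarray]
) -> pd.DataFrame:
    """Relative number of action changes at each post-onset time step.

    For each bin t >= 1, counts patients whose flat action differs from
    bin t-1, divided by the number of patients still ventilated at t;
    computed separately for the clinician and the learned sequences.
    Also emits per-patient total change counts in ``attrs``.
    """
    horizon = max((len(s) for s in clin_sequences), default=0)
    rows = []
    per_patient = {"clinician": [], "ai": []}
    for name, seqs in (("clinician", clin_sequences), ("ai", ai_sequences)):
        for s in seqs:
            s = np.asarray(s)
            per_patient[name].append(int(np.sum(s[1:] != s[:-1])))
    for t in range(1, horizon):
        n_vent = sum(1 for s in clin_sequences if len(s) > t)
        ch_clin = sum(
            1 for s in clin_sequences if len(s) > t and s[t] != s[t - 1]
        )
        ch_ai = sum(
            1
            for s in ai_sequences
            if len(s) > t and s[t] != s[t - 1]
        )
        rows.append(
            {
                "time_bin": t,
                "n_ventilated": n_vent,
                "clinician_changes": ch_clin,
                "ai_changes": ch_ai,
                "clinician_rel": ch_clin / n_vent if n_vent else 0.0,
                "ai_rel": ch_ai / n_vent if n_vent else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["per_patient_changes"] = per_patient
    return out


@dataclass
class FeatureImportanceResult:
    """Normalized out-of-bag permutation importances per action dimension."""

    weights: pd.DataFrame  # columns: one per action dimension, index: feature
    n_top80: dict[str, int]  # features reaching cumulative 0.80, per dimension


def _oob_indices(tree, n: int) -> np.ndarray:
    from sklearn.ensemble._forest import _generate_unsampled_indices

    try:
        return _generate_unsampled_indices(tree.random_state, n, n, None)
    except TypeError:  # older signature without sample_weight
        return _generate_unsampled_indices(tree.random_state, n, n)


def _oob_permutation_importance(
    forest: RandomForestRegressor, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Breiman-style OOB importance: per tree, the increase in MSE on its
    out-of-bag samples when a feature column is permuted.  One row
    permutation per tree is shared across features, so reordering the
    feature columns reorders the importances identically."""
    n, d = X.shape
    increases = np.zeros(d)
    counts = np.zeros(d)
    for est in forest.estimators_:
        unsampled = _oob_indices(est, n)
        if len(unsampled) < 2:
            continue
        Xo, yo = X[unsampled], y[unsampled]
        base = np.mean((est.predict(Xo) - yo) ** 2)
        perm = rng.permutation(len(unsampled))
        for j in range(d):
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            mse = np.mean((est.predict(Xp) - yo) ** 2)
            increases[j] += mse - base
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        imp = np.where(counts > 0, increases / np.maximum(counts, 1), 0.0)
    return imp


def feature_importance_oob(
    features: np.ndarray,
    targets: dict[str, np.ndarray],
    feature_names: list[str],
    n_trees: int = 500,
    max_features: float | str = "sqrt",
    seed: int = 0,
) -> FeatureImportanceResult:
    """Random-forest out-of-bag permutation importance per action dimension.

    ``targets`` maps each action dimension to the continuous chosen
    setting at every decision instance.  Importance is the OOB increase
    in mean squared error under feature permutation, floored at zero and
    normalized to sum to one.  Reports the number of top-ranked features
    reaching a cumulative weight of 0.80 per dimension.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 50:
        raise ValueError("need at least 50 decision instances")
    rng = np.random.default_rng(seed)
    cols = {}
    n_top80 = {}
    for dim, y in targets.items():
        y = np.asarray(y, dtype=float)
        if np.all(y == y[0]):
            logger.warning("constant target for %s: all-zero importances", dim)
            cols[dim] = np.zeros(X.shape[1])
            n_top80[dim] = 0
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        ).fit(X, y)
        imp = _oob_permutation_importance(forest, X, y, rng)
        imp = np.maximum(imp, 0.0)
        total = imp.sum()
        imp = imp / total if total > 0 else imp
        cols[dim] = imp
        order = np.argsort(imp)[::-1]
        cum = np.cumsum(imp[order])
        n_top80[dim] = int(np.searchsorted(cum, 0.80) + 1) if total > 0 else 0
    weights = pd.DataFrame(cols, index=feature_names)
    return FeatureImportanceResult(weights=weights, n_top80=n_top80)


def return_vs_mortality(
    returns: np.ndarray, died: np.ndarray, n_bins: int = 10, level: float = 0.95
) -> pd.DataFrame:
    """Empirical mortality fraction per equal-width return bin.

    Each bin reports the mortality with a binomial (Wilson) confidence
    interval; empty bins are marked rather than interpolated.
    """
    returns = np.asarray(returns, dtype=float)
    died = np.asarray(died, dtype=bool)
    if not np.all(np.isfinite(returns)):
        raise ValueError("returns must be finite")
    lo, hi = returns.min(), returns.max()
    if lo == hi:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(returns, edges) - 1, 0, n_bins - 1)
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for b in range(n_bins):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            rows.append(
                {"bin": b, "return_low": edges[b], "return_high": edges[b + 1],
                 "n": 0, "mortality": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "empty": True}
            )
            continue
        k = int(died[m].sum())
        p = k / n
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        ci_low = 0.0 if k == 0 else max(0.0, center - half)
        ci_high = 1.0 if k == n else min(1.0, center + half)
        rows.append(
            {"bin": b, "return_low": edges[b], "return_high": edges[b + 1],
             "n": n, "mortality": p, "ci_low": ci_low,
             "ci_high": ci_high, "empty": False}
        )
    return pd.DataFrame(rows)


def state_time_correlation(state_sequences: dict[object, np.ndarray]) -> pd.DataFrame:
    """Spearman correlation of the assigned state index against time per stay.

    Constant sequences get a flagged correlation of 0.  A cohort summary
    (mean, median, fraction positive) is attached in ``attrs``.
    """
    rows = []
    for stay_id, seq in state_sequences.items():
        seq = np.asarray(seq)
        if len(seq) < 2:
            raise ValueError(f"stay {stay_id!r} has fewer than 2 bins")
        if np.all(seq == seq[0]):
            rows.append({"stay_id": stay_id, "rho": 0.0, "constant": True})
            continue
        rho, _ = stats.spearmanr(np.arange(len(seq)), seq)
        rows.append({"stay_id": stay_id, "rho": float(rho), "constant": False})
    out = pd.DataFrame(rows)
    valid = out.loc[~out["constant"], "rho"]
    out.attrs["summary"] = {
        "mean_rho": float(valid.mean()) if len(valid) else 0.0,
        "median_rho": float(valid.median()) if len(valid) else 0.0,
        "frac_positive": float((valid > 0).mean()) if len(valid) else 0.0,
        "n_constant": int(out["constant"].sum()),
    }
    return out
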