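"""Off-policy evaluation by weighted importance sampling (WIS) with
trajectory-bootstrap confidence bounds, and ensemble model selection.

A candidate policy pi_e is scored from trajectories collected under the
clinician (behavior) policy pi_b.  The trajectory-level WIS estimate is

    V_hat = sum_i w_i G_i / sum_i w_i,
    w_i = prod_t pi_e(a_t | s_t) / pi_b(a_t | s_t),
    G_i = sum_t gamma^t r_t,

a self-normalized, consistent estimator.  The default "stepwise"
estimator is the per-decision variant with per-step self-normalized
cumulative weights, which reduces variance for long horizons.
Confidence bounds come from bootstrap resampling of whole trajectories.

Model selection runs an ensemble of models, each from a fresh random
60/20/20 stay split: clustering + MDP estimation on train, bootstrap-WIS
of the softened learned policy on validation, selection of the model
maximizing the configured lower bound, and re-evaluation of the winner
on its held-out test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mdp_policy import (
    MDPModel,
    PolicyTable,
    Trajectory,
    discretize_trajectories,
    estimate_behavior_policy,
    estimate_mdp,
    random_policy,
    soften_policy,
    solve_optimal_policy,
)
from .preprocessing import VentilationEvent
from .state_action import ActionGrid, StateModel, fit_state_model
from .trajectory_io import RunConfig

logger = logging.getLogger("ventrl")


@dataclass
class OPEResult:
    """WIS point estimate with optional bootstrap distribution and bounds.

    ``lower``/``upper`` map a confidence level to the corresponding
    percentile bound of the bootstrap distribution; the estimate lives on
    the performance-return scale [-100, 100].
    """

    estimate: float
    weights: np.ndarray
    returns: np.ndarray
    estimator: str
    bootstrap: np.ndarray | None = None
    lower: dict[float, float] = field(default_factory=dict)
    upper: dict[float, float] = field(default_factory=dict)

    @property
    def effective_sample_size(self) -> float:
        s = self.weights.sum()
        s2 = (self.weights**2).sum()
        return float(s * s / s2) if s2 > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "estimator": self.estimator,
            "ess": self.effective_sample_size,
            "lower": {str(k): v for k, v in self.lower.items()},
            "upper": {str(k): v for k, v in self.upper.items()},
        }


def _step_ratios(
    tr: Trajectory, pi_e: PolicyTable, pi_b: PolicyTable
) -> np.ndarray:
    pe = pi_e.probs[tr.states, tr.actions]
    pb = pi_b.probs[tr.states, tr.actions]
    if np.any(pb <= 0):
        # behavior support violated: the trajectory carries zero weight
        return np.zeros(len(tr))
    return pe / pb


def _padded_arrays(
    trajectories: list[Trajectory], pi_e: PolicyTable, pi_b: PolicyTable, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trajectory cumulative weights and discounted rewards on a common
    horizon grid.

    Terminated trajectories are padded as if in a virtual absorbing state
    with importance ratio 1 and reward 0: their final cumulative weight
    keeps contributing to later per-step normalizations.
    """
    n = len(trajectories)
    horizon = max(len(tr) for tr in trajectories)
    W = np.zeros((n, horizon))
    Rg = np.zeros((n, horizon))
    for i, tr in enumerate(trajectories):
        cw = np.cumprod(_step_ratios(tr, pi_e, pi_b))
        L = len(tr)
        W[i, :L] = cw
        W[i, L:] = cw[-1] if L else 0.0
        Rg[i, :L] = tr.rewards * gamma ** np.arange(L)
    return W, Rg


def _stepwise_estimates(W: np.ndarray, Rg: np.ndarray) -> np.ndarray:
    """Per-decision WIS on (possibly batched) padded arrays.

    Accepts (n, T) or (B, n, T); returns a scalar array of estimates.
    Steps with zero total weight contribute nothing; an all-zero batch
    member yields NaN.
    """
    num = (W * Rg).sum(axis=-2)
    den = W.sum(axis=-2)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_step = np.where(den > 0, num / den, 0.0)
    est = per_step.sum(axis=-1)
    dead = (den <= 0).all(axis=-1)
    return np.where(dead, np.nan, est)


def wis_evaluate(
    trajectories: list[Trajectory],
    pi_e: PolicyTable,
    pi_b: PolicyTable,
    gamma: float,
    estimator: str = "stepwise",
) -> OPEResult:
    """Weighted importance sampling estimate of the target policy's value.

    ``trajectory``: classic trajectory-level WIS.  ``stepwise``: the
    per-decision self-normalized variant (variance-reduced default).
    Trajectories stepping outside the behavior policy's support get zero
    weight (logged).  Raises if every weight is zero.
    """
    if estimator not in ("trajectory", "stepwise"):
        raise ValueError(f"unknown estimator {estimator!r}")
    n = len(trajectories)
    W, Rg = _padded_arrays(trajectories, pi_e, pi_b, gamma)
    weights = W[:, -1]
    returns = Rg.sum(axis=1)
    n_zero = int((weights == 0).sum())
    if n_zero:
        logger.debug("wis: %d/%d trajectories with zero weight", n_zero, n)
    if estimator == "trajectory":
        total = weights.sum()
        if total <= 0:
            raise ValueError("all importance weights are zero; estimate undefined")
        estimate = float(weights @ returns / total)
    else:
        estimate = float(_stepwise_estimates(W, Rg))
        if np.isnan(estimate):
            raise ValueError("all importance weights are zero; estimate undefined")
    return OPEResult(
        estimate=estimate, weights=weights, returns=returns, estimator=estimator
    )


def bootstrap_bounds(
    trajectories: list[Trajectory],
    pi_e: PolicyTable,
    pi_b: PolicyTable,
    gamma: float,
    n_bootstrap: int = 1000,
    levels: tuple[float, ...] = (0.90, 0.95),
    seed: int = 0,
    estimator: str = "stepwise",
) -> OPEResult:
    """WIS with percentile confidence bounds from ``n_bootstrap`` resamples
    of whole trajectories (with replacement); deterministic given seed."""
    if n_bootstrap < 1:
        raise ValueError("need at least one bootstrap replicate")
    result = wis_evaluate(trajectories, pi_e, pi_b, gamma, estimator)
    if len(trajectories) < 2:
        logger.warning("bootstrap on < 2 trajectories gives degenerate bounds")
    rng = np.random.default_rng(seed)
    n = len(trajectories)
    # per-trajectory padded weights/rewards are resample-invariant, so the
    # bootstrap reduces to row gathers (chunked to bound memory)
    W, Rg = _padded_arrays(trajectories, pi_e, pi_b, gamma)
    boots = np.empty(n_bootstrap)
    chunk = max(1, int(2_000_000 / max(W.size, 1)) + 1)
    if estimator == "trajectory":
        w, g = W[:, -1], Rg.sum(axis=1)
        idx = rng.integers(0, n, size=(n_bootstrap, n))
        wB = w[idx]
        totals = wB.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            boots = (wB * g[idx]).sum(axis=1) / totals
        boots[totals <= 0] = np.nan
    else:
        for start in range(0, n_bootstrap, chunk):
            b = min(chunk, n_bootstrap - start)
            idx = rng.integers(0, n, size=(b, n))
            boots[start : start + b] = _stepwise_estimates(W[idx], Rg[idx])
    boots = boots[~np.isnan(boots)]
    result.bootstrap = boots
    for lv in levels:
        result.lower[lv] = float(np.percentile(boots, 100 * (1 - lv)))
        result.upper[lv] = float(np.percentile(boots, 100 * lv))
    return result


# ---------------------------------------------------------------------------
# ensemble model selection

@dataclass
class ModelRecord:
    """One candidate model of the ensemble."""

    model_id: int
    seed: int
    state_model: StateModel
    mdp: MDPModel
    policy_ai: PolicyTable  # softened learned policy
    ai: OPEResult  # validation bootstrap-WIS of the AI policy
    clinician: OPEResult
    random: OPEResult
    clinician_model_based: float  # linear-solve value of pi_b on the MDP
    selection_criterion: float  # configured lower bound of the AI estimate


@dataclass
class EnsembleResult:
    models: list[ModelRecord]
    selected_id: int
    best_so_far: np.ndarray  # running max of the selection criterion
    cumulative_std: np.ndarray  # up-to-the-point std of the criterion
    test_ai: OPEResult | None = None  # selected policy on its test split
    test_clinician: OPEResult | None = None

    @property
    def selected(self) -> ModelRecord:
        return next(m for m in self.models if m.model_id == self.selected_id)


def _split_events(
    events: list[VentilationEvent], fracs: tuple[float, float, float], rng: np.random.Generator
):
    idx = rng.permutation(len(events))
    n_train = int(round(fracs[0] * len(events)))
    n_val = int(round(fracs[1] * len(events)))
    tr = [events[i] for i in idx[:n_train]]
    va = [events[i] for i in idx[n_train : n_train + n_val]]
    te = [events[i] for i in idx[n_train + n_val :]]
    return tr, va, te


def fit_single_model(
    events_train: list[VentilationEvent],
    events_val: list[VentilationEvent],
    grid: ActionGrid,
    config: RunConfig,
    seed: int,
    model_id: int = 0,
) -> ModelRecord:
    """Fit one candidate model: state clustering and MDP on the training
    events, bootstrap-WIS of the softened learned / clinician / random
    policies on the validation events."""
    rows = np.vstack([ev.features for ev in events_train])
    k = min(config.n_states, len(np.unique(rows, axis=0)))
    sm = fit_state_model(rows, k=k, seed=seed)
    train_traj = discretize_trajectories(events_train, sm, grid)
    mdp = estimate_mdp(
        train_traj, n_physio=sm.k, n_actions=grid.n_actions,
        gamma=config.gamma, min_count=config.min_action_count,
    )
    _, greedy = solve_optimal_policy(mdp)
    pi_ai = soften_policy(greedy, config.epsilon, mdp.mask)
    pi_b = estimate_behavior_policy(train_traj, mdp.n_states, grid.n_actions)
    pi_rand = random_policy(mdp)

    val_traj = discretize_trajectories(events_val, sm, grid)
    common = dict(
        pi_b=pi_b, gamma=config.gamma, n_bootstrap=config.n_bootstrap,
        levels=tuple(sorted(set(config.report_levels) | {config.select_level})),
        estimator=config.estimator,
    )
    ai = bootstrap_bounds(val_traj, pi_ai, seed=seed + 1, **common)
    clin = bootstrap_bounds(val_traj, pi_b, seed=seed + 2, **common)
    rand = bootstrap_bounds(val_traj, pi_rand, seed=seed + 3, **common)
    from .mdp_policy import policy_value

    clin_mb = policy_value(mdp, pi_b, train_traj)
    return ModelRecord(
        model_id=model_id,
        seed=seed,
        state_model=sm,
        mdp=mdp,
        policy_ai=pi_ai,
        ai=ai,
        clinician=clin,
        random=rand,
        clinician_model_based=clin_mb,
        selection_criterion=ai.lower[config.select_level],
    )


def run_ensemble(
    events: list[VentilationEvent],
    grid: ActionGrid,
    config: RunConfig,
    seed: int | None = None,
) -> EnsembleResult:
    """Run the full model-selection ensemble.

    For each of ``config.n_models`` candidates: a fresh random
    train/validation/test split of the events, state-model + MDP fit on
    train, bootstrap-WIS evaluation of the softened learned policy (and
    the clinician and random baselines) on validation.  The selected
    model maximizes the configured lower bound; its policy is
    re-evaluated on the held-out test split.  Per-model failures are
    logged and skipped.
    """
    seed = config.seed if seed is None else seed
    master = np.random.default_rng(seed)
    fracs = (config.train_frac, config.val_frac, config.test_frac)
    records: list[ModelRecord] = []
    criteria: list[float] = []
    test_splits: dict[int, list[VentilationEvent]] = {}
    n_failed = 0
    for m in range(config.n_models):
        sub = int(master.integers(0, 2**31 - 1))
        rng_m = np.random.default_rng(sub)
        ev_tr, ev_va, ev_te = _split_events(events, fracs, rng_m)
        try:
            rec = fit_single_model(ev_tr, ev_va, grid, config, seed=sub % (2**31 - 10), model_id=m)
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.warning("model %d failed: %s", m, exc)
            continue
        records.append(rec)
        criteria.append(rec.selection_criterion)
        test_splits[m] = ev_te
    if not records:
        raise ValueError(f"all {config.n_models} models failed")
    if n_failed:
        logger.info("ensemble: %d/%d models failed and were skipped", n_failed, config.n_models)
    crit = np.array(criteria)
    best_so_far = np.maximum.accumulate(crit)
    cum_std = np.array([crit[: i + 1].std() for i in range(len(crit))])
    best_idx = int(np.argmax(crit))
    selected = records[best_idx]

    ev_te = test_splits[selected.model_id]
    test_ai = test_clin = None
    if ev_te:
        te_traj = discretize_trajectories(ev_te, selected.state_model, grid)
        pi_b = estimate_behavior_policy(
            te_traj, selected.mdp.n_states, grid.n_actions
        )
        levels = tuple(sorted(set(config.report_levels) | {config.select_level}))
        if te_traj:
            test_ai = bootstrap_bounds(
                te_traj, selected.policy_ai, pi_b, config.gamma,
                n_bootstrap=config.n_bootstrap, levels=levels,
                seed=selected.seed + 7, estimator=config.estimator,
            )
            test_clin = bootstrap_bounds(
                te_traj, pi_b, pi_b, config.gamma,
                n_bootstrap=config.n_bootstrap, levels=levels,
                seed=selected.seed + 8, estimator=config.estimator,
            )
    return EnsembleResult(
        models=records,
        selected_id=selected.model_id,
        best_so_far=best_so_far,
        cumulative_std=cum_std,
        test_ai=test_ai,
        test_clinician=test_clin,
    )
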