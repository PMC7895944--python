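"""MDP estimation from discretized trajectories and tabular policy solving.

The decision process is the tuple <S, A, T, R, gamma>: S are the k
physiologic states plus two absorbing terminal states (survival, death);
A is the flat action grid; T(s, a, s') is the empirical transition
frequency; rewards are terminal-only, +100 on transition into survival
and -100 into death, collapsed to R(s, a) = sum_s' T(s, a, s') R(s, s', a).

Two solvers ship: model-based value iteration (default) and sample-based
tabular Q-learning with replay over the observed transitions; both
converge to the same fixed point on small MDPs.  Policies are tabular
and row-stochastic over the eligible actions of each state (eligibility:
at least ``min_count`` observed visits of (s, a)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import VentilationEvent
from .state_action import ActionGrid, StateModel, assign_state, encode_action

logger = logging.getLogger("ventrl")

TERMINAL_REWARD = 100.0


@dataclass
class Trajectory:
    """One discretized patient trajectory: per-bin (state, action) pairs
    followed by absorption into survival or death."""

    stay_id: object
    states: np.ndarray  # (L,) physiologic state ids
    actions: np.ndarray  # (L,) flat action indices
    rewards: np.ndarray  # (L,) 0 everywhere except the terminal step
    terminal_state: int

    def __len__(self) -> int:
        return len(self.states)

    @property
    def ret(self) -> float:
        return float(self.rewards[-1]) if len(self.rewards) else 0.0

    def discounted_return(self, gamma: float) -> float:
        t = np.arange(len(self.rewards))
        return float(np.sum(self.rewards * gamma**t))


def discretize_trajectories(
    events: list[VentilationEvent],
    model: StateModel,
    grid: ActionGrid,
) -> list[Trajectory]:
    """Map imputed events to (s, a, s', r) sequences.

    Every post-onset 4-h bin with documented settings yields one
    (state, action) pair; the final observed bin transitions into the
    survival (+100) or death (-100) absorbing state.  Intermediate
    rewards are exactly zero.
    """
    out: list[Trajectory] = []
    for ev in events:
        post = ev.bins >= ev.onset_bin
        settings_ok = (
            ~np.isnan(ev.vt_set_ml) & ~np.isnan(ev.peep_cmh2o) & ~np.isnan(ev.fio2_pct)
        )
        use = post & settings_ok
        if not use.any():
            logger.info("skipping event %s: no usable post-onset bins", ev.stay_id)
            continue
        feats = ev.features[use]
        states = np.asarray(assign_state(model, feats), dtype=int)
        actions = np.array(
            [
                encode_action(vt, ev.ibw_kg, pe, fi, grid)
                for vt, pe, fi in zip(
                    ev.vt_set_ml[use], ev.peep_cmh2o[use], ev.fio2_pct[use]
                )
            ],
            dtype=int,
        )
        rewards = np.zeros(len(states))
        rewards[-1] = -TERMINAL_REWARD if ev.died else TERMINAL_REWARD
        terminal = model.death_state if ev.died else model.survival_state
        out.append(Trajectory(ev.stay_id, states, actions, rewards, terminal))
    return out


# ---------------------------------------------------------------------------
# MDP estimation

@dataclass
class MDPModel:
    """Estimated tabular MDP.

    States 0..k-1 are physiologic; ``survival_state`` = k and
    ``death_state`` = k+1 are absorbing with zero onward reward.
    ``mask[s, a]`` marks eligible actions (N(s, a) >= min_count).
    """

    T: np.ndarray  # (S, A, S)
    R: np.ndarray  # (S, A)
    gamma: float
    counts_sa: np.ndarray  # (S, A)
    counts_sas: np.ndarray  # (S, A, S)
    mask: np.ndarray  # (S, A) bool
    n_physio: int

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def n_actions(self) -> int:
        return self.T.shape[1]

    @property
    def survival_state(self) -> int:
        return self.n_physio

    @property
    def death_state(self) -> int:
        return self.n_physio + 1

    @property
    def terminal_states(self) -> tuple[int, int]:
        return (self.survival_state, self.death_state)

    def validate(self) -> None:
        observed = self.counts_sa > 0
        sums = self.T.sum(axis=2)
        if not np.allclose(sums[observed], 1.0, atol=1e-9):
            raise ValueError("observed T rows must sum to 1")
        if np.any(np.abs(self.R) > TERMINAL_REWARD + 1e-9):
            raise ValueError("rewards out of range")


def estimate_mdp(
    trajectories: list[Trajectory],
    n_physio: int,
    n_actions: int,
    gamma: float = 0.99,
    min_count: int = 5,
) -> MDPModel:
    """Maximum-likelihood tabular MDP from observed transitions.

    T(s, a, s') = N(s, a, s') / N(s, a); the three-dimensional reward
    R(s, s', a) (= +/-100 iff s' terminal) is collapsed against T to
    R(s, a).  Terminal states are absorbing with zero reward.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    S = n_physio + 2
    counts = np.zeros((S, n_actions, S))
    for tr in trajectories:
        s, a = tr.states, tr.actions
        for t in range(len(tr) - 1):
            counts[s[t], a[t], s[t + 1]] += 1
        counts[s[-1], a[-1], tr.terminal_state] += 1
    counts_sa = counts.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = counts / counts_sa[:, :, None]
    T = np.nan_to_num(T)
    surv, death = n_physio, n_physio + 1
    # terminal states: absorbing under every action, zero onward reward
    T[surv], T[death] = 0.0, 0.0
    T[surv, :, surv] = 1.0
    T[death, :, death] = 1.0
    r_next = np.zeros(S)
    r_next[surv] = TERMINAL_REWARD
    r_next[death] = -TERMINAL_REWARD
    R = T @ r_next
    R[surv], R[death] = 0.0, 0.0
    mask = counts_sa >= min_count
    # terminal rows are trivially eligible (no decision is taken there)
    mask[surv] = True
    mask[death] = True
    mdp = MDPModel(T=T, R=R, gamma=gamma, counts_sa=counts_sa,
                   counts_sas=counts, mask=mask, n_physio=n_physio)
    mdp.validate()
    return mdp


# ---------------------------------------------------------------------------
# policies

@dataclass
class PolicyTable:
    """Row-stochastic tabular policy pi(a | s) with zero mass on masked actions."""

    probs: np.ndarray  # (S, A)
    kind: str

    def __post_init__(self) -> None:
        rows = self.probs.sum(axis=1)
        active = rows > 0
        if not np.allclose(rows[active], 1.0, atol=1e-9):
            raise ValueError("policy rows must sum to 1")

    def prob(self, s: int, a: int) -> float:
        return float(self.probs[s, a])

    def greedy_action(self, s: int) -> int:
        return int(np.argmax(self.probs[s]))


@dataclass
class QTable:
    Q: np.ndarray  # (S, A)
    mask: np.ndarray  # eligible actions

    @property
    def V(self) -> np.ndarray:
        q = np.where(self.mask, self.Q, -np.inf)
        v = q.max(axis=1)
        return np.where(np.isfinite(v), v, 0.0)

    def greedy(self) -> PolicyTable:
        """Deterministic greedy policy; argmax ties break to the lowest index."""
        q = np.where(self.mask, self.Q, -np.inf)
        best = q.argmax(axis=1)
        probs = np.zeros_like(self.Q)
        probs[np.arange(len(best)), best] = 1.0
        return PolicyTable(probs=probs, kind="deterministic-greedy")


def _check_eligibility(mdp: MDPModel) -> None:
    visited = mdp.counts_sa.sum(axis=1) > 0
    no_action = visited & ~mdp.mask.any(axis=1)
    if no_action.any():
        s = int(np.where(no_action)[0][0])
        raise ValueError(f"state {s} has zero eligible actions; lower min_count")


def solve_optimal_policy(
    mdp: MDPModel, tol: float = 1e-8, max_iter: int = 10_000
) -> tuple[QTable, PolicyTable]:
    """Value iteration on (T, R, gamma) to a Bellman residual below ``tol``.

    Ineligible actions are excluded from the max; terminal states have
    value zero by construction (absorbing, zero reward).
    """
    _check_eligibility(mdp)
    S, A = mdp.R.shape
    V = np.zeros(S)
    neg = np.finfo(float).min / 4
    for _ in range(max_iter):
        Q = mdp.R + mdp.gamma * (mdp.T @ V)
        Vn = np.where(mdp.mask, Q, neg).max(axis=1)
        Vn[~mdp.mask.any(axis=1)] = 0.0
        Vn[list(mdp.terminal_states)] = 0.0
        if np.max(np.abs(Vn - V)) < tol:
            V = Vn
            break
        V = Vn
    Q = mdp.R + mdp.gamma * (mdp.T @ V)
    qt = QTable(Q=np.where(mdp.mask, Q, -np.inf), mask=mdp.mask)
    return qt, qt.greedy()


def q_learning(
    trajectories: list[Trajectory],
    mdp: MDPModel,
    n_sweeps: int = 400,
    alpha0: float = 0.5,
    alpha_decay: float = 50.0,
    seed: int = 0,
) -> tuple[QTable, PolicyTable]:
    """Sample-based tabular Q-learning over the observed transitions.

    Replays the dataset ``n_sweeps`` times in random order with a
    per-(s, a) harmonic learning-rate schedule alpha0 / (1 + n / decay);
    converges to the value-iteration fixed point on small MDPs.  The
    estimated MDP supplies only shapes, the discount, and the action
    mask — its transition tensor is never used.
    """
    _check_eligibility(mdp)
    S, A = mdp.R.shape
    rng = np.random.default_rng(seed)
    Q = np.zeros((S, A))
    visits = np.zeros((S, A))
    steps = []
    for tr in trajectories:
        for t in range(len(tr)):
            s, a = tr.states[t], tr.actions[t]
            if t < len(tr) - 1:
                steps.append((s, a, 0.0, tr.states[t + 1], False))
            else:
                steps.append((s, a, tr.rewards[-1], tr.terminal_state, True))
    steps = np.array(steps, dtype=float)
    gamma = mdp.gamma
    neg = -np.inf
    for _ in range(n_sweeps):
        order = rng.permutation(len(steps))
        for idx in order:
            s, a, r, s2, terminal = steps[idx]
            s, a, s2 = int(s), int(a), int(s2)
            visits[s, a] += 1
            alpha = alpha0 / (1.0 + visits[s, a] / alpha_decay)
            if terminal or s2 >= mdp.n_physio:
                target = r
            else:
                q2 = np.where(mdp.mask[s2], Q[s2], neg)
                target = r + gamma * (q2.max() if np.isfinite(q2).any() else 0.0)
            Q[s, a] += alpha * (target - Q[s, a])
    qt = QTable(Q=np.where(mdp.mask, Q, -np.inf), mask=mdp.mask)
    return qt, qt.greedy()


def estimate_behavior_policy(
    trajectories: list[Trajectory], n_states: int, n_actions: int
) -> PolicyTable:
    """Empirical clinician policy pi_b(a | s) = N(s, a) / N(s).

    States never visited get a uniform distribution over the full grid
    (logged), so the policy is defined everywhere.
    """
    counts = np.zeros((n_states, n_actions))
    for tr in trajectories:
        np.add.at(counts, (tr.states, tr.actions), 1)
    totals = counts.sum(axis=1, keepdims=True)
    probs = np.where(totals > 0, counts / np.maximum(totals, 1), 1.0 / n_actions)
    n_unvisited = int((totals == 0).sum())
    if n_unvisited:
        logger.info("behavior policy: %d unvisited states set uniform", n_unvisited)
    return PolicyTable(probs=probs, kind="behavior-empirical")


def soften_policy(greedy: PolicyTable, epsilon: float, mask: np.ndarray) -> PolicyTable:
    """Epsilon-soften a deterministic policy over the eligible actions.

    The greedy action keeps 1 - eps + eps/m, every other eligible action
    receives eps/m, with m the eligible-action count of the state.
    """
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must lie in [0, 1)")
    if epsilon == 0:
        return PolicyTable(probs=greedy.probs.copy(), kind="softened")
    probs = np.zeros_like(greedy.probs)
    for s in range(probs.shape[0]):
        eligible = np.where(mask[s])[0]
        if len(eligible) == 0:
            continue
        m = len(eligible)
        g = greedy.greedy_action(s)
        probs[s, eligible] = epsilon / m
        probs[s, g] += 1 - epsilon
    return PolicyTable(probs=probs, kind="softened")


def random_policy(mdp: MDPModel) -> PolicyTable:
    """Uniform distribution over the eligible actions of each state."""
    probs = mdp.mask.astype(float)
    totals = probs.sum(axis=1, keepdims=True)
    probs = np.divide(probs, totals, out=np.zeros_like(probs), where=totals > 0)
    return PolicyTable(probs=probs, kind="random")


# ---------------------------------------------------------------------------
# policy evaluation

def policy_evaluation(mdp: MDPModel, policy: PolicyTable) -> np.ndarray:
    """Exact state values of a policy by linear solve.

    V = (I - gamma * P_pi)^{-1} r_pi over the physiologic states;
    terminal states have value zero.
    """
    S = mdp.n_states
    P = np.einsum("sa,sax->sx", policy.probs, mdp.T)
    r = np.einsum("sa,sa->s", policy.probs, mdp.R)
    phys = np.arange(mdp.n_physio)
    A_mat = np.eye(mdp.n_physio) - mdp.gamma * P[np.ix_(phys, phys)]
    V = np.zeros(S)
    V[phys] = np.linalg.solve(A_mat, r[phys])
    return V


def initial_state_distribution(trajectories: list[Trajectory], n_states: int) -> np.ndarray:
    d = np.zeros(n_states)
    for tr in trajectories:
        d[tr.states[0]] += 1
    total = d.sum()
    return d / total if total else d


def policy_value(
    mdp: MDPModel, policy: PolicyTable, trajectories: list[Trajectory]
) -> float:
    """Scalar performance return: initial-state-weighted exact value."""
    V = policy_evaluation(mdp, policy)
    d0 = initial_state_distribution(trajectories, mdp.n_states)
    return float(d0 @ V)


def evaluate_clinician_td(
    trajectories: list[Trajectory],
    n_states: int,
    n_actions: int,
    gamma: float = 0.99,
    n_sweeps: int = 200,
    alpha0: float = 0.1,
    alpha_decay: float = 100.0,
    seed: int = 0,
) -> float:
    """On-policy TD (SARSA-style) evaluation of the observed clinician policy.

    Replays observed (s, a, r, s', a') tuples with a decaying learning
    rate; the returned scalar is the initial-state-distribution-weighted
    state value.  The model-based equivalent is
    ``policy_value(mdp, estimate_behavior_policy(...), trajectories)``.
    """
    rng = np.random.default_rng(seed)
    Q = np.zeros((n_states, n_actions))
    visits = np.zeros((n_states, n_actions))
    tuples = []
    for tr in trajectories:
        for t in range(len(tr)):
            s, a = tr.states[t], tr.actions[t]
            if t < len(tr) - 1:
                tuples.append((s, a, 0.0, tr.states[t + 1], tr.actions[t + 1]))
            else:
                tuples.append((s, a, tr.rewards[-1], -1, -1))
    for _ in range(n_sweeps):
        for idx in rng.permutation(len(tuples)):
            s, a, r, s2, a2 = tuples[idx]
            visits[s, a] += 1
            alpha = alpha0 / (1.0 + visits[s, a] / alpha_decay)
            target = r if s2 < 0 else r + gamma * Q[s2, a2]
            Q[s, a] += alpha * (target - Q[s, a])
    # state value under the empirical behavior policy
    pi_b = estimate_behavior_policy(trajectories, n_states, n_actions)
    V = np.einsum("sa,sa->s", pi_b.probs, Q)
    d0 = initial_state_distribution(trajectories, n_states)
    return float(d0 @ V)
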