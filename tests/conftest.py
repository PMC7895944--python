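"""Shared fixtures: tiny cohorts, hand-built toy MDPs, and independent
oracles (exhaustive policy enumeration, closed-form policy evaluation)."""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ventrl.mdp_policy import MDPModel, PolicyTable, Trajectory
from ventrl.trajectory_io import DEFAULT_MANIFEST, TrajectoryTable


def make_toy_mdp(T_phys: np.ndarray, gamma: float = 0.9, mask: np.ndarray | None = None) -> MDPModel:
    """Build an MDPModel from a physiologic transition tensor.

    ``T_phys`` has shape (n_phys, A, n_phys + 2): transition rows over
    physiologic states plus the survival / death columns.  Rewards follow
    the terminal-only +/-100 convention; counts are set large enough that
    every action is eligible unless ``mask`` says otherwise.
    """
    n_phys, A, S = T_phys.shape
    assert S == n_phys + 2
    T = np.zeros((S, A, S))
    T[:n_phys] = T_phys
    surv, death = n_phys, n_phys + 1
    T[surv, :, surv] = 1.0
    T[death, :, death] = 1.0
    r_next = np.zeros(S)
    r_next[surv], r_next[death] = 100.0, -100.0
    R = T @ r_next
    R[surv], R[death] = 0.0, 0.0
    counts_sas = T * 1000.0
    counts_sa = counts_sas.sum(axis=2)
    if mask is None:
        mask = np.ones((S, A), dtype=bool)
    mdp = MDPModel(T=T, R=R, gamma=gamma, counts_sa=counts_sa,
                   counts_sas=counts_sas, mask=mask, n_physio=n_phys)
    mdp.validate()
    return mdp


def enumerate_optimal(mdp: MDPModel) -> tuple[np.ndarray, np.ndarray]:
    """Independent oracle: optimal V and Q by exhaustive enumeration of all
    deterministic policies, each evaluated by linear solve."""
    n, A = mdp.n_physio, mdp.n_actions
    best_V = np.full(n, -np.inf)
    for assignment in product(range(A), repeat=n):
        probs = np.zeros((mdp.n_states, A))
        probs[np.arange(n), list(assignment)] = 1.0
        probs[n:, 0] = 1.0
        V = evaluate_policy_linear(mdp, probs)
        best_V = np.maximum(best_V, V)
    V_full = np.zeros(mdp.n_states)
    V_full[:n] = best_V
    Q = mdp.R + mdp.gamma * (mdp.T @ V_full)
    return best_V, Q


def evaluate_policy_linear(mdp: MDPModel, probs: np.ndarray) -> np.ndarray:
    """Closed-form value of a stochastic policy over physiologic states."""
    n = mdp.n_physio
    P = np.einsum("sa,sax->sx", probs, mdp.T)[:n, :n]
    r = np.einsum("sa,sa->s", probs, mdp.R)[:n]
    return np.linalg.solve(np.eye(n) - mdp.gamma * P, r)


def rollout(mdp: MDPModel, probs: np.ndarray, n_traj: int, seed: int,
            max_len: int = 50, init: np.ndarray | None = None) -> list[Trajectory]:
    """Simulate trajectories from an MDPModel under a policy."""
    rng = np.random.default_rng(seed)
    n, A, S = mdp.n_physio, mdp.n_actions, mdp.n_states
    if init is None:
        init = np.full(n, 1.0 / n)
    out = []
    for i in range(n_traj):
        s = int(rng.choice(n, p=init))
        states, actions = [], []
        terminal = None
        for _ in range(max_len):
            a = int(rng.choice(A, p=probs[s]))
            states.append(s)
            actions.append(a)
            nxt = int(rng.choice(S, p=mdp.T[s, a]))
            if nxt >= n:
                terminal = nxt
                break
            s = nxt
        if terminal is None:
            terminal = mdp.survival_state  # censored: counted as survival
        rewards = np.zeros(len(states))
        rewards[-1] = 100.0 if terminal == mdp.survival_state else -100.0
        out.append(Trajectory(f"t{i}", np.array(states), np.array(actions),
                              rewards, terminal))
    return out


@pytest.fixture
def two_state_chain() -> MDPModel:
    """Deterministic 2-state chain into survival: s0 -> s1 -> survival."""
    T_phys = np.zeros((2, 1, 4))
    T_phys[0, 0, 1] = 1.0
    T_phys[1, 0, 2] = 1.0  # survival
    return make_toy_mdp(T_phys, gamma=0.9)


@pytest.fixture
def three_state_mdp() -> MDPModel:
    """Random-ish 3-state, 2-action MDP with mixed absorption odds."""
    rng = np.random.default_rng(7)
    n, A = 3, 2
    T_phys = np.zeros((n, A, n + 2))
    for s in range(n):
        for a in range(A):
            cont = rng.dirichlet(np.ones(n))
            p_abs = 0.25
            p_death = p_abs * (0.2 + 0.6 * rng.random())
            T_phys[s, a, :n] = (1 - p_abs) * cont
            T_phys[s, a, n] = p_abs - p_death
            T_phys[s, a, n + 1] = p_death
    return make_toy_mdp(T_phys, gamma=0.9)


def tiny_cohort_frame(n_stays: int = 3, n_bins: int = 10, seed: int = 0) -> pd.DataFrame:
    """Small fully-observed cohort conforming to the trajectory schema."""
    rng = np.random.default_rng(seed)
    names = DEFAULT_MANIFEST.names
    rows = []
    for i in range(n_stays):
        sex = "male" if i % 2 == 0 else "female"
        outcome = "died" if i == n_stays - 1 else "survived"
        for b in range(n_bins):
            row = {
                "stay_id": f"s{i}",
                "time_bin": b,
                "height_cm": 170.0 + i,
                "sex": sex,
                "age_years": 50.0 + i,
                "outcome": outcome,
                "extubation": False,
                "niv_start": False,
                "suppl_o2": False,
                "withdrawal": False,
                "vt_set_ml": 450.0 + 10 * b if b >= 1 else np.nan,
                "peep_cmh2o": 6.0 if b >= 1 else np.nan,
                "fio2_pct": 40.0 if b >= 1 else np.nan,
            }
            row.update({nm: float(rng.normal()) for nm in names})
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_table() -> TrajectoryTable:
    return TrajectoryTable(df=tiny_cohort_frame(), manifest=DEFAULT_MANIFEST)
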