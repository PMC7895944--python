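"""Synthetic ICU cohort generator with a known ground-truth MDP.

Every pipeline stage gets an oracle: the true transition kernel, the
true optimal and behavior policy values (closed-form linear solve), the
true latent state labels, and controlled missingness/outlier injection.

The generator draws, per (state, action), a sparse Dirichlet transition
kernel over latent physiologic states plus severity-linked absorption
into death or survival; each latent state emits the patient fingerprint
from a Gaussian whose mean is tied to the state's severity, so observed
features are informative of prognosis.  The clinician-like behavior
policy is a softmax over a noise-perturbed optimal Q with temperature
tau — mostly sensible, sometimes suboptimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mdp_policy import PolicyTable, TERMINAL_REWARD
from .state_action import ActionGrid
from .preprocessing import ideal_body_weight
from .trajectory_io import (
    EVENT_FLAG_COLUMNS,
    ONSET_BIN,
    OUTCOME_DIED,
    OUTCOME_SURVIVED,
    DEFAULT_MANIFEST,
    FeatureManifest,
    TrajectoryTable,
)

__all__ = [
    "GroundTruthMDP",
    "SimulationConfig",
    "generate_ground_truth",
    "simulate_cohort",
    "true_policy_value",
]


@dataclass
class GroundTruthMDP:
    """Known data-generating decision process.

    States 0..n-1 are latent physiologic states ordered by increasing
    severity; n and n+1 are the absorbing survival and death states.
    ``kernel[s, a]`` is the full next-state distribution (including
    absorption); ``emission_means``/``emission_sds`` define per-state
    Gaussian feature emissions in manifest space.
    """

    n_states: int
    grid: ActionGrid
    kernel: np.ndarray  # (n, A, n + 2)
    severity: np.ndarray  # (n,) in [0, 1]
    emission_means: np.ndarray  # (n, d)
    emission_sds: np.ndarray  # (n, d)
    gamma: float
    tau: float
    q_star: np.ndarray  # (n, A)
    v_star: np.ndarray  # (n,)
    behavior: PolicyTable  # over latent states
    v_behavior: np.ndarray  # (n,)
    seed: int
    manifest: FeatureManifest = field(default_factory=lambda: DEFAULT_MANIFEST)

    @property
    def survival_state(self) -> int:
        return self.n_states

    @property
    def death_state(self) -> int:
        return self.n_states + 1

    @property
    def n_actions(self) -> int:
        return self.grid.n_actions

    def optimal_actions(self) -> np.ndarray:
        return self.q_star.argmax(axis=1)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-simulation settings.

    ``max_bins`` is the post-onset horizon (18 four-hour bins = 72 h);
    ``missing_rate`` and ``mechanism`` control feature missingness
    (MCAR, or MAR triggered by another feature exceeding its median);
    ``tau`` is the behavior softmax temperature.
    """

    n_stays: int = 1000
    max_bins: int = 18
    missing_rate: float = 0.15
    mechanism: str = "mcar"  # mcar | mar
    outlier_rate: float = 0.01
    tau: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.missing_rate, self.outlier_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.mechanism not in ("mcar", "mar"):
            raise ValueError(f"unknown missingness mechanism {self.mechanism!r}")


def _solve_q(kernel: np.ndarray, gamma: float, tol: float = 1e-10) -> np.ndarray:
    """Optimal Q on the true kernel by value iteration (terminal-only rewards)."""
    n, A, _ = kernel.shape
    r_next = np.zeros(n + 2)
    r_next[n] = TERMINAL_REWARD
    r_next[n + 1] = -TERMINAL_REWARD
    R = kernel @ r_next
    V = np.zeros(n + 2)
    for _ in range(100_000):
        Q = R + gamma * (kernel @ V)
        Vn = Q.max(axis=1)
        if np.max(np.abs(Vn - V[:n])) < tol:
            V[:n] = Vn
            break
        V[:n] = Vn
    return R + gamma * (kernel @ V)


def _evaluate_policy_on_kernel(
    kernel: np.ndarray, probs: np.ndarray, gamma: float
) -> np.ndarray:
    """Exact per-state value of a policy on the true kernel (linear solve)."""
    n, A, _ = kernel.shape
    r_next = np.zeros(n + 2)
    r_next[n] = TERMINAL_REWARD
    r_next[n + 1] = -TERMINAL_REWARD
    R = kernel @ r_next
    P = np.einsum("sa,sax->sx", probs[:n], kernel)[:, :n]
    r_pi = np.einsum("sa,sa->s", probs[:n], R)
    mat = np.eye(n) - gamma * P
    if gamma == 1.0 and np.linalg.cond(mat) > 1e12:
        raise np.linalg.LinAlgError(
            "singular policy-evaluation system (gamma = 1 with a recurrent class)"
        )
    return np.linalg.solve(mat, r_pi)


def generate_ground_truth(
    n_states: int = 20,
    grid: ActionGrid | None = None,
    gamma: float = 0.99,
    tau: float = 2.0,
    dirichlet_alpha: float = 0.5,
    absorption_base: float = 0.08,
    emission_separation: float = 2.0,
    severity_weight: float = 2.5,
    action_weight: float = 4.0,
    q_perturbation: float = 2.0,
    manifest: FeatureManifest | None = None,
    seed: int = 0,
) -> GroundTruthMDP:
    """Draw a random ground-truth MDP; deterministic given seed.

    Severity increases with state index and drives both the odds of
    absorbing into death and the emission means, so the fingerprint is
    prognostic.  Per-(s, a) action quality shifts the death/survival
    split, so actions genuinely matter.  V* and the behavior policy's
    exact values are computed at construction by value iteration /
    linear solve on the true kernel.
    """
    if n_states < 2:
        raise ValueError("need at least two physiologic states")
    rng = np.random.default_rng(seed)
    grid = grid or ActionGrid.coarse()
    manifest = manifest or DEFAULT_MANIFEST
    A = grid.n_actions
    d = len(manifest)

    severity = np.linspace(0.05, 0.95, n_states)
    # one clearly best setting per state with a controlled margin; the
    # remaining actions are comparable to each other.  This keeps the
    # per-state optimum identifiable, which the recovery oracles need,
    # and mirrors the clinical picture of a protective setting standing
    # out against broadly similar alternatives.
    quality = np.empty((n_states, A))
    for s in range(n_states):
        q = rng.uniform(0.0, 0.6, size=A)
        q[rng.integers(A)] = 1.0
        quality[s] = q

    kernel = np.zeros((n_states, A, n_states + 2))
    for s in range(n_states):
        p_abs = absorption_base * (0.5 + severity[s])
        for a in range(A):
            cont = rng.dirichlet(np.full(n_states, dirichlet_alpha))
            # good actions tilt absorption away from death
            logit = severity_weight * (severity[s] - 0.5) - action_weight * (
                quality[s, a] - 0.5
            )
            p_death = p_abs / (1.0 + np.exp(-logit))
            p_surv = p_abs - p_death
            kernel[s, a, :n_states] = (1 - p_abs) * cont
            kernel[s, a, n_states] = p_surv
            kernel[s, a, n_states + 1] = p_death
    assert np.allclose(kernel.sum(axis=2), 1.0, atol=1e-9)

    # severity-linked, well-separated Gaussian emissions
    direction = rng.normal(size=d)
    direction /= np.linalg.norm(direction)
    means = (
        emission_separation * np.sqrt(d) * np.outer(severity - 0.5, direction)
        + emission_separation * rng.normal(size=(n_states, d))
    )
    sds = np.full((n_states, d), 1.0)

    q_star = _solve_q(kernel, gamma)
    v_star = q_star.max(axis=1)

    if tau <= 0:
        probs_latent = np.zeros((n_states, A))
        probs_latent[np.arange(n_states), q_star.argmax(axis=1)] = 1.0
    else:
        perturbed = q_star + q_perturbation * rng.normal(size=q_star.shape)
        z = (perturbed - perturbed.max(axis=1, keepdims=True)) / tau
        probs_latent = np.exp(z)
        probs_latent /= probs_latent.sum(axis=1, keepdims=True)
    probs = np.zeros((n_states + 2, A))
    probs[:n_states] = probs_latent
    probs[n_states:] = 1.0 / A  # arbitrary on absorbing states
    behavior = PolicyTable(probs=probs, kind="behavior-empirical")
    v_behavior = _evaluate_policy_on_kernel(kernel, probs, gamma)

    return GroundTruthMDP(
        n_states=n_states,
        grid=grid,
        kernel=kernel,
        severity=severity,
        emission_means=means,
        emission_sds=sds,
        gamma=gamma,
        tau=tau,
        q_star=q_star,
        v_star=v_star,
        behavior=behavior,
        v_behavior=v_behavior,
        seed=seed,
        manifest=manifest,
    )


def true_policy_value(
    mdp: GroundTruthMDP, policy: PolicyTable, initial: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Exact value of a policy over latent states on the true kernel.

    ``policy.probs`` must cover the latent states (extra terminal rows
    are ignored).  Returns (initial-distribution-weighted scalar,
    per-state values); the default initial distribution is uniform.
    """
    probs = policy.probs
    if probs.shape[0] < mdp.n_states:
        raise ValueError("policy does not cover all latent states")
    if probs.shape[1] != mdp.n_actions:
        raise ValueError("policy action dimension mismatch")
    V = _evaluate_policy_on_kernel(mdp.kernel, probs, mdp.gamma)
    if initial is None:
        initial = np.full(mdp.n_states, 1.0 / mdp.n_states)
    return float(initial @ V), V


def _sample_setting_in_bin(
    grid: ActionGrid, dim: str, bin_idx: int, rng: np.random.Generator
) -> float:
    lo, hi = grid.bin_range(dim, bin_idx)
    if np.isinf(hi):
        width = grid.edges[dim][-1] - grid.edges[dim][-2] if len(grid.edges[dim]) > 1 else lo or 1.0
        hi = lo + width
    lo_eff = lo if bin_idx > 0 else min(hi, lo + 0.1 * (hi - lo))
    return float(rng.uniform(lo_eff, hi))


def simulate_cohort(
    mdp: GroundTruthMDP, sim: SimulationConfig
) -> tuple[TrajectoryTable, pd.DataFrame]:
    """Roll out stays under the behavior policy and emit a schema-conforming
    cohort table plus the hidden truth.

    Each stay starts in a random latent state, steps under the behavior
    policy until absorption or ``max_bins``, emits features from the
    per-state Gaussians, and writes raw ventilator settings sampled
    uniformly within the behavior action's bin ranges (tidal volume is
    scaled by the stay's ideal body weight).  Missingness and spike
    outliers are injected afterwards.  The hidden-truth frame carries
    the latent state labels, actions, outcome and realized return.
    """
    rng = np.random.default_rng(sim.seed)
    grid = mdp.grid
    names = mdp.manifest.names
    d = len(names)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    for i in range(sim.n_stays):
        stay_id = f"stay{i:05d}"
        sex = "male" if rng.random() < 0.6 else "female"
        height = float(rng.normal(175 if sex == "male" else 162, 7))
        height = max(height, 140.0)
        age = float(rng.uniform(19, 95))
        ibw = ideal_body_weight(sex, height)
        s = int(rng.integers(0, mdp.n_states))
        states, actions = [], []
        outcome = None
        for t in range(sim.max_bins):
            a = int(rng.choice(mdp.n_actions, p=mdp.behavior.probs[s]))
            states.append(s)
            actions.append(a)
            nxt = int(rng.choice(mdp.n_states + 2, p=mdp.kernel[s, a]))
            if nxt == mdp.survival_state:
                outcome = OUTCOME_SURVIVED
                break
            if nxt == mdp.death_state:
                outcome = OUTCOME_DIED
                break
            s = nxt
        if outcome is None:
            # still ventilated at the window edge: the 90-day outcome is
            # the eventual absorption of the latent chain, continued under
            # the behavior policy beyond the observation window
            s_cont = s
            for _ in range(1000):
                a_cont = int(rng.choice(mdp.n_actions, p=mdp.behavior.probs[s_cont]))
                nxt = int(rng.choice(mdp.n_states + 2, p=mdp.kernel[s_cont, a_cont]))
                if nxt == mdp.survival_state:
                    outcome = OUTCOME_SURVIVED
                    break
                if nxt == mdp.death_state:
                    outcome = OUTCOME_DIED
                    break
                s_cont = nxt
            if outcome is None:
                outcome = OUTCOME_SURVIVED
        L = len(states)
        ret = (TERMINAL_REWARD if outcome == OUTCOME_SURVIVED else -TERMINAL_REWARD) * (
            mdp.gamma ** (L - 1)
        )
        # pre-onset context bin (bin 0) emitted from the initial state
        for t in range(-1, L):
            st = states[max(t, 0)]
            feats = rng.normal(mdp.emission_means[st], mdp.emission_sds[st])
            row = {
                "stay_id": stay_id,
                "time_bin": ONSET_BIN + t,
                "height_cm": height,
                "sex": sex,
                "age_years": age,
                "outcome": outcome,
                "extubation": False,
                "niv_start": False,
                "suppl_o2": False,
                "withdrawal": False,
            }
            row.update(dict(zip(names, feats)))
            if t >= 0:
                a = actions[t]
                bins = grid.unflatten(a)
                dims = grid.dims
                vt_kg = _sample_setting_in_bin(grid, dims[0], bins[0], rng)
                row["vt_set_ml"] = vt_kg * ibw
                row["peep_cmh2o"] = _sample_setting_in_bin(grid, dims[1], bins[1], rng)
                row["fio2_pct"] = _sample_setting_in_bin(grid, dims[2], bins[2], rng)
                truth_rows.append(
                    {
                        "stay_id": stay_id,
                        "time_bin": ONSET_BIN + t,
                        "true_state": st,
                        "action": a,
                        "outcome": outcome,
                        "return": ret,
                    }
                )
            else:
                row["vt_set_ml"] = np.nan
                row["peep_cmh2o"] = np.nan
                row["fio2_pct"] = np.nan
            rows.append(row)

    df = pd.DataFrame(rows)
    feat_vals = df[names].to_numpy(float)

    if sim.outlier_rate > 0:
        spike = rng.random(feat_vals.shape) < sim.outlier_rate
        col_sd = feat_vals.std(axis=0)
        feat_vals = np.where(
            spike, feat_vals + 12.0 * col_sd * np.sign(rng.normal(size=feat_vals.shape)),
            feat_vals,
        )

    if sim.missing_rate > 0:
        if sim.mechanism == "mcar":
            miss = rng.random(feat_vals.shape) < sim.missing_rate
        else:  # MAR: missingness of each feature driven by the previous column
            driver = np.roll(feat_vals, 1, axis=1)
            med = np.median(driver, axis=0)
            p = np.where(driver > med, min(1.0, 2 * sim.missing_rate), 0.0)
            miss = rng.random(feat_vals.shape) < p
        feat_vals = np.where(miss, np.nan, feat_vals)

    df[names] = feat_vals
    table = TrajectoryTable(df=df, manifest=mdp.manifest)
    return table, pd.DataFrame(truth_rows)
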