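# ventrl

Offline reinforcement learning for mechanical-ventilation settings.

Suboptimal ventilator settings — tidal volume (Vt), positive
end-expiratory pressure (PEEP), and inspired-oxygen fraction (FiO2) —
cause ventilator-induced lung injury and excess mortality in
critically-ill patients, yet the "right" settings depend on dozens of
evolving clinical variables.  `ventrl` is for researchers who want to
learn dynamically optimized ventilation policies from retrospective ICU
time series and evaluate them *without deploying them*, purely from
data collected under usual care.

## The model

Care is cast as a Markov decision process ⟨S, A, T, R, γ⟩ on 4-hour
bins over −4 h..+72 h around ventilation onset:

- **S** — k-means clusters of the z-scored patient fingerprint
  (44 features by default), default k = 650, plus two absorbing
  terminal states (survival, death);
- **A** — a 7×7×7 grid over Vt/kg ideal body weight, PEEP, and FiO2
  (343 discrete actions; IBW = 50 + 0.91·(height−152.4) kg for males,
  45.5 + 0.91·(height−152.4) for females);
- **T** — empirical transition frequencies, with actions observed fewer
  than a minimum count per state masked ineligible;
- **R** — terminal-only: +100 for survival, −100 for death, collapsed
  to R(s,a) = Σ_s′ T(s,a,s′)·R(s,s′,a);
- **γ** — 0.99 by default.

The optimal policy comes from value iteration (or tabular Q-learning;
both fixed points agree).  Candidate policies are scored off-policy by
weighted importance sampling (WIS)

    V̂ = Σᵢ wᵢGᵢ / Σᵢ wᵢ,  wᵢ = Πₜ πₑ(aₜ|sₜ)/π_b(aₜ|sₜ),

with a variance-reduced per-decision variant as the default, and
percentile confidence bounds from trajectory bootstrap.  Model
selection repeats the whole learning cycle over many random 60/20/20
splits and keeps the model maximizing the 95 % bootstrap lower bound of
the learned policy's value.  A synthetic cohort generator with a known
ground-truth MDP (exact V\*, true state labels, controlled MAR/MCAR
missingness and outliers) provides oracles for every stage.

See `docs/methods.md` for assumptions, parameter rationale, and
limitations.

## Worked example

Simulate a small synthetic cohort, learn a policy, and compare it to
the simulated clinician:

```sh
ventrl --seed 2 --out-dir out run-all --stays 150 --states 4 --models 2 --bootstrap 30
```

prints

```
selected model 0: AI=78.7 clinician=54.5 random=46.5
report: out/ensemble.json
```

The three numbers are estimated performance returns on the validation
split, on the −100..+100 scale set by the terminal rewards: the
bootstrap-selected learned policy (78.7) is estimated to outperform the
empirical clinician policy (54.5), and both beat acting uniformly at
random over the eligible actions (46.5).  `out/ensemble.json` holds the
point estimates, bootstrap lower/upper bounds at 90 %/95 %, effective
sample sizes, and the held-out test re-evaluation of the selected
policy.

The same steps are available piecemeal (`simulate`, `preprocess`,
`fit`/`evaluate`, `analyze`) and as library calls:

```python
from ventrl import (generate_ground_truth, simulate_cohort, SimulationConfig,
                    preprocess_cohort, run_ensemble, load_config)

gt = generate_ground_truth(n_states=4, seed=0)
table, truth = simulate_cohort(gt, SimulationConfig(n_stays=300, seed=1))
cfg = load_config(None, n_states=4, n_models=3, n_bootstrap=100)
events, diagnostics = preprocess_cohort(table, cfg)
result = run_ensemble(events, gt.grid, cfg, seed=0)
print(result.selected.ai.estimate, result.selected.clinician.estimate)
```

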