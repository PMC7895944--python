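# Methods

`ventrl` learns dynamically optimized mechanical-ventilation settings —
ideal-body-weight-adjusted tidal volume (Vt, mL/kg), positive
end-expiratory pressure (PEEP, cmH2O), and inspired-oxygen fraction
(FiO2, %) — from retrospective ICU time series, and evaluates the
learned policy off-policy against the clinicians who generated the
data.  This note documents the model, the main numerical and design
choices, and what the synthetic testbed does and does not establish.

## The decision process

Patient care is modeled as a finite Markov decision process
⟨S, A, T, R, γ⟩ on 4-hour time steps covering −4 h to +72 h around the
onset of a volume-controlled ventilation event.

**States.** The patient "data fingerprint" (44 time-series features by
default: vitals, blood gases, chemistry, hematology/coagulation, fluid
balance, Glasgow Coma Scale) is z-scored on the training split and
clustered with k-means (default k = 650; BIC/AIC selection over
candidate k is available but off by default, since the published
configuration fixes k while the selection procedure motivates it).  Two
absorbing terminal states — survival and death — are appended *after*
the k physiologic states, so the total state count is k + 2.  State
membership of new data is the nearest centroid in scaled space, ties to
the lowest index.

The BIC used for `select_k` is the spherical-Gaussian-mixture criterion
with shared variance and free mixing proportions (the X-means form):
the multinomial cluster-size term is required — with the fit term
alone, the criterion decreases monotonically in k on well-separated
data and never selects the generating cluster count.

**Actions.** Each of the three setting dimensions is cut into 7
half-open bins [lower, upper), the last bin open-ended — Vt/kg edges
(0, 2.5, 5, 7.5, 10, 12.5, 15), PEEP (0, 5, 7, 9, 11, 13, 15), FiO2
(0, 30, 35, 40, 45, 50, 55) — giving 343 flat actions.  Values below
the lowest printed edge (e.g. FiO2 < 25 %) fold into the first bin.
Tidal volume is normalized by predicted ideal body weight,
50 + 0.91·(height − 152.4) kg for males and 45.5 + 0.91·(height −
152.4) for females.  Extra dimensions (e.g. respiratory rate) can be
appended with user-supplied edges; the grid size multiplies
accordingly.

**Rewards.** Terminal-only: +100 on the transition into survival, −100
into death, 0 elsewhere.  The three-dimensional reward R(s, s′, a) is
collapsed against the estimated transition tensor to R(s, a) =
Σ_s′ T(s, a, s′)·R(s, s′, a).  With γ ≤ 1 every return and Q value
lies in [−100, 100] (window-truncated estimates can exceed the
infinite-horizon truth but never the bound).

**Discount.** γ defaults to 0.99: on a 4-h grid this weights outcomes
~3 days out at 0.99¹⁸ ≈ 0.84, appropriate for a mortality endpoint
observed largely beyond the 72-h window.

## Estimation and solving

T(s, a, s′) = N(s, a, s′)/N(s, a) by maximum likelihood.  Actions with
N(s, a) below a minimum count are masked ineligible everywhere
(policies place zero mass on them).  The library default is 5
observations, sized for the sparse published configuration
(650 × 343, where most pairs have very few visits).  **This threshold
must scale with the per-state sample size**: in dense configurations
(few states and actions, ~10³ decision instances per state) a 5-visit
action estimate is dominated by sampling luck, and the greedy argmax
systematically exploits it — the familiar optimizer's curse of offline
RL.  The synthetic end-to-end studies therefore use a threshold of
about 10 % of the expected per-state decision instances in a training
split (100 at 20 states × 8 actions × 5000 stays).

Two solvers ship and agree on small MDPs: model-based value iteration
(default; Bellman residual < 1e−8) and sample-based tabular Q-learning
(replay over observed transitions, harmonic per-(s, a) learning rate
α₀/(1 + n/decay)).  Greedy ties break to the lowest flat action index.
The clinician is evaluated both model-free (on-policy TD(0)/SARSA over
the observed tuples) and model-based (linear policy evaluation of the
empirical behavior policy π_b(a|s) = N(s, a)/N(s) on the estimated
MDP); scalar "performance returns" weight state values by the
empirical distribution of trajectory-initial states.

## Off-policy evaluation

Weighted importance sampling compares a candidate policy π_e to the
behavior policy without deploying it.  Because a deterministic greedy
target gives degenerate weights, the learned policy is ε-softened over
the eligible actions (default ε = 0.01) before evaluation.  Two
estimators:

- `trajectory`: w_i = Π_t π_e/π_b, estimate Σ w_i G_i / Σ w_i;
- `stepwise` (default): the consistent per-decision variant — per-step
  self-normalized cumulative weights with per-step discounted rewards.
  Terminated trajectories are kept in every later step's normalization
  at their final cumulative weight (conceptually: an absorbing state
  with importance ratio 1 and reward 0).  Dropping them instead makes
  the estimator inconsistent and unbounded.  This estimator is a
  documented stand-in for a variance-reduced ("control-variate") WIS
  whose exact published form is unspecified; outputs are labeled with
  the estimator used.

Confidence bounds come from percentile bootstrap over whole
trajectories (default B = 1000), deterministic given the seed.

## Ensemble model selection

Each of `n_models` (default 500) candidates draws a fresh random
60/20/20 train/validation/test split of the events; clustering and MDP
estimation use train only (the scaler is frozen there, so validation
and test rows never leak into it); bootstrap-WIS of the softened
learned policy, the clinician policy, and the uniform-over-eligible
random policy runs on validation.  The selected model maximizes the
95 % bootstrap lower bound of the learned policy's estimate and is
re-evaluated on its held-out test split.  The running best-so-far
criterion curve is emitted with the up-to-the-point cumulative standard
deviation across models.

## Preprocessing

A ventilation event starts at the first documented set tidal volume,
continues while any of the three settings is documented within two
sample periods (8 h), and ends at extubation, the start of non-invasive
ventilation or supplemental oxygen (the event flag is taken literally),
or when the 8-h continuation rule lapses — the event ends at the last
documented setting, not at the end of the bridged gap.  Inclusion:
age > 18, no treatment withdrawal in the window, documented outcome,
duration ≥ 24 h (6 post-onset bins); only the first qualifying event
per stay; clipped to the −4 h..+72 h window.

Order of operations: Tukey outlier removal (fences Q1 − 1.5·IQR,
Q3 + 1.5·IQR; an optional central-90 % frequency filter is off by
default since how the two filters compose is not fixed) precedes
sample-and-hold, so held values are never outliers.  The hold limit per
feature is the median inter-measurement gap within stays (fallback 2
bins, the event-continuation horizon).  Events still > 50 % missing
after holding are discarded; the rest are imputed by kNN (k = 3,
Euclidean distance on z-scored coordinates; donor pool a deterministic
strided subsample capped at 2000 rows, since exact all-pairs search is
quadratic in cohort size), by iterative low-rank SVD completion
(rank min(10, d/4), tolerance 1e−4), or by column means.  Observed
cells are never altered.

The missingness diagnostic tests, per feature, whether its missingness
indicator is associated with the observed values of the other features
(Mann-Whitney per other feature, Bonferroni-corrected minimum): small
p-values indicate missingness at random (MAR) driven by observed data
rather than MCAR.  The choice of test is this package's own.

## The synthetic testbed

`ventrl.synthetic` generates cohorts from a known ground-truth MDP so
that every stage has an oracle: the true kernel, the true latent state
per bin, closed-form V* and behavior values (value iteration / linear
solve at construction), and controlled missingness and outliers.

Structure: n latent states ordered by severity in [0, 1]; per (s, a) a
sparse Dirichlet(0.5) continuation over latent states plus absorption
with base probability 0.08·(0.5 + severity) per 4-h bin (mean event
duration ≈ 50 h, matching an included-cohort of ≥ 24-h events in a
72-h window).  The absorbed mass splits into death vs survival through
a logistic in severity (weight 2.5) minus action quality (weight 4).
Action quality per state is one clearly best action (quality 1.0)
against comparable alternatives (uniform on [0, 0.6]): the per-state
optimum is uniquely identifiable with a controlled margin, which the
policy-recovery oracles require — with i.i.d. uniform qualities the
top two actions are frequently true near-ties (value gaps < 0.5 return
points) and exact-argmax recovery is ill-posed at any sample size.
Emissions are Gaussian per latent state with severity-linked,
well-separated means (so the fingerprint is prognostic); the behavior
policy is softmax((Q* + 2·noise)/τ) with τ = 2 — mostly sensible,
sometimes suboptimal, with every action receiving some visits.  Stays
still ventilated at the window edge continue the *latent* chain under
the behavior policy until absorption, and that eventual outcome is
recorded — the analogue of 90-day mortality observed beyond the
72-hour observation window.  (An action-independent censoring coin
would decouple the recorded outcome from within-window treatment and
bias action rankings.)

What passing the synthetic studies shows: the pipeline recovers
well-separated latent states (ARI ≥ 0.8 at 20 states / 5000 stays),
identifies uniquely optimal actions where the data supports them, and
its selected policy weakly improves on the behavior policy in
ground-truth value.  What it does not show: performance under weak
state separability, near-tied treatment effects, unmeasured
confounding, non-stationary physiology within a stay, or feature
distributions resembling real ICU charts — real charted data have none
of the generator's Gaussian regularity.

## Numerical conventions and degenerate inputs

Half-open bins everywhere; argmax ties to the lowest index; terminal
states are absorbing with zero onward reward and value 0; unvisited
states receive a uniform behavior policy (logged); trajectories
stepping outside the behavior policy's support get zero WIS weight
(logged), and an all-zero-weight evaluation raises rather than
returning a number; constant state sequences report a flagged rank
correlation of 0; a constant regression target yields all-zero feature
importances with a warning.

Confidence-bound convention: `lower[q]` and `upper[q]` are *one-sided*
bounds at level q (the (1−q)- and q-quantiles of the bootstrap
distribution), matching the "90 % lower bound" language of
model-selection curves; the central 90 % interval is therefore
[`lower[0.95]`, `upper[0.95]`].  Measured on a 4-state toy process
against closed-form values, the per-decision estimator is unbiased and
the central 90 % interval covers at ~86 % — percentile intervals run
mildly narrow when importance weights are heavy-tailed (a target
policy far from the behavior policy over long horizons), a known
limitation worth remembering when ε is small.

Study sizes used in the shipped tests (20 latent states, 8 actions,
5000 stays; 5-candidate ensembles with 200 bootstrap resamples;
200-replication coverage runs at 2000 trajectories and 300 resamples
each) are the package's default small-study configuration.
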