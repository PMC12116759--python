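# Methods

This note documents the models and procedures implemented in `glycorl`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic experiments do and do not show.

## The decision problem

Hourly regular-insulin dosing in the first 24 ICU hours after cardiac
surgery is cast as a Markov decision process. Time starts at the first
glucose measurement; episodes are at most 24 hourly steps. The state is a
normalized feature vector; the action is a continuous dose in [0, 10]
units (doses above 10 U/h are rare and clipped as a safety cap); the
reward is a function of the glucose observed at the *next* hour.

**Reward timing.** The reward for action `a_t` at state `s_t` is computed
from the glucose at `s_{t+1}` — the action's consequence. This is the only
causal reading of an hourly dose-response loop: the dose given at hour t
cannot influence the glucose already measured at hour t. The terminal
state of an episode contributes no reward (there is no observed
consequence). Glucose outside 20–600 mg/dL is rejected as a data error,
not clipped: values there are physiologically implausible and indicate an
upstream unit or transcription problem.

**Reward shape.** Five linear pieces, continuous at every boundary
(70/140/180/220 mg/dL), with a +0.2 plateau on the 140–180 mg/dL target
band and a −1 floor outside 70–220. The magnitude is deliberately small
for optimization stability. The quadratic penalty 0.001·a² discourages
large single-hour corrections; it applies to the executed continuous
action during training (the quantity the learner optimizes), while
reported recommendations are integers.

## State construction

- Four glucose lags. Lags reaching before the first measurement are
  backfilled with the earliest observed glucose, not zero: 0 mg/dL is
  physiologically absurd and would corrupt min–max normalization.
- Hourly deltas over the same window, and the response ratio
  Δglucose / max(dose, 0.1) — the change per unit of the *preceding*
  hour's dose, a crude observable signature of insulin sensitivity. The
  0.1 U floor keeps the ratio finite at zero dose.
- The hour index is a state feature. Beyond its clinical meaning
  (stress-response decay), it is required for correctness of value
  estimation: episodes truncate at 24 h, so values are time-dependent, and
  a stationary Q-function can only represent them if time is observable.
  Removing it produced a measured ~0.15 systematic bias in fitted-Q
  evaluation on tabular benchmarks.

## Preprocessing rules

- Exclusions (death within 24 h; ambiguous medication records; no glucose
  in the first three hours; other short-acting insulins) remove patients
  before any statistics are computed. The tally attributes each patient to
  the **first** matching criterion in that fixed order — the order is a
  declared convention for reproducible accounting.
- Features missing in **strictly more than 30%** of training patient-hours
  are dropped ("over 30%" read literally). Remaining gaps: forward fill
  within patient, then k-NN imputation (k = 5). The imputer is fit on the
  training split only, so held-out rows are imputed from training donors;
  distances are computed on features standardized by training min–max so
  no scale dominates. Hours with no recorded insulin are dose 0, not
  missing: an unrecorded dose is an ungiven dose.
- Min–max normalization to [0, 1] uses training-split statistics;
  out-of-range held-out values clip to the boundary. Constant training
  features are dropped. Splits are at the patient level (85/15), and the
  multi-model protocol trains each seed on an independent 80% patient
  subsample of the training split.

## The learner

Conservative Q-learning with an implicit-quantile critic, on compact MLPs.

| parameter | default | note |
|---|---|---|
| discount γ | 0.67 | effective horizon 1/(1−γ) ≈ 3 h; glucose moves fast, so long-horizon credit is noise |
| batch size | 256 | |
| actor / critic LR | 1e−4 / 3e−4 | Adam |
| hidden layers | 3 × 512 | publication scale; desk-scale runs use 2 × 64 |
| dropout | 0.1 | training only |
| CQL weight α | 5.0 | library default; desk-scale runs use 1.0 |
| quantile samples (online/target) | 8 / 8 | uniform τ per step |
| τ embedding | 64 cosine features | |
| Huber κ | 1.0 | |
| OOD action samples | 10 uniform + 4 actor | candidates for the conservatism term |
| target sync | Polyak 0.005 | |
| return-sampling temperature | 1.0 (desk 2.0) | softmax over episode discounted returns |

The CQL weight, quantile-sample counts, embedding size, Huber κ, sync
rate, OOD sample count and entropy handling are not pinned by any
published value for this problem; defaults follow the reference CQL/IQN
literature and every one is exposed in `AgentConfig`.

**Batch sampling.** Transitions are drawn with probability ∝
softmax(episode return / temperature): high-return trajectories shape the
policy more, preventing the conservatism term from regularizing toward
low-return behavior. Temperature → ∞ recovers uniform sampling; the
mechanism is declared and ablatable since only its purpose, not its form,
is fixed by precedent.

**Conservatism.** The penalty is logsumexp over candidate doses (the data
dose, uniform draws on [0, 10], actor samples) of the expected Q minus the
expected Q at the data dose, normalized by the candidate count. Two
consequences verified in the test suite: out-of-support doses are pushed
below both the best in-data dose and an α = 0 ablation; and in-data Q
acquires a small *upward* bias at large α — tests probing the shape of the
return distribution therefore use a small α, since they test the
distributional critic, not conservatism.

**Actor.** A squashed Gaussian, a = 5·(tanh(u) + 1), entropy-regularized,
deterministic mean at deployment (clip to [0, 10], round half-up to whole
units). The conservative critic is multimodal in the dose, and pure
gradient ascent on it stalls in local optima (measured: rollout value
−0.32 for the gradient-only actor vs −0.08 for the critic's greedy
whole-unit policy on the same critic). A distillation term — squared
distance between the actor mean and the critic's best dose on the integer
grid, weight `greedy_distill_coeff` = 1, ablatable to 0 — closes most of
that gap while keeping the deployed interface (actor mean) unchanged.

## Off-policy evaluation and selection

FQE fits a non-distributional MLP critic (2 × 256 default; 2 × 64 at desk
scale) by iterated Bellman regression r + γ·Q(s′, π(s′)) with a
periodically hard-synced target network; the per-episode value is
Q(s₀, π(s₀)) at the episode's first state. The clinician value is the
empirical discounted return — on on-policy data the empirical estimator is
unbiased, so fitting a behavior model would only add error. Bootstrap CIs
resample **episodes** (patients), not timesteps: timesteps within a
patient are strongly dependent. Model selection keeps the candidate with
the highest lower 95% bound (ties: lowest index) — pessimistic selection
suited to the high seed-to-seed variance of offline RL. FQE aborts with
diagnostics if the loss goes non-finite or |Q| exceeds ten times the
largest attainable discounted return (1.1/(1−γ)).

## The synthetic cohort

Dynamics are a deliberately simple linear-Gaussian stress model:

    G[t+1] = clip(G[t] + drive·e^{−t/30} − sens·(a[t] + 0.3·a[t−1])
                  + dextrose + ε, 20, 600),   ε ~ N(0, 10 mg/dL)

with a right-skewed endogenous stress drive (most patients mild, a strong
hyperglycemic tail; diabetics shifted up), insulin sensitivity uniform on
2.5–9 mg/dL per unit, a 30% one-hour dose carryover (IV regular insulin
acts fast; the tail is folded into one step), and sporadic IV dextrose
events. There is no meal model (patients are NPO in this window) and no
insulin compartment kinetics: the simulator exists to exercise and
ground-truth the learning machinery, and ground truth must be computable.

The behavior policy combines a reactive sliding scale (0 U below
150 mg/dL, then 1/2/4/6/8 U per ascending 40 mg/dL band, 10 U from
350 mg/dL) with an anticipatory basal component: after a 2-hour
observation window clinicians add their estimate of the patient's hourly
requirement, misestimated by a lognormal factor (σ = 0.35), withheld below
115 mg/dL and capped at 6 U. 15% of intended doses are omitted and 25%
jittered by ±1 U. The basal component exists because a purely reactive
scale cannot reproduce the joint calibration targets of real cohorts —
≈2.2 U/h mean insulin alongside ≈48% hyperglycemia and ≈8% hypoglycemia;
its delays, misestimates and omissions are exactly the suboptimality the
learner exploits.

Default generator parameters were calibrated once against those cohort
targets and then frozen; at n = 2000 they give 53% of patients with a
hyperglycemic event, 5–6% with a hypoglycemic one, mean hourly insulin
2.1 U with skewness 1.4. A small fraction of patients carries each
exclusion flag so the filters have work to do. The covariate schema
(~28 features) is a stand-in for the 70+ features of real extracts; the
pipeline is schema-driven so a richer schema drops in. Dynamics noise and
behavior-policy randomness use separate seeded streams, so the same seed
exposes *identical* virtual patients and noise to any policy — rollout
comparisons are paired.

What passing tests show: the machinery (reward, pipeline, learner,
estimator, selection) is correct and can find in-support improvements
over an imperfect behavior policy when one exists. What they do not show:
performance on real ICU dynamics — the linear-Gaussian model has no
receptor kinetics, no measurement artifacts, and a far smaller feature
set than real extracts.

## Problem sizes

Desk-scale experiments use compact settings chosen so a full run completes
on one CPU: the headline-ordering experiment trains 3 models for 4500
gradient steps each on 80% subsamples of a 500-patient cohort with 2 × 64
networks, batch 128, α = 1, temperature 2; FQE uses 2 × 64 networks for
3000–4000 steps; tabular FQE benchmarks use 20 random MDPs (≤5 states,
3 actions, horizon 10). Publication-scale defaults (3 × 512, batch 256,
10k+ steps, 200 models, 10,000 bootstrap resamples) remain the library
defaults and are what a user with a real cohort should start from.

## Known limitations

- The simulator's linearity means the learned policies' clinical realism
  is untested; only the machinery is validated.
- FQE carries function-approximation bias (~0.05 on tabular benchmarks at
  desk scale); CIs reflect sampling uncertainty only, not estimator bias.
- The CQL candidate set omits the importance-weighting correction of the
  original formulation; with uniform + actor candidates this changes the
  penalty by a state-independent offset absorbed in α.
- Permutation importance measures dose sensitivity to marginal
  permutation; unlike coalitional (Shapley-type) attribution it can split
  credit among correlated features (the four glucose lags especially).
- The rollout adapter feeds the policy training-set midpoints for the few
  hourly labs the simulator does not expose at decision time; learned
  policies lean on glucose history and statics, so this mainly adds noise.
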