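# revlearn

Simulation and analysis toolkit for **three-armed probabilistic
reversal-learning experiments** — the kind of task used to ask how primates
assign credit for rewards to the choices that caused them, and how that
ability changes after focal brain lesions (e.g. to the magnocellular
mediodorsal thalamus).

On each trial a subject picks one of three stimuli and is rewarded with a
stimulus-specific probability.  In *varying* schedules the probabilities
drift and the identity of the best option reverses mid-session; in *fixed*
schedules they are constant at graded overall yields.  The package
provides, for anyone who runs or models such tasks:

- **Task environments** — generators for the drifting 300-trial schedules
  (with the reversal at trial 150) and the constant 150-trial schedules
  with 1 : 0.75 : 0.5 yield scaling, a trial loop for arbitrary agent
  policies, 20-trial moving-window reward likelihoods, and per-trial
  best-option labels (`V1_sch`).
- **Synthetic agents** — a Rescorla–Wagner control learner, a lesion
  mechanism that degrades credit assignment for recently-switched-to
  options (an eligibility-trace account), and a planted-kernel agent that
  provides ground truth for the regression analysis; plus a cohort
  simulator mirroring the 7-control / 3-lesion, 5-sessions-per-schedule,
  pre/post design.
- **Model fitting** — maximum-likelihood estimation of the learning rate
  α (and softmax inverse temperature β) with values
  `V ← V + α(r − V)` and choice `P(c) ∝ exp(βV_c)`, and subjective
  best-option labels (`V1_RL`).
- **The credit-assignment kernel** — the lagged choice × outcome logistic
  regression: for each stimulus, 36 EVs coding every combination of the
  choice made *i* trials ago and the outcome *j* trials ago (i, j = 1..6;
  25 of interest, 11 confounds), combined across stimuli by the
  inverse-covariance-weighted mean
  `β̂ = (Ĉ_A⁻¹+Ĉ_B⁻¹+Ĉ_C⁻¹)⁻¹(Ĉ_A⁻¹β̂_A+Ĉ_B⁻¹β̂_B+Ĉ_C⁻¹β̂_C)`,
  and partitioned into contingent (diagonal) and spread-of-effect
  (off-diagonal) components.
- **Behavioral metrics** — outcome-conditioned switch/stay rates split at
  the reversal, A_kB run-history tables, choice-frequency repeat tables,
  trials-to-criterion (≥65% best-option choices over 20 trials), latency
  stay/switch comparisons, and fixed-schedule EARLY LOW / EARLY HIGH
  classification.
- **IO and CLI** — tidy TSV session/schedule formats, YAML cohort
  configs, and a `revlearn` command with `simulate-schedule`,
  `simulate-session`, `simulate-cohort`, `fit-rl`, `kernel`, `metrics`
  and `report` verbs.

## Worked example

```python
import revlearn as rl
from revlearn.agents import AgentParams, RWPolicy
from revlearn.metrics import switch_stay_table, trials_to_criterion

sched = rl.generate_varying_schedule("stable", seed=1)   # 300 trials, reversal at 150
agent = RWPolicy(AgentParams(alpha=0.3, beta_sm=5.0))
session = rl.play_session(sched, agent, seed=42, subject_id="C1")

labels = rl.v1_sch_labels(sched)
print("trials to criterion:",
      trials_to_criterion([session], [labels]).per_session.criterion_trial.iloc[0])
print("after reversal:",
      trials_to_criterion([session], [labels],
                          segment="post_reversal").per_session.criterion_trial.iloc[0])
print(switch_stay_table([session])[["prior_outcome", "n_events", "p_switch"]]
      .to_string(index=False))
fit = rl.fit_learning_rate([session])
print(f"alpha_hat={fit.alpha_hat:.3f}  beta_sm_hat={fit.beta_sm_hat:.2f}")
```

prints

```
trials to criterion: 20
after reversal: 24
prior_outcome  n_events  p_switch
       reward       190  0.194737
    no_reward       109  0.522936
alpha_hat=0.229  beta_sm_hat=5.17
```

The agent reaches the 65%-best-option criterion at trial 20 (the earliest
possible with a trailing 20-trial window) and re-reaches it 24 trials
after the reversal; it switches far more often after unrewarded than
rewarded choices (win-stay / lose-shift), and refitting the generative
model to this single session recovers the learning rate to within ~0.07
of the true 0.3 (five sessions tighten this considerably).

A full cohort analysis — learning-rate fits, kernels, and every metric
table — is one call:

```bash
revlearn report --seed 1 --out report_dir/
```

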