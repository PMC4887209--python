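# Methods

`revlearn` models and analyzes behavior on a three-option probabilistic
("three-armed bandit") learning task of the kind used to study
reward-guided decision-making in macaques before and after thalamic
lesions.  Because trial-level animal data are not distributed with the
package, every analysis is exercised on synthetic sessions from simulated
agents whose generative structure matches the task design.  This note
records the models, the defaults and why they were chosen, and what the
synthetic-data results do and do not establish.

## Task environments

Each trial offers three stimulus options; choosing option *c* on trial *t*
yields reward 1 with probability `p[t, c]`, drawn independently of the
other two options, and unchosen rewards are never held over.

**Varying schedules** (`stable`, `variable`) have 300 trials.  Option
probabilities follow bounded, lightly smoothed Gaussian random walks
confined to non-overlapping bands: the initially best option (index 0)
lives in [0.55, 0.90] for trials 1–150, the eventual best option (index 1)
in [0.15, 0.50], and the third option in [0.05, 0.35].  After trial 150
(the reversal) options 0 and 1 swap bands, so the identity of the best
option changes exactly once.  The two kinds share every random component
except option 0's pre-reversal trace: near-constant around 0.75 under
`stable` (step s.d. 0.0015), strongly fluctuating under `variable`
(0.035).  This reproduces the published design property that the two
schedules differ only in the best option's reward probability during
initial learning.  Exact published probability traces are available only
graphically, so the generator produces a parametric family with the same
structural constraints; digitized schedules can be supplied via the
schedule-TSV loader.

**Fixed schedules** have 150 trials of constant probabilities.  The base
probabilities are not printed in the source design, so the package ships a
configurable default of (0.8, 0.5, 0.2); level 2 scales all three by 0.75
and level 3 by 0.5, preserving the option ratio while changing absolute
yield — the properties the analyses depend on.

**Labels.**  The objectively best option per trial (`V1_sch`) is the
argmax of each option's probability smoothed with a 20-trial moving window
(±10 trials, truncated at session edges; a trailing alignment is available
as an option).  Ties break to the lowest option index.  Because the
probability bands of the best and runner-up options never overlap, the
smoothed traces cross exactly once, within ±10 trials of the reversal.

## Agents

**Control learner.**  A Rescorla–Wagner delta rule updates only the chosen
option, `V ← V + α(r − V)`, with Boltzmann choice
`P(c) ∝ exp(β_sm V_c)`.  Cohort defaults are α = 0.3, β_sm = 5 — values
that produce rapid acquisition (criterion in ~20–30 trials) and
post-reversal switching in the range typical of trained macaques on such
schedules.

**Lesion mechanism.**  The hypothesized deficit is a degraded short-term
record of the animal's own recent choices (an eligibility-trace-like
store).  The agent implements this as *credit attenuation for
rarely-chosen options*: when the chosen option appears fewer than
`trace_thresh` (default 2) times among the previous `trace_span`
(default 5) choices, the update's learning rate is multiplied by
`trace_atten` (1.0 = intact; the lesion cohort uses 0.2).  Outcomes for
well-established options are credited normally, so long-run value trends
survive while credit for recent switches is lost.  This is one concrete
operationalization of a verbal hypothesis, not a uniqueness claim;
alternative mechanisms can be added behind the same policy interface.
Consequences, verified by simulation: more switching after rewarded
choices post-reversal; the reward vs no-reward difference in repeating a
just-chosen option collapses when that option was chosen ≤1 of the last 5
trials but is preserved at ≥4; acquisition of fixed schedules is slowed.

**Latencies** are lognormal: `log L ~ N(log base + κ·switch, σ)` with
control defaults base 400 ms, switch cost κ = 0.25 (log-ms), σ = 0.25.
The lesion phenotype sets κ = 0 and base 300 ms — generally faster
responding with no switch cost.  Speeding and the loss of the switch cost
are treated as independent parameters because the evidence does not
constrain their interaction.

**Planted-kernel agent.**  For validating the regression, an agent scores
each option by a planted 5×5 choice-lag × outcome-lag weight grid (plus
lag-6 confound weights) applied to exactly the regression's feature
coding, and chooses by softmax over the three scores.  With fewer than six
past trials it chooses uniformly, mirroring the regression's exclusion of
incomplete-history trials.

**Cohorts.**  The default simulated design mirrors the study: 7 control
and 3 lesion subjects, two varying schedules × 5 sessions × pre/post
phases (fixed schedules post-phase only), lesion parameters applied only
to the lesion group post phase.  Every session seed derives
deterministically from a master seed and the session's identity (via CRC32
of the subject/phase/schedule/index strings), so a cohort is a pure
function of its config.

## Rescorla–Wagner fitting

The likelihood is the product over trials of the softmax probability of
the observed choice under forward-simulated values, with values reset to
`init_value` at each session start (every session uses novel stimuli).
`init_value` defaults to 1/3, the symmetric prior over a 0/1 reward; it is
configurable because the original treatment is unreported.  The original
analysis fitted "a learning rate"; whether the temperature was fitted is
unstated, so fitting β_sm jointly is the default with a fixed-β mode
available.  Optimization is L-BFGS-B over α ∈ [1e-4, 1] and
β_sm ∈ [1e-3, 50] from a 4×3 grid of starts (α ∈ {0.05, 0.2, 0.5, 0.8},
β ∈ {1, 4, 12}); non-convergence and boundary estimates are flagged, never
silent.  Degenerate inputs (e.g. constant rewarded choices) legitimately
drive α to a bound and are flagged as such.  At the study's data size
(5 × 300 trials) the true α = 0.3 is recovered within ±0.1 in ≥ 90% of
replicate cohorts (measured: 100% of 50).

`V1_RL` labels are the argmax of the pre-choice forward-simulated values
given the subject's actual choices and outcomes, ties to the lowest index.

## The choice × outcome history kernel

For each target stimulus a binary logistic regression predicts "chose the
target on trial n" from 36 EVs indexed by (choice lag i, outcome lag j),
i, j = 1..6: an EV is 0 if trial n−j was unrewarded, +1 if rewarded and
the choice at n−i was the target, −1 if rewarded and the choice was
another option.  The 25 EVs with i, j ≤ 5 are of interest; the 11 with
i = 6 or j = 6 are confounds capturing longer trends (this 6×6-grid
completion is adopted because it uniquely reproduces the 36/25/11 counts).
Rows require six same-session predecessors; histories never span sessions.
The default fitting unit pools one subject × phase.

Fits use maximum likelihood with the covariance taken as the inverse
observed information (a sandwich option exists).  Because the sparse ±1
coding can separate on short synthetic data sets, separation or divergence
triggers an L2 penalty of 1e-2 on the slopes (intercept unpenalized),
solved by Newton iteration with covariance from the penalized Hessian;
the result is flagged `ridged`, never applied silently.

The three per-stimulus coefficient vectors β̂^A, β̂^B, β̂^C with
covariances Ĉ^A, Ĉ^B, Ĉ^C combine by the inverse-covariance-weighted
mean β̂ = (ΣĈ⁻¹)⁻¹ Σ(Ĉ⁻¹β̂); singular covariances fall back to
pseudo-inverses with a warning.  The combined 5×5 interest grid partitions
into the contingent diagonal (i = j, 5 cells), choice-spread (i < j,
10 cells: past outcomes spreading forward onto more recent choices) and
outcome-spread (i > j, 10 cells); per-lag summaries average each choice
lag over the other outcome lags (j ≠ i) and vice versa.  The recency
contrast compares outcome-lag-1 weights at choice lags {1,2} (or {2,3}
excluding the contingent cell) against {4,5}.

## Descriptive metrics

*Switch/stay*: a switch is `choice_n ≠ choice_{n−1}` within a session,
conditioned on the previous outcome and optionally split at the reversal.

*A_kB run history*: an event at trial n requires choice B at n−1 preceded
by a homogeneous run of k choices of a single other option A; the run must
be maximal (the trial before it is not A, or the session starts) and A
must not recur elsewhere in the 7-trial lookback window — a mixed-identity
history is not a clean run condition.  k ≥ 4 pools into the "4–7" bin;
runs longer than 7 pool there too (configurable).  A non-maximal
("at least k") mode is provided because the original edge rule is
unstated.  Bins are disjoint in the default mode, verified against an
independent scanner.

*Choice frequency*: for trials with ≥6 predecessors, the count of
`choice_{n−1}` repeats over n−2..n−6 (0–5) crossed with the n−1 outcome,
against P(repeat at n).

*Criterion*: first trial whose trailing 20-trial window holds ≥ 65%
best-option choices (inclusive threshold), counted within the acquisition
segment or from the reversal; sessions that never reach it carry a
sentinel and are excluded from subject medians.

*Fixed-schedule start/end*: sessions with first-20-trial best-option
proportions ≤ 0.25 / ≥ 0.75 (inclusive) are EARLY LOW / EARLY HIGH; the
endpoint is the last-20 proportion, compared across groups per class with
a two-sample Kolmogorov–Smirnov test (sessions as independent samples).

*Latencies* are natural-log transformed; histograms use 100 ms bins.

## Numerical and design choices

- Softmax uses max-subtraction; its output sums to 1 within 1e-12.
- Zero-probability choices make the likelihood +∞ rather than raising.
- All argmax ties break to the lowest option index, documented and stable.
- Moving windows truncate at session edges rather than padding.
- Trials are 1-based in files and reports; reversal_trial = 150 means
  trials 1–150 are pre-reversal.
- TSV (not CSV) throughout to avoid locale decimal issues.

## Problem sizes

Validation workloads were sized for quick desk runs while keeping
estimates stable: kernel recovery uses 30,000 planted-kernel trials
(elementwise grid correlation, measured > 0.93); learning-rate recovery
uses 50 replicate cohorts of 5 × 300 trials; lesion-contrast cohorts use
6 subjects × 5 sessions per arm; oracle-equivalence checks use 200 random
toy sessions.

## Limitations

The synthetic agents reproduce the statistical structure the analyses
assume — value learning, outcome-dependent switching, run histories,
lognormal latencies — but not satiety, session-level drifts, spatial
biases, or any physiological detail of the lesion; passing tests show the
*pipeline* is correct and self-consistent, not that the lesion mechanism
is the true account of the animal data.  Group-level inferential
statistics (repeated-measures ANOVAs, post-hoc tests) on the original
animal data are out of scope, as are hierarchical model fits and RL model
comparison.
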