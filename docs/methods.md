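# Methods

## The reward-bases model

Standard temporal-difference (TD) learning estimates a single value function
V(x) = E[r(x) + γr(x′) + γ²r(x″) + …] over environmental states x, driven by
the prediction error δ = r + γV(x′) − V(x). Its reward function is fixed, so
a change in physiological state (hunger, thirst, salt depletion) cannot move
the value function until the animal re-experiences the rewards.

This package implements a decomposition of the reward into *reward bases*,
r(x) = Σᵢ mᵢ rᵢ(x), where each rᵢ is one reward dimension (food, fluid, salt,
…) and mᵢ is the motivational drive currently attached to it. A separate
*value basis* Vᵢ(x) is learned for each dimension with its own TD error
δᵢ = rᵢ + γVᵢ(x′) − Vᵢ(x), and the acted-upon value function is composed at
decision time as V(x) = Σᵢ mᵢ Vᵢ(x). Because the updates are linear in the
reward, a fixed trajectory gives exactly Σᵢ Vᵢ = V_TD when all drives equal
1 — the package asserts this to machine precision — and any re-weighting of
the drives revalues every state instantly, with zero learning updates.

The *state-modulated* variant scales the error itself by the drive,
δ̃ᵢ = mᵢδᵢ, and updates ΔVᵢ = α mᵢ δ̃ᵢ (gradient descent on ½δ̃ᵢ²), so the
effective learning rate is α mᵢ². A satiated dimension (mᵢ = 0) is frozen; a
dimension trained under a negative drive (salt at mᵢ = −1) still learns the
*magnitude* of its reward, which is what makes instant revaluation to a
positive drive possible later.

### Terminal transitions and reward timing

Terminal transitions drop the discounted future term; terminality is an
explicit flag on the transition sample. The learning sample carries the
reward of the **current** state (the r(x) of the value definition above), so
learned surfaces peak on rewarded cells; the grid-step helper reports the
arrival cell's reward, and the episodic room task closes each episode with
one extra terminal update that delivers the valued object's own reward.
Value tables initialise at zero everywhere.

## Successor representation

The comparator agent learns the successor matrix M = I + γT + γ²T² + … by a
row-wise TD rule: on x → x′, row x moves toward onehot(x) + γ·row x′ (the
one-hot is over the pre-transition state; terminal transitions keep only the
one-hot term, mirroring the agents). Values follow as V = M·r for any reward
vector, and a value basis is Vᵢ = M·rᵢ, so the reward-bases agent is exactly
a successor representation compressed onto the reward dimensions that
matter: n_states × n_bases numbers instead of n_states². On the 6×6 room
task with three objects that is 108 versus 1296.

## Task environments

* **Free-exploration grid** (value-surface visualisation): 6×6 grid, three
  objects, each basis pays +5 on its own object's cell and −0.1 on every
  other cell; a 1000-step uniform random walk, α = 0.01, γ = 0.99. The walk
  is non-episodic.
* **Room task**: same grid, but an object's cell pays +5 in its own
  dimension and −1 in the others, empty cells pay 0; reaching the currently
  valued object ends the episode and the agent restarts on a uniformly
  random non-object cell. Objects are placed once per run from the seeded
  RNG on distinct cells. Actions are the four cardinal moves (walls absorb
  in place); value-based agents choose by a one-step lookahead — the
  preference of an action is the composed value of its successor cell, fed
  through a softmax (temperature 1). Run settings: α = 0.05, γ = 0.9, 500
  steps per reversal, 10 seeds; we use 6 inter-reversal blocks, with the
  valued dimension cycling at each reversal. Performance is mean obtained
  reward per step within each block (the arrival cell's reward in the valued
  dimension).
* **Devaluation levers**: two levers (food/sucrose); pressing one delivers
  its own reward type (1 unit) with probability 0.80, the other type (1
  unit) with 0.15, or four units of its own type with 0.05. Training: 500
  trials, α = 0.1, unit drives, softmax choice between composed lever
  values, one-step terminal updates of both bases of the chosen lever; three
  seeded repetitions are averaged. The converged bases are analytic:
  V_own = 0.8·1 + 0.05·4 = 1.0 and V_other = 0.15.
* **Salt/juice levers**: two Pavlovian levers with orthogonal one-hot reward
  bases; 100 random exposures, α = 0.1, γ = 0 (single-step task). TD trains
  on +1 (juice) / −1 (salt); the reward-bases agent trains with modulated
  errors under drives (m_juice, m_salt) = (1, −1). Setting m_salt = +0.5
  afterwards flips the composed salt-lever value from ≈ −1 to ≈ +0.5 with no
  learning; TD has no mechanism to follow.

## Dopamine readouts and drive fitting (devaluation)

Simulated dopamine is the summed drive-modulated prediction error Σᵢ δ̃ᵢ. Cue
responses use the discounted expected value of the cued lever (discount 1);
outcome responses are the summed errors for each outcome type, e.g. the MORE
outcome at the valued lever reads m_v(4 − V_v) − m_d·V_d. The two drives are
re-parameterised as m_valued = K·R, m_devalued = K; R is grid-searched over
[1, 10] in steps of 0.1 and, because predictions are linear in K at fixed R,
K is solved in closed form as K = Σⱼ pⱼyⱼ / Σⱼ pⱼ² for targets yⱼ and unit-K
predictions pⱼ. The eight fit targets (two cue, six outcome responses) are
user-supplied; the shipped defaults are a clearly-labelled synthetic demo
generated from the model's own analytic readouts at R = 2, K = 1, so the
fitting machinery demonstrably recovers known parameters. Approach behaviour
in the salt task is mapped linearly, approaches(x) = β₁V(x) + β₀, fitted
exactly through the two normal-condition targets (also synthetic demo
values).

## Mixed-selectivity circuit

The striato-dopaminergic network has 5 cortical (one-hot stimulus), 2 reward,
M = 50 striatal and N = 10 dopamine linear units. Dopamine unit k carries a
mixture of drive-scaled rewards minus striatal inhibition,
δ̃ᵏ = Σᵢ w_RD[k,i]mᵢrᵢ − Σᵢ w_SD[k,i]sⁱ (no future term: single-step task),
and tonically the drive mixture Dᵏ = Σᵢ w_RD[k,i]mᵢ, which sets striatal
gains gᵏ = Σᵢ w_DS[k,i]Dⁱ; striatal activity is sᵏ = gᵏ·Σᵢ w_CS[k,i]xᵢ, and
the value readout is the total striatal output S_out = Σₖ Σᵢ w_SD[k,i]sⁱ. If
every δ̃ᵏ = 0 and each w_RD column sums to 1, then S_out = Σᵢ mᵢrᵢ exactly
(tested constructively). Learning minimises L = ½Σₖ(δ̃ᵏ)²: w_SD follows the
exact gradient (Hebbian, αδ̃ᵏsⁱ); w_CS follows feedback alignment, routing
the error through the fixed random feedback w_DS instead of the transported
w_SDᵀ. Both correspondences are verified against central-difference
numerical gradients at 1e−6.

Training follows the five-stimulus schedule (juice values 1, 0.5, 0.1;
banana values 0.7, 0.05): 100,000 iterations, α = 0.05, uniform random
stimulus, drives Uniform[0, 1]. Loss and the alignment statistic — the
Pearson correlation between flattened w_SD and w_DSᵀ at matching index
pairs — are recorded every 1000 iterations. All weights are Xavier-uniform;
the w_RD columns are then divided by their signed sum. A column whose sum
magnitude falls below 0.5 is redrawn first: dividing by a near-zero signed
sum amplifies the reward weights without bound, and amplifications beyond
about 2× destabilise training at α = 0.05 (~3% of raw seeds diverge with a
0.1 threshold; none in 200 with 0.5). The threshold is exposed as
configuration. Trained evaluation uses only stimulus and drives (D, g, s,
S_out); under pure drives (1,0)/(0,1) the output recovers the stimulus's
schedule entry when its reward type is valued and ≈0 otherwise.

## Spike-count analysis pipeline

The pipeline analyses long-format spike data (neuron, trial, condition,
spike times with stimulus onset at t = 0) across five conditions — three
juice (subjective values 1, 0.5, 0.1) and two banana (0.7, 0.05), values on
a 0–1 scale. Responses are spike counts in the 150–500 ms post-stimulus
window (rates divide by 0.35 s); baseline correction subtracts the rate in
the 500 ms before onset; smoothed rates use 200 ms windows every 50 ms.
Window membership is half-open [start, end), so boundary spikes count once.

Two per-neuron OLS regressions are fitted: counts on the two reward-basis
regressors (r₁ = value on juice conditions else 0; r₂ likewise for banana),
and counts on value R(x) and its interaction with identity I(x) ∈ {+1, −1}.
These are exact reparameterisations — b₁ = (β₁+β₂)/2, b₂ = (β₁−β₂)/2 with
identical fitted values — and the model set for comparison is {value,
value+identity, value+identity:value, value+identity+identity:value,
stimulus}, the last being the saturated five-condition-means model.
Information criteria use the Gaussian maximum-likelihood form
n·ln(RSS/n) + penalty with k counting the coefficients plus the residual
variance, summed across neurons; the convention differs from full-likelihood
AIC by an additive constant that cancels in comparisons (cross-checked
against statsmodels). Significance of coefficients is a two-sided t-test at
p < 0.05, uncorrected.

Two permutation nulls are built with 1000 repetitions: (i) the across-neuron
correlation of mean baseline-corrected responses to the top-juice and
top-banana conditions, against resplits of the pooled trials into groups of
the original sizes (one-sided, low); (ii) the count of neurons with a
significant interaction coefficient, against within-neuron permutations of
the identity labels (one-sided, high). Empirical p-values are reported both
as the plain proportion and with the +1 correction. Model recovery simulates
surrogate counts from each fitted candidate model plus Gaussian noise at the
neuron's residual SD, refits both, and reports the two summed-ΔAIC
distributions and their overlap. Split-half stability refits the interaction
coefficient on the first and second halves of each neuron's trials (by trial
order) and correlates the two across neurons.

## Synthetic spike generator

Expected response-window counts follow the interaction forward model
μ = b₀ + b₁R + b₂IR per neuron, realised as round(max(0, μ + N(0, σ))) or
Poisson(max(0.01, μ)); the realised count is placed uniformly inside the
response window and background spikes at 10 Hz elsewhere in [−0.5, 1.0] s,
so the windowing operations are all exercised. Conditions are interleaved in
session order. Defaults emulate the structure the pipeline assumes: 19
neurons, 20 trials per condition, b₀ = 10, b₁ = 3, σ = 2. Three populations
drive the permutation tests: *null* (b₂ = 0 everywhere), *planted* (7 of 19
neurons with b₂ = ±2.5, alternating sign), and *anticorrelated* (b₂ drawn
N(0, 4) across neurons, giving opposed juice/banana selectivity). The
planted effect size is chosen so every planted neuron is unambiguously
significant (t ≈ 5–6) while the identity-shuffle null keeps near-nominal
behaviour; much larger planted effects leave unmodelled interaction variance
that visibly inflates the shuffle null. A *stimulus-selective* mode adds
per-condition offsets off the value structure, which is what makes the
model-recovery analysis genuinely separable.

What the generator does **not** emulate: burst/pause temporal dynamics,
non-stationarity across a session (a stationary process by default),
inter-neuron correlations, and non-Poisson background statistics. Passing
tests therefore certify the analysis machinery — exact algebraic identities,
valid permutation behaviour, recoverable planted effects — not any property
of real dopamine recordings, which this package does not include.

## Numerical choices and degenerate inputs

Softmax uses max-shifting (overflow-safe; probabilities invariant to common
shifts). OLS is plain least squares via numpy with t-based two-sided
p-values; a rank-deficient design raises a flagged degenerate-fit error, and
pipeline-level functions exclude such neurons with a warning rather than
silently. The basis regression requires trials in at least three distinct
conditions. Zero RSS is floored at 1e−300 per observation so criteria stay
finite on noiseless data. All randomness flows through seeded numpy
generators; multi-seed runs derive child seeds from a SeedSequence, capped
below 2³¹.

## Problem sizes in the shipped runs

The default test and demo runs use the published settings directly: 100,000
training iterations × 10 seeds for the circuit, 1000-rep permutations on
19-neuron populations, 10-seed room runs of 6 × 500 steps. Simulation-heavy
*unit* tests use smaller replicas (e.g. 20,000-iteration training runs, 200–
400-rep permutations) chosen to keep the default suite quick; the full-size
settings are exercised in the end-to-end checks.

## Known limitations

Drives are always user-supplied — learning them from homeostatic set-points
is out of scope. No function approximation, eligibility traces, or per-basis
discount factors. The trial-level devaluation model ignores within-trial
event timing (the MORE outcome is a single four-unit delivery). The room
task's block count and the restart rule are package choices where the source
material is silent. Whether terminal successor-matrix updates should keep
the discounted row term is undetermined; the package drops it for
consistency with the agents, and the flag is exposed for sensitivity
analysis.
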