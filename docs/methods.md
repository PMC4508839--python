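# Methods

## Markov targets

Transition matrices are row-stochastic over 0-based states. The backward
conditionals are derived by Bayes' rule, P_B[i, j] = P_F[j, i]·π_j/π_i,
with the stationary distribution π found by damped power iteration;
reducibility is detected by iterating from a second starting point and
checking that both converge to the same fixed point (an absorbing chain
with a unique π is accepted; a chain whose stationary distribution depends
on the start is rejected, and a state with π_i = 0 raises an error when a
backward matrix is requested).

Three synthetic families are provided:

- **Circulant Gaussian** (`make_gaussian_tm`): row i is a Gaussian density
  evaluated at integer offsets, centered at column (i+9) mod n, and
  renormalized. Centering uses circular indexing so every state sees
  identical statistics; without wrapping, the stated center would leave the
  state range for i > n−10. σ = 0 gives the deterministic permutation.
  Row entropy is strictly increasing in σ, so `solve_sigma_for_entropy`
  bisects it to 10⁻³ bits. The per-row entropy ranges from 0 to
  log₂ n (4.2479 bits at n = 19), the upper end reached asymptotically.
- **Birdsong-like** (`make_birdsong_like_tm`): emulates the published
  summary statistics of Bengalese finch songs (5–10 syllables, mean
  sequence entropies of order 0.1–2.8 bits); the real song-derived matrices
  are not public, so only these coordinates are reproduced. Each syllable
  gets 1–4 random successors (more if the entropy target demands it) with
  Dirichlet(1) probabilities, then all rows are tempered by a common
  exponent γ (p ∝ p₀^γ). The entropy-vs-γ map is deterministic given the
  seed and strictly monotone, so γ is bisected to hit the mean-entropy
  target; this was chosen over bisecting a Dirichlet concentration, whose
  realized entropy would be resampled at every candidate value.
- **Mixed** (`make_mixed_tm`): even-indexed rows deterministic (σ = 0),
  odd-indexed rows Gaussian at a given σ — the alternating low/high
  entropy construction used in the mixed-statistics experiment.

Entropies use the convention 0·log₂0 = 0 and are reported with the
conventional negative sign, so all values are non-negative bits.

## Binary correlation learning

Events are drawn one per step from the joint pairing probabilities
(a silent step occurs with probability 1 − Σp). Weights start uniform at
1/N and are clipped at zero after each update (large learning rates can
transiently push a weight negative). The closed-form steady state is the
pairing distribution normalized to 1 (the Bayes conditional). Because the
stochastic dynamics fluctuate around that fixed point on a scale ~√lr, the
steady state is estimated by a trailing time average of the weight
trajectory (`steady_weights`), not by the last sample.

## Recurrent rate network with Hebbian covariance plasticity

One unit per sequence state. Each time step, the current state's unit
receives a teaching pulse δ_amp = 1; rates saturate at r_max = 1 and are
floored at 0.

**Recurrent gain.** With the competing weight sums divisively normalized
to 1, the bare recurrence y → Mᵀy conserves total activity exactly (the
weight matrix is stochastic along the competing axis), so the teaching
input injected every step accumulates until the whole network pins at
r_max — at which point all covariance deviations vanish and plasticity
stops. Bounded, stationary dynamics therefore require a leak: the
recurrent input is scaled by g_rec ∈ (0, 1), default 0.3. The value is not
critical provided the network stays unsaturated; larger values add a
homogenizing bias because graded recurrent predictions potentiate whole
successor sets.

**Background noise and SNR.** Background activity is modeled as sparse
Poisson pulses: each unit receives a pulse of amplitude δ_amp/snr with
expectation 1/n per step, so the network sees on average one noise pulse
per step against one teaching pulse and `snr` is the amplitude ratio of
the two. A DC background with mean equal to the teaching amplitude is not
usable here: combined with the saturating nonlinearity it parks every unit
at r_max. Noise pulses create random co-activations whose net effect is
homogenizing; lowering snr therefore lowers the optimal weight dependence
β, and `snr = inf` disables noise entirely.

**Calibration of unprinted constants.** A_plus (default 0.001), snr
(default 10) and g_rec (default 0.3) are not determined by the model
definition. They were calibrated once against the two reported Gaussian
operating points — the deterministic target trained at (α = 1.9, β = 0.18)
should reach error ≈ 7·10⁻⁴ with ≈ 0.06 bits of final weight entropy, and
the 2.2-bit target at (α = 1.05, β = 0.34) error ≈ 0.007 with ≈ 2.25
bits — and then frozen. The final entropy of a learned deterministic
target scales roughly with √A_plus (it is a fluctuation floor), which
pins A_plus once the noise level is set; 1000 songs reach asymptote on
19-state problems at this rate.

**Rule details.** The running mean uses the previous 5 time points (the
pre-synaptic deviation uses the window ending one step earlier than the
post-synaptic one); before 5 steps of history exist the mean uses what is
available, initialized to the background mean. Potentiation requires both
deviations strictly positive (the covariance-quadrant reading); opposite
signs give depression scaled by α; both non-positive gives no change.
Constraints are enforced after every update: clip to [0, 1], then divide
each competing group by its sum (a group that collapses to 0 is reset
uniform). Songs are 5n states long, start at a uniformly random state, and
carry the rate and running-mean buffers across song boundaries. Error is
the L1 mean absolute difference (an L2 variant is available behind
`error_norm`), measured against P_F for pre-synaptic competition and
against the Bayes backward conditionals for post-synaptic competition;
entropy is the mean Shannon entropy of the competing weight groups.
Runs are averaged over `n_runs` independent initializations (1/n ± 5%
uniform jitter, renormalized). The per-step loop is numba-compiled; cell
seeds for grid searches derive from `SeedSequence([base, i, j])` so
surfaces are reproducible and cells independent.

## Spiking network with STDP

One singleton neuron and a 17-neuron array; LIF constants V_th = −54 mV,
V_reset = −60 mV, τ_m = 10 ms, E_leak = −70 mV, E_ex = 0, E_in = −80 mV,
5 ms absolute refractory period, 2 ms conductance decay, 1 ms steps
(forward Euler). The teacher conductance (2.5 mS/cm²) fires its neuron
deterministically; plastic feed-forward synapses inject m·g_ff with
g_ff = 0.1 mS/cm², which generally stays subthreshold. A spiking neuron's
synaptic conductances are cleared at the spike: the teacher conductance
tail would otherwise still be suprathreshold when the refractory period
ends, producing a spurious echo spike per imposed pulse.

STDP uses Δt = t_pre − t_post, potentiation for Δt < 0, depression
(with the negative sign made explicit) for Δt ≥ 0, τ_± = 10 ms,
A₊ = 0.001, A₋ = αA₊. All spike pairs within a ±10 ms window (one time
constant) are applied, each pair counted once. The window choice matters
at the 20 ms teacher pacing: a wider window pairs every imposed spike with
the *previous* imposed pair 15 ms back, adding a depression channel
proportional to the same sampling probability as the potentiation, which
cancels the probability dependence of the weight-dependent steady state.
Background spiking is Bernoulli at 5 Hz per neuron per ms; background
spikes propagate conductances, collide with the refractory period, and by
default participate in plasticity pairings. Note that uncorrelated
pairings under a weight-dependent rule equilibrate every weight at
m* = 1/(1 + α^(1/β)) (≈ 0.38 for α = 1.1, β = 0.2) regardless of the
training distribution; on long runs this floor dominates the weakly
sampled synapses, so regime-comparison experiments that focus on the rule
itself are run with the background set to zero.

Weights start uniform at m0 = 0.05 so that structure grows into the
distribution. With the 20 ms pacing the maximal weight transfer per
imposed pair is A₊e^(−1/2) ≈ 6·10⁻⁴, so the characteristic phenomenology —
the additive rule's error dipping and then rising as the most-sampled
synapses hit the upper bound and the less probable ones are carved away,
versus the weight-dependent rule's longer monotone decay to a graded
match — unfolds on the 10⁴-pair scale; experiments and tests use horizons
of that order. With pre-synaptic divisive normalization the outgoing
weight vector converges onto the imposed conditional distribution, with a
convergence exponent set by the per-pair transfer (~12000 pairs reach a
maximal per-weight deviation below 0.02).

## Quantification suite

Ψ(α, β) is continuous at β = 0.5 and spans [−1, 1] on the default grids
α ∈ 1:0.05:2, β ∈ 0:0.02:1. Error/entropy surfaces are smoothed with a
normalized 3×3 box filter with edge replication (normalization does not
move the argmin; replication keeps the surface size); the optimum is the
argmin of the smoothed error surface with ties broken toward the smallest
(α, β) in row-major order. Learning slopes are least-squares fits over a
configurable window (default songs 1–50). The entropy sweep fits
ψ* = a·sinh(bH) + c by unweighted least squares. Scaled-down sweeps use
coarse grids (3 α × 10 β values bracketing the reported optima) with one
run per cell — justified for circulant Gaussian targets, where every state
experiences identical statistics — and five runs for the final retrain at
each optimum.

## What the synthetic generators do and do not capture

The Gaussian and mixed families reproduce the entropy coordinates of the
published experiments exactly, so results on them are directly
comparable. The birdsong-like generator reproduces only summary statistics
(syllable counts, entropy ranges, sparse skewed rows) of real song; it
does not model repeat phrases, higher-order dependencies, bout boundaries,
or the empirical distribution of branching ratios. Passing tests on these
matrices show that the learning-force trade-offs hold on sparse,
heterogeneous targets, not that any specific bird's song statistics are
recovered.

## Known limitations

- The rate equation's stability constant g_rec and the noise
  parameterization are package choices; the learned-weight error at a
  given (α, β) shifts with them, though the qualitative structure
  (site dichotomy, entropy monotonicity in Ψ, SNR dependence of β*) does
  not.
- STDP results are sensitive to the pairing bookkeeping (window,
  nearest-vs-all pairs) at the fixed 20 ms pacing; the one-time-constant
  window is documented and configurable.
- Grid-search optima are quantized to the grid; reported ψ* inherits that
  resolution.
- Chains whose stationary distribution is degenerate (unreachable states)
  have no backward representation and are rejected rather than patched.
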