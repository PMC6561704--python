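# Methods

## Model and conventions

The network is the standard leaky rate RNN

    h(t) = (1 − 1/τ) h(t−1) + (1/τ) φ(u(t)),
    u(t) = W h(t−1) + W_in x(t),
    y(t) = W_out h(t),

with φ = tanh by default (a linear mode exists for oracle tests, since the
analytic ODE solution and descent guarantees are exact there). Trials are
indexed t = 1..T; array row t−1 stores the time-t quantities and `h_seq`
row 0 stores h(0). The loss is the time-averaged squared error
L = (1/2T) Σ_t |y*(t) − y(t)|². The update is synchronous: the right-hand
side uses the pre-update state.

Initialisation follows the convention used throughout the experiments:
W ~ N(0, g²/N) with g = 1.5, W_in uniform on [−1, 1], W_out uniform on
[−1/N, 1/N], feedback B ~ N(0, 1), τ = 10 timesteps. These are the
defaults of `init_params` and of the YAML config layer.

**Initial state.** h(0) = 0 everywhere except the autonomous periodic
task, where the origin is a trapping fixed point (φ(0) = 0 and there is no
input); there h(0) is drawn once from a standard Gaussian using a dedicated
seed stream and reused across all trials of a run.

## Learning rules

Exact gradient, two routes:

* **RTRL** propagates the sensitivity tensor P[j,a,b] = ∂h_j(t)/∂W_ab
  forward with
  P ← (1−1/τ)P + (1/τ)δ_ja φ'(u_a)h_b(t−1) + (1/τ)φ'(u_j)(W P)_jab,
  O(N³) state per step.
* **BPTT** runs the reverse adjoint recursion over the stored trajectory,
  O(N²) per step. The two agree to ~1e−15 relative error; both are checked
  against central finite differences (step 1e−6, float64) in the tests and
  the acceptance script.

**RFLO** applies two independent approximations, exposed as orthogonal
switches so each can be ablated:

* `gradient_mode="local"` drops the nonlocal W·P term, collapsing the
  sensitivity tensor onto eligibility traces p (N×N) and q (N×N_x) — the
  O(N²) quantities a synapse could plausibly hold. When W = 0 the dropped
  term vanishes and the local rule is exact; this reduction is asserted to
  1e−12.
* `feedback_mode="random"` replaces W_outᵀ by the fixed random B in the
  error-feedback projection. With B := W_outᵀ the local rule coincides
  bitwise with the "local + symmetric" ablation.

**Input-trace index.** The printed trace recursion pairs φ'(u_a(t)) with
x_b(t−1), but u_a(t) itself contains x(t). The default pairs the trace
with x(t), which makes the W = 0 reduction match the exact input-weight
gradient (a testable property); the one-step-shifted variant is available
as `eq6_literal=True` and is indistinguishable at the resolution of any
benchmark here.

**Schedules and normalisation.** Updates can be applied online (every
timestep, no 1/T factor — the learning rate absorbs the scale), per trial
(accumulated with the 1/T of the loss, the default, so printed η values
refer to this schedule), or in batches of k trials (sum of per-trial
updates, applied once; the interval-matching experiments use k = 10).
Per-trial application is the default for the periodic benchmark because it
makes RFLO and BPTT updates directly comparable; whether online or
per-trial application is used changes none of the qualitative results.

**Dale's law.** In `dale=True` mode units 1..N/2 are excitatory and the
rest inhibitory; columns of W are sign-rectified at initialisation
(W_ij ← ξ_j|W_ij|) and every update is followed by clipping
sign-violating entries to zero, so the invariant holds after every trial
by construction.

**Readout-feedback control.** With `readout_feedback=True` the current
output y(t−1) is added to the input current through the same random matrix
B. This stabilises the dynamics when only the readout is trained (the
recurrent weights being frozen at a chaotic or decaying initialisation).
Two control experiments use it: recurrent-only learning with a frozen
readout fails (alignment between W_out and B cannot develop when W_out
never moves), while readout-only learning with fed-back output succeeds
partially.

**REINFORCE / node perturbation.** Noise ξ_a(t) ~ N(0, σ²) is injected
into each unit's input current; at trial end
ΔW_ab = (η/T)(R − R̄) Σ_t ξ_a(t) h_b(t) with R = −L and R̄ an exponential
moving average (decay 0.9, initialised at the first trial's R so the first
update vanishes). The rule pairs ξ(t) with h(t) of the same step, exactly
as written in its classical form. The benchmark micro-task is a
regression-like problem — constant unit drive, constant target 1, N = 5,
T = 20, linear units, g = 0.5 — with η = 2.0 and σ = 0.3, chosen once so
that learning is visible (roughly halving the loss) within 5,000 trials;
the large η compensates for the small (R − R̄)·ξ product scale.

**Divergence guard.** Training aborts with a named error if any update or
weight becomes non-finite or the trial loss exceeds 1e6; multi-seed
drivers record the divergence and continue with the remaining seeds, and
the grid search flags (and never selects) diverged learning rates.

## Tasks (the synthetic data)

* **Periodic output**: no input; target
  sin(2πt/T) + 0.5 sin(4πt/T) + 0.25 sin(8πt/T), one trial = one period.
  Reference scale: N = 30, T = 200 = 20τ, η = 0.03, 3,000 trials,
  3 network realisations.
* **Ready-Set-Go**: one input channel with two unit Gaussian pulses
  (σ = 15 steps) separated by a delay uniform on [5τ, 10τ]; the target is
  one pulse trailing the second by the same delay. Trial length is
  t_first + 2·delay_max + 4σ = 310 steps with the first pulse at t = 50.
  This is a scaled-down range (the original extends to 15τ): N = 100,
  batch(10) updates, η = 0.003 selected by the same coarse learning-rate
  grid search used everywhere, 5,000 training trials. Training delays are
  the integers in [50, 100] that are *not* multiples of 5; evaluation uses
  the 11 multiples of 5, so held-out delays are genuinely unseen. The
  produced delay is the output's argmax (searched from the second pulse to
  trial end) minus the second pulse time. Random-feedback training of this
  task is bimodal across network realisations: most runs learn
  delay-dependent timing (final training loss ~0.002–0.006), a minority
  settle on producing the pulse at the average target time (loss ≥ 0.011,
  flat produced delays). The benchmark therefore trains four realisations
  and evaluates the one with the lowest final-100-trial training loss —
  the same ranking statistic the learning-rate grid search uses — so no
  held-out information enters the selection.
* **Reach syllables**: four tonic input channels, each selecting a unit
  direction (±x, ±y); the 2-D target velocity is a Gaussian speed bump
  (sd = T/8) integrating to a reach of length 1.0 over 20τ steps. Action
  a < 4 is a reach, a ≥ 4 a hold (channel a−4 active, zero velocity). The
  workspace is a square of half-width 1.5 (1.5× the reach length); pulse
  and input amplitudes are 1.0. These choices fill in quantities the task
  descriptions leave open.

Generators are pure functions of (spec, seed). What they do **not**
emulate: observation noise, trial-to-trial target variability, or
amplitude uncertainty — passing benchmarks here demonstrates the learning
rules under clean, stationary task statistics, not robustness to real
sensory data.

## Sequence learning via the auxiliary loop

After syllables are learned, loop weights W^s read the hidden state at
each syllable boundary (z = W^s h), a winner-take-all rule picks the next
syllable — with probability p_explore = 0.1 a uniformly random allowed
action instead — and W^s is trained with ΔW^s_ij = η_s R z_i h_j, R = 1
iff the executed transition matches the target sequence (successor
relation of the 8-long target, made cyclic so a transition is defined
after exploratory detours). Reaches that would push the cursor out of
bounds are masked from both greedy and exploratory choices; holds are
always allowed.

Two design points deserve emphasis:

* **Post-competition Hebbian factor.** Applied to the raw pre-competition
  z, the outer-product rule only rescales z in each context
  (Δz ∝ z‖h‖²) and can never reorder action preferences; the driver
  therefore passes the winner-take-all activity (one-hot on the winner),
  so only the winning row is reinforced. W^s is initialised with small
  Gaussians because the rule is multiplicative in z and cannot start from
  exactly zero weights.
* **Idealized emulator.** Loop learning is benchmarked against a scripted
  stand-in for the trained network (synthetic test double): one fixed
  state per syllable, *orthogonalised* and scaled to norm √N, plus the
  exact per-syllable displacement. Orthogonality matters: the plain
  unnormalised Hebbian rule lets frequently rewarded rows grow linearly in
  time, and with correlated context states that growth leaks into other
  contexts faster than rarely explored correct actions can accumulate
  evidence, stalling learning partway through the sequence. Real RNN
  states are correlated, so the emulator results are an upper bound on
  what the plain rule achieves; η_s = 0.05 converges within a few hundred
  trials in this idealised setting.

With exploration on, the per-transition reward of even a perfect policy is
capped at (1 − p_explore) + p_explore/|allowed| ≈ 0.91 (lower still after
masking-induced detours); training reward therefore plateaus around
0.85–0.89 while the greedy (exploration-off) policy reproduces the target
sequence exactly. Reported numbers include both so the two effects are
separable.

## Numerical choices

* float64 throughout; finite-difference oracle step 1e−6 (central).
* Identity checks use 1e−12 absolute tolerance: algebraically identical
  code paths differ only by BLAS evaluation order.
* Argmax ties (winner-take-all, peak time) resolve to the lowest index.
* Degenerate sizes are first-class: N_x = 0 (autonomous tasks) gives
  zero-column W_in and inert input traces; T = 0 trials carry only h(0)
  and have undefined loss (an error, not NaN).
* Seeds: one root seed per run; independent substreams are derived by
  hashing (root, name) for init / task / explore / noise / h0, so all
  derived seeds are < 2³¹ and changing one component's draws leaves the
  others fixed.
* "Resumability" of experiment runs means deterministic replay from the
  manifest (config + seeds + package version), which reproduces every
  artifact bitwise — not warm-restart from partial state.

## Known limitations

* RFLO degrades relative to BPTT as task duration grows (the accumulated
  effect of the dropped gradient term); the benchmarks here use short and
  intermediate durations where the rules are comparable, plus the loop
  architecture for long sequences.
* The sequence loop is only demonstrated on the idealised emulator; with
  a really-trained RNN the context correlations reintroduce the Hebbian
  cross-talk discussed above.
* Grid-search and multi-seed drivers are serial; runtimes are minutes at
  the reference scales (N ≤ 100).
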