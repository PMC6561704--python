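# rflo

Training recurrent neural networks with a learning rule that a brain could
plausibly implement — and measuring what the required approximations cost.

Classic gradient-based training of recurrent networks is either acausal
(backpropagation through time, BPTT) or nonlocal (real-time recurrent
learning, RTRL), and both need error feedback weights precisely matched to
the readout. **Random-feedback local online (RFLO) learning** drops the
nonlocal term of the RTRL gradient — leaving a per-synapse eligibility
trace of pre/postsynaptic activity — and feeds the output error back
through a *fixed random* matrix instead of the transposed readout. This
package implements RFLO together with exact RTRL/BPTT baselines, the two
single-approximation ablations, a node-perturbation (REINFORCE) baseline,
three synthetic motor/timing benchmark tasks, and an auxiliary-loop
architecture that concatenates learned "behavioral syllables" into longer
sequences. It is aimed at computational-neuroscience researchers studying
biologically plausible credit assignment.

## Model

A leaky rate network of `N` units with time constant `τ` (timesteps):

```
h(t) = (1 − 1/τ) h(t−1) + (1/τ) φ(W h(t−1) + W_in x(t)),   φ = tanh
y(t) = W_out h(t),     ε(t) = y*(t) − y(t),
L = (1/2T) Σ_t |ε(t)|²
```

RFLO updates, with `B` a fixed random feedback matrix:

```
ΔW_out = η₁ ε(t) h(t)ᵀ
ΔW_ab  = η₂ [B ε(t)]_a p_ab(t),   p_ab(t) = (1/τ) φ'(u_a(t)) h_b(t−1) + (1−1/τ) p_ab(t−1)
ΔW_in  = η₃ [B ε(t)]_a q_ab(t)    (same trace with x in place of h)
```

The two approximations are exposed independently (`gradient_mode` ∈
{local, full}, `feedback_mode` ∈ {random, symmetric}); (full, symmetric)
is exact RTRL, verified against finite differences and BPTT.

## Worked example

Train a 30-unit autonomous network to produce a periodic waveform
(period 200 steps) with RFLO, and inspect the result:

```python
import numpy as np
from rflo import (PeriodicTaskSpec, periodic_trial, init_params,
                  LearningConfig, train_single, run_trial,
                  output_correlation, named_rng)

trial = periodic_trial(PeriodicTaskSpec(T=200))
params = init_params(N=30, N_x=0, N_y=1, tau=10, g=1.5, seed=named_rng(0, "init"))
h0 = named_rng(0, "h0").normal(size=30)     # h(0)=0 would be a fixed point
cfg = LearningConfig(eta1=0.03, eta2=0.03, eta3=0.03, rule="rflo")
log = train_single(params, lambda rng: trial, cfg, 3000, np.random.default_rng(0), h0=h0)

traj = run_trial(params, trial, h0=h0)
print(f"untrained loss {log.loss.iloc[0]:.4f}")
print(f"final loss     {log.loss.tail(100).median():.5f}")
print(f"correlation    {output_correlation(traj.y_seq, trial.ystar_seq):.4f}")
print(f"alignment      {log.alignment.iloc[0]:+.3f} -> {log.alignment.iloc[-1]:+.3f}")
```

prints

```
untrained loss 0.3806
final loss     0.00344
correlation    0.9955
alignment      -0.078 -> +0.752
```

The loss falls to ~1% of the untrained network's, the output tracks the
target almost perfectly, and — the signature of random-feedback learning —
the readout weights align with the fixed feedback matrix during training
even though `B` never changes.

A CLI wraps the same machinery (`rflo train config.yaml`,
`rflo gridsearch`, `rflo sequence`, `rflo evaluate`); configs are YAML,
logs CSV, weights HDF5.

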