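import numpy as np
import pytest

from rflo.rnn_core import TrialData, init_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_instance(seed, N=6, N_x=2, N_y=2, T=25, tau=10.0, phi="tanh", g=1.2):
    """A small random network + trial + initial state for oracle checks."""
    rng = np.random.default_rng(seed)
    params = init_params(N, N_x, N_y, tau=tau, g=g, seed=seed, phi=phi)
    trial = TrialData(x_seq=rng.normal(size=(T, N_x)), ystar_seq=rng.normal(size=(T, N_y)))
    h0 = 0.5 * rng.normal(size=N)
    return params, trial, h0


def finite_difference_gradients(params, trial, h0, eps=1e-6):
    """Central-difference gradient of the trial loss w.r.t. every weight."""
    from rflo.rnn_core import compute_loss, run_trial

    def loss_of(p):
        return compute_loss(run_trial(p, trial, h0=h0))

    grads = {}
    for name in ("W", "W_in", "W_out"):
        M = getattr(params, name)
        g = np.zeros_like(M)
        for idx in np.ndindex(M.shape):
            p = params.copy()
            getattr(p, name)[idx] += eps
            lp = loss_of(p)
            p = params.copy()
            getattr(p, name)[idx] -= eps
            lm = loss_of(p)
            g[idx] = (lp - lm) / (2 * eps)
        grads[name] = g
    return grads
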