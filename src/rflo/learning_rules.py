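"""Learning rules: RFLO, RTRL, BPTT, their ablations, and REINFORCE.

The exact gradient of the time-averaged squared error with respect to the
recurrent weights is

    dL/dW_ab = -(1/T) sum_t sum_j [W_out^T err(t)]_j  dh_j(t)/dW_ab,

where the sensitivity dh_j(t)/dW_ab obeys the forward (RTRL) recursion

    P[j,a,b](t) = (1-1/tau) P[j,a,b](t-1)
                + (1/tau) delta_ja phi'(u_a(t)) h_b(t-1)
                + (1/tau) phi'(u_j(t)) sum_k W_jk P[k,a,b](t-1).

RFLO makes two independent approximations: it *localises* the gradient by
dropping the third (nonlocal) term, which collapses the sensitivity tensor
to the rank-deficient form P[j,a,b] = delta_ja p_ab with an eligibility
trace p, and it replaces the symmetric error feedback W_out^T by a fixed
random matrix B.  The two approximations are exposed independently here as
``gradient_mode`` ("local"/"full") and ``feedback_mode`` ("random"/
"symmetric"); (local, random) is RFLO and (full, symmetric) is exact RTRL.

All ``*_gradient_trial`` functions return per-trial accumulated updates in
the descent direction (to be *added* to the weights), scaled by the
learning rates and including the 1/T of the loss.  Online RFLO updates
(``rflo_step``) omit the 1/T; the learning rate absorbs the scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .rnn_core import (
    ConfigurationError,
    RNNParams,
    Trajectory,
    TrialData,
    compute_loss,
    apply_dale_constraint,
    run_trial,
)

__all__ = [
    "EligibilityTraces",
    "SensitivityTensor",
    "WeightUpdate",
    "LearningConfig",
    "ReinforceConfig",
    "TrainingDivergedError",
    "update_eligibility",
    "rflo_step",
    "gradient_trial",
    "rflo_gradient_trial",
    "rtrl_step",
    "rtrl_gradient_trial",
    "bptt_gradient_trial",
    "reinforce_trial",
    "apply_updates",
]

LOSS_DIVERGENCE_LIMIT = 1e6


class TrainingDivergedError(RuntimeError):
    """Raised when weights or loss become non-finite or absurdly large."""

    def __init__(self, rule: str, trial_index: int, detail: str = "") -> None:
        msg = f"training diverged (rule={rule}, trial={trial_index})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
        self.rule = rule
        self.trial_index = trial_index


@dataclass
class EligibilityTraces:
    """Low-pass-filtered pre/post products p (recurrent) and q (input)."""

    p: np.ndarray  # N x N
    q: np.ndarray  # N x N_x

    @classmethod
    def zeros(cls, params: RNNParams) -> "EligibilityTraces":
        return cls(p=np.zeros((params.n, params.n)), q=np.zeros((params.n, params.n_in)))


@dataclass
class SensitivityTensor:
    """Full forward-mode sensitivities of the hidden state.

    ``P[j, a, b] = dh_j(t)/dW_ab`` and ``P_in[j, a, b] = dh_j(t)/dW_in_ab``.
    Storage is O(N^3) versus O(N^2) for the eligibility traces, which is the
    structural cost of exactness.
    """

    P: np.ndarray  # N x N x N
    P_in: np.ndarray  # N x N x N_x

    @classmethod
    def zeros(cls, params: RNNParams) -> "SensitivityTensor":
        n, nx = params.n, params.n_in
        return cls(P=np.zeros((n, n, n)), P_in=np.zeros((n, n, nx)))


@dataclass
class WeightUpdate:
    dW_in: np.ndarray
    dW: np.ndarray
    dW_out: np.ndarray

    @classmethod
    def zeros(cls, params: RNNParams) -> "WeightUpdate":
        return cls(
            dW_in=np.zeros_like(params.W_in),
            dW=np.zeros_like(params.W),
            dW_out=np.zeros_like(params.W_out),
        )

    def __iadd__(self, other: "WeightUpdate") -> "WeightUpdate":
        self.dW_in += other.dW_in
        self.dW += other.dW
        self.dW_out += other.dW_out
        return self

    def scaled(self, c: float) -> "WeightUpdate":
        return WeightUpdate(dW_in=c * self.dW_in, dW=c * self.dW, dW_out=c * self.dW_out)

    def is_finite(self) -> bool:
        return bool(
            np.all(np.isfinite(self.dW_in))
            and np.all(np.isfinite(self.dW))
            and np.all(np.isfinite(self.dW_out))
        )


@dataclass
class LearningConfig:
    """Learning rates and the two approximation switches.

    eta1/eta2/eta3 scale the readout, recurrent and input-weight updates
    respectively.  ``schedule`` is "online", "per_trial" or "batch";
    ``batch_size`` applies to the latter.  ``eq6_literal`` pairs the input
    trace with the one-step-delayed input x(t-1) instead of x(t).
    """

    eta1: float = 0.0
    eta2: float = 0.0
    eta3: float = 0.0
    feedback_mode: str = "random"  # "random" | "symmetric"
    gradient_mode: str = "local"  # "local" | "full"
    schedule: str = "per_trial"  # "online" | "per_trial" | "batch"
    batch_size: int = 1
    rule: str = "rflo"  # "rflo" | "rtrl" | "bptt" | "reinforce"
    eq6_literal: bool = False

    def __post_init__(self) -> None:
        if min(self.eta1, self.eta2, self.eta3) < 0:
            raise ConfigurationError("learning rates must be >= 0")
        if self.feedback_mode not in ("random", "symmetric"):
            raise ConfigurationError(f"bad feedback_mode {self.feedback_mode!r}")
        if self.gradient_mode not in ("local", "full"):
            raise ConfigurationError(f"bad gradient_mode {self.gradient_mode!r}")
        if self.schedule not in ("online", "per_trial", "batch"):
            raise ConfigurationError(f"bad schedule {self.schedule!r}")
        if self.schedule == "batch" and self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.rule not in ("rflo", "rtrl", "bptt", "reinforce"):
            raise ConfigurationError(f"bad rule {self.rule!r}")


@dataclass
class ReinforceConfig:
    """Node-perturbation (REINFORCE) hyperparameters."""

    eta: float = 0.01
    noise_sigma: float = 0.1
    rbar_decay: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.rbar_decay < 1.0:
            raise ConfigurationError("rbar_decay must lie in (0, 1)")


def _feedback_vector(err_t: np.ndarray, params: RNNParams, feedback_mode: str) -> np.ndarray:
    if feedback_mode == "random":
        return params.B @ err_t
    return params.W_out.T @ err_t


def update_eligibility(
    traces: EligibilityTraces,
    u_t: np.ndarray,
    h_prev: np.ndarray,
    x_t: np.ndarray,
    params: RNNParams,
    eq6_literal: bool = False,
    x_prev: Optional[np.ndarray] = None,
) -> EligibilityTraces:
    """One step of the eligibility-trace recursion.

    p_ab <- (1/tau) phi'(u_a(t)) h_b(t-1) + (1 - 1/tau) p_ab, and likewise
    q with the input in place of the presynaptic rate.  With
    ``eq6_literal`` the input trace uses x(t-1) (``x_prev``; zeros at the
    first step) rather than x(t).
    """
    if u_t.shape != (params.n,) or h_prev.shape != (params.n,):
        raise ConfigurationError("u_t and h_prev must be length-N vectors")
    alpha = 1.0 / params.tau
    dphi = params.phi.derivative(u_t)
    x_for_trace = x_t
    if eq6_literal:
        x_for_trace = np.zeros(params.n_in) if x_prev is None else x_prev
    if x_for_trace.shape != (params.n_in,):
        raise ConfigurationError("input vector must have length N_x")
    p = alpha * np.outer(dphi, h_prev) + (1.0 - alpha) * traces.p
    q = alpha * np.outer(dphi, x_for_trace) + (1.0 - alpha) * traces.q
    return EligibilityTraces(p=p, q=q)


def rflo_step(
    h_t: np.ndarray,
    err_t: np.ndarray,
    traces: EligibilityTraces,
    params: RNNParams,
    cfg: LearningConfig,
) -> WeightUpdate:
    """Per-timestep RFLO update (traces must be current through time t)."""
    f = _feedback_vector(err_t, params, cfg.feedback_mode)
    dW_out = cfg.eta1 * np.outer(err_t, h_t)
    dW = cfg.eta2 * f[:, np.newaxis] * traces.p
    dW_in = cfg.eta3 * f[:, np.newaxis] * traces.q
    return WeightUpdate(dW_in=dW_in, dW=dW, dW_out=dW_out)


def rtrl_step(
    P: SensitivityTensor,
    u_t: np.ndarray,
    h_prev: np.ndarray,
    x_t: np.ndarray,
    params: RNNParams,
) -> SensitivityTensor:
    """One step of the exact forward-sensitivity recursion."""
    alpha = 1.0 / params.tau
    dphi = params.phi.derivative(u_t)
    n = params.n

    # nonlocal propagation term: (1/tau) phi'(u_j) sum_k W_jk P[k,a,b]
    prop = alpha * dphi[:, np.newaxis, np.newaxis] * np.tensordot(params.W, P.P, axes=(1, 0))
    new_P = (1.0 - alpha) * P.P + prop
    idx = np.arange(n)
    new_P[idx, idx, :] += alpha * dphi[:, np.newaxis] * h_prev[np.newaxis, :]

    prop_in = alpha * dphi[:, np.newaxis, np.newaxis] * np.tensordot(params.W, P.P_in, axes=(1, 0))
    new_P_in = (1.0 - alpha) * P.P_in + prop_in
    new_P_in[idx, idx, :] += alpha * dphi[:, np.newaxis] * x_t[np.newaxis, :]
    return SensitivityTensor(P=new_P, P_in=new_P_in)


def gradient_trial(
    params: RNNParams,
    trial: TrialData,
    h0: Optional[np.ndarray] = None,
    cfg: Optional[LearningConfig] = None,
    traj: Optional[Trajectory] = None,
) -> Tuple[WeightUpdate, Trajectory]:
    """Per-trial accumulated update for any (gradient_mode, feedback_mode).

    (local, random)     -> RFLO;
    (local, symmetric)  -> locality-only ablation;
    (full, random)      -> random-feedback-only ablation;
    (full, symmetric)   -> exact RTRL gradient descent.

    Returns the update (descent direction, learning rates and 1/T applied)
    along with the trajectory it was computed from.
    """
    cfg = cfg or LearningConfig(eta1=1.0, eta2=1.0, eta3=1.0, gradient_mode="full", feedback_mode="symmetric")
    if traj is None:
        traj = run_trial(params, trial, h0=h0)
    T = traj.T
    upd = WeightUpdate.zeros(params)
    local = cfg.gradient_mode == "local"
    state = EligibilityTraces.zeros(params) if local else SensitivityTensor.zeros(params)

    for i in range(T):
        u_t = traj.u_seq[i]
        h_prev = traj.h_seq[i]
        h_t = traj.h_seq[i + 1]
        x_t = traj.x_seq[i]
        err_t = traj.err_seq[i]
        if local:
            x_prev = traj.x_seq[i - 1] if i > 0 else None
            state = update_eligibility(
                state, u_t, h_prev, x_t, params, eq6_literal=cfg.eq6_literal, x_prev=x_prev
            )
            upd += rflo_step(h_t, err_t, state, params, cfg)
        else:
            state = rtrl_step(state, u_t, h_prev, x_t, params)
            f = _feedback_vector(err_t, params, cfg.feedback_mode)
            upd.dW_out += cfg.eta1 * np.outer(err_t, h_t)
            upd.dW += cfg.eta2 * np.tensordot(f, state.P, axes=(0, 0))
            upd.dW_in += cfg.eta3 * np.tensordot(f, state.P_in, axes=(0, 0))
    return upd.scaled(1.0 / T), traj


def rflo_gradient_trial(
    params: RNNParams,
    trial: TrialData,
    h0: Optional[np.ndarray] = None,
    cfg: Optional[LearningConfig] = None,
) -> Tuple[WeightUpdate, Trajectory]:
    """RFLO per-trial update (local gradient, random feedback by default)."""
    cfg = cfg or LearningConfig(eta1=1.0, eta2=1.0, eta3=1.0)
    if cfg.gradient_mode != "local":
        raise ConfigurationError("rflo requires gradient_mode='local'")
    return gradient_trial(params, trial, h0=h0, cfg=cfg)


def rtrl_gradient_trial(
    params: RNNParams,
    trial: TrialData,
    h0: Optional[np.ndarray] = None,
    feedback_mode: str = "symmetric",
    etas: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Tuple[WeightUpdate, Trajectory]:
    """Exact forward-mode gradient update (symmetric feedback = true RTRL)."""
    cfg = LearningConfig(
        eta1=etas[0], eta2=etas[1], eta3=etas[2],
        gradient_mode="full", feedback_mode=feedback_mode, rule="rtrl",
    )
    return gradient_trial(params, trial, h0=h0, cfg=cfg)


def bptt_gradient_trial(
    params: RNNParams,
    trial: TrialData,
    h0: Optional[np.ndarray] = None,
    etas: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Tuple[WeightUpdate, Trajectory]:
    """Exact gradient by reverse-time adjoint recursion.

    lam(T+1) = 0;
    lam(t) = (1/T) W_out^T err(t)
           + [(1-1/tau) I + (1/tau) W^T diag(phi'(u(t+1)))] lam(t+1);
    dW_ab = eta2 sum_t lam_a(t) (1/tau) phi'(u_a(t)) h_b(t-1),
    with the analogous input-weight form and the exact readout gradient.
    Must agree with ``rtrl_gradient_trial`` to floating-point accuracy.
    """
    traj = run_trial(params, trial, h0=h0)
    T = traj.T
    alpha = 1.0 / params.tau
    upd = WeightUpdate.zeros(params)
    lam = np.zeros(params.n)
    for i in range(T - 1, -1, -1):
        err_t = traj.err_seq[i]
        lam_direct = (1.0 / T) * (params.W_out.T @ err_t)
        if i == T - 1:
            lam = lam_direct
        else:
            dphi_next = params.phi.derivative(traj.u_seq[i + 1])
            lam = lam_direct + (1.0 - alpha) * lam + alpha * (params.W.T @ (dphi_next * lam))
        dphi_t = params.phi.derivative(traj.u_seq[i])
        pre = alpha * dphi_t * lam
        upd.dW += np.outer(pre, traj.h_seq[i])
        upd.dW_in += np.outer(pre, traj.x_seq[i])
        upd.dW_out += (1.0 / T) * np.outer(err_t, traj.h_seq[i + 1])
    upd.dW_in *= etas[2]
    upd.dW *= etas[1]
    upd.dW_out *= etas[0]
    return upd, traj


def reinforce_trial(
    params: RNNParams,
    trial: TrialData,
    h0: Optional[np.ndarray],
    rcfg: ReinforceConfig,
    rbar: Optional[float],
    rng: np.random.Generator,
) -> Tuple[WeightUpdate, float, float]:
    """One trial of node-perturbation learning.

    Noise xi_a(t) ~ N(0, sigma^2) is injected into every input current; at
    trial end the recurrent weights move by
    dW_ab = (eta/T)(R - Rbar) sum_t xi_a(t) h_b(t) with reward R = -L.
    Returns (update, R, updated running-average reward).  ``rbar=None``
    initialises the baseline at R (zero update on the first trial).
    """
    T = trial.T
    noise = rng.normal(0.0, rcfg.noise_sigma, size=(T, params.n)) if rcfg.noise_sigma > 0 else np.zeros((T, params.n))
    traj = run_trial(params, trial, h0=h0, noise_seq=noise)
    R = -compute_loss(traj)
    if rbar is None:
        rbar = R
    dW = (rcfg.eta / T) * (R - rbar) * (noise.T @ traj.h_seq[1:])
    upd = WeightUpdate(dW_in=np.zeros_like(params.W_in), dW=dW, dW_out=np.zeros_like(params.W_out))
    rbar_new = rcfg.rbar_decay * rbar + (1.0 - rcfg.rbar_decay) * R
    return upd, R, rbar_new


def apply_updates(
    params: RNNParams,
    upd: WeightUpdate,
    rule: str = "rflo",
    trial_index: int = 0,
) -> RNNParams:
    """Add an update to the weights in place, re-imposing Dale's law if set."""
    if not upd.is_finite():
        raise TrainingDivergedError(rule, trial_index, "non-finite weight update")
    params.W_in += upd.dW_in
    params.W += upd.dW
    params.W_out += upd.dW_out
    if params.dale_signs is not None:
        params.W = apply_dale_constraint(params.W, params.dale_signs)
    return params
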