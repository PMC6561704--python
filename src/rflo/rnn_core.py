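"""Core recurrent-network machinery: parameters, dynamics, loss.

The network is a leaky rate RNN of ``N`` units with time constant ``tau``
(in timesteps),

    h(t) = (1 - 1/tau) h(t-1) + (1/tau) phi(u(t)),
    u(t) = W h(t-1) + W_in x(t)            [+ B y(t-1) in readout-feedback mode],
    y(t) = W_out h(t),

driven for ``T`` steps by an input sequence ``x`` and compared against a
target ``y*`` through the time-averaged squared error

    L = (1/2T) sum_{t=1..T} |y*(t) - y(t)|^2.

Trials are indexed ``t = 1..T``; array row ``t-1`` of the input/output
sequences holds the quantities at time ``t``, while ``h_seq`` additionally
stores the initial state ``h(0)`` in row 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import h5py
import numpy as np

__all__ = [
    "ActivationFunction",
    "RNNParams",
    "RNNState",
    "Trajectory",
    "TrialData",
    "get_activation",
    "init_params",
    "step",
    "run_trial",
    "compute_loss",
    "apply_dale_constraint",
    "save_params",
    "load_params",
    "ConfigurationError",
    "UndefinedLossError",
]


class ConfigurationError(ValueError):
    """Raised for invalid network or learning configuration."""


class UndefinedLossError(ValueError):
    """Raised when the loss is requested for an empty trajectory."""


@dataclass(frozen=True)
class ActivationFunction:
    """Pointwise activation with its exact analytic derivative."""

    name: str
    value: Callable[[np.ndarray], np.ndarray]
    derivative: Callable[[np.ndarray], np.ndarray]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ActivationFunction({self.name!r})"


_TANH = ActivationFunction("tanh", np.tanh, lambda u: 1.0 - np.tanh(u) ** 2)
_LINEAR = ActivationFunction(
    "linear", lambda u: np.asarray(u, dtype=float), lambda u: np.ones_like(u, dtype=float)
)
_ACTIVATIONS = {"tanh": _TANH, "linear": _LINEAR}


def get_activation(name: str) -> ActivationFunction:
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ConfigurationError(f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}")


@dataclass
class RNNParams:
    """All synaptic weights plus the fixed random feedback matrix.

    ``B`` (shape N x N_y) projects the output error back into the network
    for learning; in ``readout_feedback`` mode it additionally carries the
    readout itself back as an input current (used when only the readout is
    trained, to stabilise the otherwise untrained recurrent dynamics).
    """

    W_in: np.ndarray  # N x N_x
    W: np.ndarray  # N x N
    W_out: np.ndarray  # N_y x N
    B: np.ndarray  # N x N_y
    tau: float
    phi: ActivationFunction = _TANH
    dale_signs: Optional[np.ndarray] = None  # length N, entries +-1
    readout_feedback: bool = False

    def __post_init__(self) -> None:
        self.W_in = np.asarray(self.W_in, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.W_out = np.asarray(self.W_out, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ConfigurationError(f"W must be square, got {self.W.shape}")
        if self.W_in.shape[0] != n:
            raise ConfigurationError("W_in rows must match N")
        if self.W_out.shape[1] != n:
            raise ConfigurationError("W_out columns must match N")
        if self.B.shape != (n, self.W_out.shape[0]):
            raise ConfigurationError("B must be N x N_y")
        if self.tau < 1:
            raise ConfigurationError(f"tau must be >= 1 timestep, got {self.tau}")
        if self.dale_signs is not None:
            self.dale_signs = np.asarray(self.dale_signs, dtype=float)
            if self.dale_signs.shape != (n,) or not np.all(np.abs(self.dale_signs) == 1):
                raise ConfigurationError("dale_signs must be a length-N vector of +-1")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def n_in(self) -> int:
        return self.W_in.shape[1]

    @property
    def n_out(self) -> int:
        return self.W_out.shape[0]

    def copy(self) -> "RNNParams":
        return RNNParams(
            W_in=self.W_in.copy(),
            W=self.W.copy(),
            W_out=self.W_out.copy(),
            B=self.B.copy(),
            tau=self.tau,
            phi=self.phi,
            dale_signs=None if self.dale_signs is None else self.dale_signs.copy(),
            readout_feedback=self.readout_feedback,
        )


@dataclass
class RNNState:
    h: np.ndarray
    u: np.ndarray
    t: int


@dataclass
class Trajectory:
    """One trial's worth of states, currents, outputs and errors."""

    h_seq: np.ndarray  # (T+1) x N, row 0 is h(0)
    u_seq: np.ndarray  # T x N
    y_seq: np.ndarray  # T x N_y
    err_seq: np.ndarray  # T x N_y
    x_seq: np.ndarray  # T x N_x

    @property
    def T(self) -> int:
        return self.y_seq.shape[0]


@dataclass
class TrialData:
    """Input and target sequences defining one trial of a task."""

    x_seq: np.ndarray  # T x N_x
    ystar_seq: np.ndarray  # T x N_y
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_seq = np.atleast_2d(np.asarray(self.x_seq, dtype=float))
        self.ystar_seq = np.atleast_2d(np.asarray(self.ystar_seq, dtype=float))
        if self.x_seq.shape[0] != self.ystar_seq.shape[0]:
            raise ConfigurationError("x_seq and ystar_seq must share trial length T")

    @property
    def T(self) -> int:
        return self.ystar_seq.shape[0]


def init_params(
    N: int,
    N_x: int,
    N_y: int,
    tau: float = 10.0,
    g: float = 1.5,
    seed: int | np.random.Generator = 0,
    dale: bool = False,
    phi: str | ActivationFunction = "tanh",
    readout_feedback: bool = False,
) -> RNNParams:
    """Random initialisation of all weights.

    Recurrent weights ~ N(0, g^2/N); input weights uniform on [-1, 1];
    readout weights uniform on [-1/N, 1/N]; feedback weights ~ N(0, 1).
    In Dale mode the first half of the units is excitatory and the second
    half inhibitory: column j of W is sign-rectified to xi_j |W_ij|.
    """
    if N < 0 or N_x < 0 or N_y < 0:
        raise ConfigurationError("network sizes must be non-negative")
    if tau < 1:
        raise ConfigurationError("tau must be >= 1")
    if g <= 0:
        raise ConfigurationError("g must be positive")
    if isinstance(phi, str):
        phi = get_activation(phi)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    W_in = rng.uniform(-1.0, 1.0, size=(N, N_x))
    W = rng.normal(0.0, g / np.sqrt(N) if N else 0.0, size=(N, N))
    W_out = rng.uniform(-1.0 / N if N else 0.0, 1.0 / N if N else 0.0, size=(N_y, N))
    B = rng.normal(0.0, 1.0, size=(N, N_y))

    dale_signs = None
    if dale:
        if N % 2:
            raise ConfigurationError("Dale mode requires an even number of units")
        dale_signs = np.concatenate([np.ones(N // 2), -np.ones(N // 2)])
        W = np.abs(W) * dale_signs[np.newaxis, :]

    return RNNParams(
        W_in=W_in,
        W=W,
        W_out=W_out,
        B=B,
        tau=float(tau),
        phi=phi,
        dale_signs=dale_signs,
        readout_feedback=readout_feedback,
    )


def step(
    state: RNNState,
    x_next: np.ndarray,
    params: RNNParams,
    y_prev: Optional[np.ndarray] = None,
) -> RNNState:
    """Advance the dynamics by one timestep (synchronous update)."""
    h = state.h
    if h.shape != (params.n,):
        raise ConfigurationError(f"state.h has shape {h.shape}, expected ({params.n},)")
    x_next = np.asarray(x_next, dtype=float)
    if x_next.shape != (params.n_in,):
        raise ConfigurationError(f"x_next has shape {x_next.shape}, expected ({params.n_in},)")
    u = params.W @ h + params.W_in @ x_next
    if params.readout_feedback:
        if y_prev is None:
            y_prev = params.W_out @ h
        u = u + params.B @ y_prev
    alpha = 1.0 / params.tau
    h_new = (1.0 - alpha) * h + alpha * params.phi.value(u)
    return RNNState(h=h_new, u=u, t=state.t + 1)


def run_trial(
    params: RNNParams,
    trial: TrialData,
    h0: Optional[np.ndarray] = None,
    noise_seq: Optional[np.ndarray] = None,
) -> Trajectory:
    """Integrate the dynamics over a whole trial and record everything.

    ``noise_seq`` (T x N), when given, is added to the input current at each
    step (used by the node-perturbation/REINFORCE baseline).
    """
    N, N_y, T = params.n, params.n_out, trial.T
    if h0 is None:
        h0 = np.zeros(N)
    h0 = np.asarray(h0, dtype=float)
    if h0.shape != (N,):
        raise ConfigurationError(f"h0 has shape {h0.shape}, expected ({N},)")

    h_seq = np.empty((T + 1, N))
    u_seq = np.empty((T, N))
    y_seq = np.empty((T, N_y))
    h_seq[0] = h0
    alpha = 1.0 / params.tau
    h = h0
    for i in range(T):
        u = params.W @ h + params.W_in @ trial.x_seq[i]
        if params.readout_feedback:
            u = u + params.B @ (params.W_out @ h)
        if noise_seq is not None:
            u = u + noise_seq[i]
        h = (1.0 - alpha) * h + alpha * params.phi.value(u)
        h_seq[i + 1] = h
        u_seq[i] = u
        y_seq[i] = params.W_out @ h
    err_seq = trial.ystar_seq - y_seq
    return Trajectory(h_seq=h_seq, u_seq=u_seq, y_seq=y_seq, err_seq=err_seq, x_seq=trial.x_seq)


def compute_loss(traj: Trajectory) -> float:
    """Time-averaged squared output error, L = (1/2T) sum_t |err(t)|^2."""
    if traj.T == 0:
        raise UndefinedLossError("loss is undefined for an empty trial (T=0)")
    return float(0.5 * np.sum(traj.err_seq**2) / traj.T)


def apply_dale_constraint(W: np.ndarray, dale_signs: np.ndarray) -> np.ndarray:
    """Clip to zero any entry whose sign disagrees with its column's sign.

    Column j of W carries the outgoing weights of unit j; Dale's law requires
    xi_j * W[i, j] >= 0 for all i.
    """
    W = np.asarray(W, dtype=float)
    dale_signs = np.asarray(dale_signs, dtype=float)
    out = np.where(W * dale_signs[np.newaxis, :] < 0, 0.0, W)
    return out


def trajectory_to_frame(traj: Trajectory):
    """Tabulate a trajectory (columns t, h_1..h_N, y_1..y_Ny, err_1..err_Ny)
    for CSV dumping or plotting."""
    import pandas as pd

    cols = {"t": np.arange(1, traj.T + 1)}
    for i in range(traj.h_seq.shape[1]):
        cols[f"h_{i + 1}"] = traj.h_seq[1:, i]
    for k in range(traj.y_seq.shape[1]):
        cols[f"y_{k + 1}"] = traj.y_seq[:, k]
    for k in range(traj.err_seq.shape[1]):
        cols[f"err_{k + 1}"] = traj.err_seq[:, k]
    return pd.DataFrame(cols)


def save_params(params: RNNParams, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("W_in", "W", "W_out", "B"):
            f.create_dataset(name, data=getattr(params, name))
        if params.dale_signs is not None:
            f.create_dataset("dale_signs", data=params.dale_signs)
        f.attrs["tau"] = params.tau
        f.attrs["phi"] = params.phi.name
        f.attrs["readout_feedback"] = params.readout_feedback


def load_params(path) -> RNNParams:
    with h5py.File(path, "r") as f:
        return RNNParams(
            W_in=f["W_in"][...],
            W=f["W"][...],
            W_out=f["W_out"][...],
            B=f["B"][...],
            tau=float(f.attrs["tau"]),
            phi=get_activation(str(f.attrs["phi"])),
            dale_signs=f["dale_signs"][...] if "dale_signs" in f else None,
            readout_feedback=bool(f.attrs["readout_feedback"]),
        )
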