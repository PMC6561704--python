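"""Syllable sequencing via an auxiliary loop with winner-take-all selection.

A pre-trained network produces short reach/hold "syllables", one per tonic
input.  An auxiliary loop reads the hidden state at the end of each
syllable through learned weights W^s (z = W^s h), a winner-take-all rule
picks the next syllable (with epsilon-greedy exploration and with actions
that would push the cursor out of bounds masked off), and W^s is trained
with the reward-modulated Hebbian rule dW^s_ij = eta_s R z_i h_j, where
R = 1 exactly when the executed syllable transition matches the target
sequence.  The loop readout is gated: W^s is consulted and updated only at
syllable boundaries.

Actions are encoded as integers 0..2n-1 over n tonic channels: action
a < n is a reach along direction a, action a >= n is a hold with channel
a - n active.

Note on the Hebbian factor z_i: applied to the raw pre-competition readout
the printed rule only rescales z in each context (dz ∝ z |h|^2) and can
never reorder action preferences, so the driver passes the
post-winner-take-all activity (one-hot on the winning unit) to
``ws_update``; the update then reinforces the winning row only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .rnn_core import ConfigurationError, RNNParams, run_trial
from .tasks import ReachTaskSpec, reach_syllable_trial

__all__ = [
    "LoopParams",
    "CursorState",
    "SequenceTarget",
    "IdealizedSyllableEmulator",
    "RNNSyllableRunner",
    "wta_select",
    "ws_update",
    "run_sequence_trial",
    "train_sequence",
    "NoValidActionError",
]


class NoValidActionError(RuntimeError):
    """Raised when the out-of-bounds mask leaves no selectable action."""


@dataclass
class LoopParams:
    """Loop readout weights and selection hyperparameters."""

    Ws: np.ndarray  # n_actions x N
    eta_s: float = 0.05
    p_explore: float = 0.1

    def __post_init__(self) -> None:
        self.Ws = np.asarray(self.Ws, dtype=float)
        if not 0.0 <= self.p_explore <= 1.0:
            raise ConfigurationError("p_explore must be a probability")
        if not np.all(np.isfinite(self.Ws)):
            raise ConfigurationError("Ws must be finite")

    @classmethod
    def init(cls, n_actions: int, N: int, seed: int | np.random.Generator = 0,
             eta_s: float = 0.05, p_explore: float = 0.1) -> "LoopParams":
        # small random init: with Ws = 0 the Hebbian rule (∝ z) never starts
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return cls(Ws=rng.normal(0.0, 1.0 / N, size=(n_actions, N)), eta_s=eta_s, p_explore=p_explore)


@dataclass
class CursorState:
    pos: np.ndarray
    bounds: float

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)

    def in_bounds(self, displacement: np.ndarray) -> bool:
        return bool(np.all(np.abs(self.pos + displacement) <= self.bounds + 1e-12))


@dataclass
class SequenceTarget:
    """Ordered target sequence of action ids, with its transition table."""

    syllable_ids: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.syllable_ids) == 0:
            raise ConfigurationError("target sequence must be non-empty")
        self.syllable_ids = [int(s) for s in self.syllable_ids]

    def successor_table(self) -> dict:
        """Map previous action (or None for trial start) to the target next.

        The table is cyclic so that a transition is defined from every
        action in the sequence even after an exploratory detour.
        """
        table = {None: self.syllable_ids[0]}
        n = len(self.syllable_ids)
        for k, s in enumerate(self.syllable_ids):
            table[s] = self.syllable_ids[(k + 1) % n]
        return table


def default_sequence_target(n_syllables: int = 4) -> SequenceTarget:
    """Alternating reach/hold sequence: move 0, hold 0, move 1, hold 1, ..."""
    ids: List[int] = []
    for k in range(n_syllables):
        ids.extend([k, k + n_syllables])
    return SequenceTarget(ids)


class IdealizedSyllableEmulator:
    """Test double for a pre-trained syllable network.

    Supplies a distinct, reproducible hidden state at the end of each
    syllable and the exact displacement each syllable produces, so that
    loop learning can be studied independently of how well the network
    itself was trained.  The scripted states are mutually *orthogonal*
    (orthonormalised Gaussian vectors scaled to norm sqrt(N)): being
    idealised, the emulator removes the context cross-talk that the
    unnormalised Hebbian rule cannot correct, which real (correlated) RNN
    states reintroduce.  Marked synthetic: it scripts the network rather
    than running one.
    """

    def __init__(self, spec: ReachTaskSpec, N: int = 100, seed: int = 0) -> None:
        self.spec = spec
        self.N = N
        rng = np.random.default_rng(seed)
        self.n_actions = 2 * spec.n_syllables
        if self.n_actions + 1 > N:
            raise ConfigurationError("emulator needs N >= number of actions + 1")
        q, _ = np.linalg.qr(rng.normal(size=(N, self.n_actions + 1)))
        states = np.sqrt(N) * q.T  # rows orthogonal, norm sqrt(N)
        self._h_start = states[0]
        self._h_end = states[1:]

    def initial_state(self) -> np.ndarray:
        return self._h_start.copy()

    def run(self, action: int) -> Tuple[np.ndarray, np.ndarray]:
        n = self.spec.n_syllables
        disp = self.spec.displacement(action % n, hold=action >= n)
        return self._h_end[action].copy(), disp


class RNNSyllableRunner:
    """Runs an actual network one syllable at a time, carrying its state."""

    def __init__(self, params: RNNParams, spec: ReachTaskSpec) -> None:
        if params.n_in != spec.n_syllables:
            raise ConfigurationError("network input size must equal the number of tonic channels")
        if params.n_out != 2:
            raise ConfigurationError("cursor control needs a 2-D readout")
        self.params = params
        self.spec = spec
        self._h = np.zeros(params.n)

    def initial_state(self) -> np.ndarray:
        self._h = np.zeros(self.params.n)
        return self._h.copy()

    def run(self, action: int) -> Tuple[np.ndarray, np.ndarray]:
        n = self.spec.n_syllables
        trial = reach_syllable_trial(self.spec, action % n, hold=action >= n)
        traj = run_trial(self.params, trial, h0=self._h)
        self._h = traj.h_seq[-1].copy()
        return self._h.copy(), traj.y_seq.sum(axis=0)


def wta_select(
    z: np.ndarray,
    p_explore: float,
    allowed: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Winner-take-all with epsilon-greedy exploration over allowed actions.

    With probability ``p_explore`` an allowed action is drawn uniformly;
    otherwise the most active allowed unit wins (ties to the lowest index).
    """
    allowed = np.asarray(allowed, dtype=bool)
    idx = np.flatnonzero(allowed)
    if idx.size == 0:
        raise NoValidActionError("every action is masked")
    if p_explore > 0 and rng.random() < p_explore:
        return int(rng.choice(idx))
    z = np.asarray(z, dtype=float)
    masked = np.where(allowed, z, -np.inf)
    return int(np.argmax(masked))


def ws_update(
    loop: LoopParams,
    z: np.ndarray,
    h_end: np.ndarray,
    chosen: int,
    R: int,
) -> LoopParams:
    """Reward-modulated Hebbian update: Ws += eta_s * R * outer(z, h_end).

    ``z`` is the loop-unit activity vector to use as the Hebbian
    postsynaptic factor (the sequence driver passes the post-competition
    one-hot of ``chosen``); no update occurs when R = 0.
    """
    if R:
        loop.Ws += loop.eta_s * R * np.outer(z, h_end)
    return loop


def _allowed_mask(cursor: CursorState, spec: ReachTaskSpec) -> np.ndarray:
    n_actions = 2 * spec.n_syllables
    mask = np.ones(n_actions, dtype=bool)
    for a in range(spec.n_syllables):
        mask[a] = cursor.in_bounds(spec.displacement(a))
    return mask  # holds (a >= n) displace nothing and stay allowed


def run_sequence_trial(
    runner,
    loop: LoopParams,
    task: ReachTaskSpec,
    target: SequenceTarget,
    rng: np.random.Generator,
    learn: bool = True,
) -> Tuple[List[int], np.ndarray, CursorState]:
    """One trial: select, execute and (optionally) learn each transition.

    ``runner`` is any object with ``initial_state()`` and
    ``run(action) -> (h_end, displacement)`` — an
    :class:`IdealizedSyllableEmulator` or :class:`RNNSyllableRunner`.
    Returns the chosen actions, the per-transition rewards, and the final
    cursor state.
    """
    succ = target.successor_table()
    cursor = CursorState(pos=np.zeros(2), bounds=task.bounds)
    h = runner.initial_state()
    prev: Optional[int] = None
    chosen_seq: List[int] = []
    rewards = np.zeros(len(target.syllable_ids))
    for k in range(len(target.syllable_ids)):
        z = loop.Ws @ h
        allowed = _allowed_mask(cursor, task)
        chosen = wta_select(z, loop.p_explore, allowed, rng)
        R = int(succ.get(prev) == chosen)
        if learn:
            z_wta = np.zeros(loop.Ws.shape[0])
            z_wta[chosen] = 1.0
            ws_update(loop, z_wta, h, chosen, R)
        h, disp = runner.run(chosen)
        cursor.pos = cursor.pos + disp
        chosen_seq.append(chosen)
        rewards[k] = R
        prev = chosen
    return chosen_seq, rewards, cursor


def train_sequence(
    runner,
    loop: LoopParams,
    task: ReachTaskSpec,
    target: SequenceTarget,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Train W^s for ``n_trials``; returns the (n_trials x len(target))
    per-transition reward history."""
    history = np.zeros((n_trials, len(target.syllable_ids)))
    for i in range(n_trials):
        _, rewards, _ = run_sequence_trial(runner, loop, task, target, rng, learn=True)
        history[i] = rewards
    return history
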