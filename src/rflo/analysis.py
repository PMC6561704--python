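"""Metrics and experiment drivers: training loops, alignment, grid search.

Training logs are plain pandas DataFrames with one row per (seed, trial)
and columns ``trial, loss, alignment, rule, seed, diverged``.  Row
``trial = 0`` records the untrained network's loss before any update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .rnn_core import (
    ConfigurationError,
    RNNParams,
    TrialData,
    compute_loss,
    run_trial,
)
from .learning_rules import (
    EligibilityTraces,
    LearningConfig,
    ReinforceConfig,
    TrainingDivergedError,
    WeightUpdate,
    apply_updates,
    bptt_gradient_trial,
    gradient_trial,
    reinforce_trial,
    rflo_step,
    update_eligibility,
    LOSS_DIVERGENCE_LIMIT,
)
from .tasks import ReadySetGoSpec, ready_set_go_trial

__all__ = [
    "GridSpec",
    "feedback_alignment",
    "peak_time",
    "output_correlation",
    "train_single",
    "train_reinforce",
    "training_run",
    "summarize_log",
    "grid_search",
    "evaluate_interval_matching",
]

TrialSampler = Callable[[np.random.Generator], TrialData]


def feedback_alignment(W_out: np.ndarray, B: np.ndarray) -> float:
    """Normalized alignment (matrix cosine) between W_out^T and B.

    Frobenius inner product of the transposed readout weights with the
    feedback weights, divided by the product of their Frobenius norms;
    0 by convention when either matrix vanishes.
    """
    W_out = np.asarray(W_out, dtype=float)
    B = np.asarray(B, dtype=float)
    num = float(np.sum(W_out.T * B))
    denom = float(np.linalg.norm(W_out) * np.linalg.norm(B))
    if denom == 0.0:
        return 0.0
    return num / denom


def peak_time(y_seq: np.ndarray, window: Tuple[int, int]) -> int:
    """Index of the maximum of ``y_seq`` within the inclusive window.

    Ties resolve to the earliest index.  Indices refer to positions in
    ``y_seq`` (0-based).
    """
    y = np.asarray(y_seq, dtype=float).ravel()
    t_lo, t_hi = window
    if not 0 <= t_lo < t_hi <= len(y) - 1:
        raise ConfigurationError(f"bad peak window {window} for length-{len(y)} sequence")
    return t_lo + int(np.argmax(y[t_lo : t_hi + 1]))


def output_correlation(y_seq: np.ndarray, ystar_seq: np.ndarray) -> float:
    """Pearson correlation over time between output and target (flattened)."""
    y = np.asarray(y_seq, dtype=float).ravel()
    ystar = np.asarray(ystar_seq, dtype=float).ravel()
    if y.shape != ystar.shape:
        raise ConfigurationError("sequences must have equal length")
    if np.std(y) == 0 or np.std(ystar) == 0:
        raise ConfigurationError("correlation undefined for constant sequence")
    return float(stats.pearsonr(y, ystar).statistic)


def _check_divergence(loss: float, params: RNNParams, rule: str, i: int) -> None:
    if not np.isfinite(loss) or loss > LOSS_DIVERGENCE_LIMIT:
        raise TrainingDivergedError(rule, i, f"loss={loss}")
    if not np.all(np.isfinite(params.W)):
        raise TrainingDivergedError(rule, i, "non-finite recurrent weights")


def _online_trial(params: RNNParams, trial: TrialData, h0: np.ndarray, cfg: LearningConfig) -> float:
    """Run one trial applying RFLO updates at every timestep."""
    if cfg.gradient_mode != "local":
        raise ConfigurationError("online schedule supports the local rule only")
    alpha = 1.0 / params.tau
    traces = EligibilityTraces.zeros(params)
    h = h0.copy()
    sq = 0.0
    T = trial.T
    x_prev = None
    for i in range(T):
        x_t = trial.x_seq[i]
        u = params.W @ h + params.W_in @ x_t
        if params.readout_feedback:
            u = u + params.B @ (params.W_out @ h)
        h_prev = h
        h = (1.0 - alpha) * h + alpha * params.phi.value(u)
        err = trial.ystar_seq[i] - params.W_out @ h
        traces = update_eligibility(traces, u, h_prev, x_t, params, eq6_literal=cfg.eq6_literal, x_prev=x_prev)
        upd = rflo_step(h, err, traces, params, cfg)
        apply_updates(params, upd, rule=cfg.rule)
        sq += float(err @ err)
        x_prev = x_t
    return 0.5 * sq / T


def _trial_update(
    params: RNNParams, trial: TrialData, h0: np.ndarray, cfg: LearningConfig
) -> Tuple[WeightUpdate, float]:
    if cfg.rule == "bptt":
        upd, traj = bptt_gradient_trial(params, trial, h0=h0, etas=(cfg.eta1, cfg.eta2, cfg.eta3))
    else:
        upd, traj = gradient_trial(params, trial, h0=h0, cfg=cfg)
    return upd, compute_loss(traj)


def train_single(
    params: RNNParams,
    trial_sampler: TrialSampler,
    cfg: LearningConfig,
    n_trials: int,
    rng: np.random.Generator,
    h0: Optional[np.ndarray] = None,
    seed_label: int = 0,
    record_alignment: bool = True,
) -> pd.DataFrame:
    """Train one network in place; returns its per-trial log.

    Row 0 holds the untrained loss on a freshly sampled trial.  ``h0`` is
    reused on every trial (zeros when omitted).
    """
    if h0 is None:
        h0 = np.zeros(params.n)
    records: List[dict] = []

    def log(i: int, loss: float) -> None:
        records.append(
            {
                "trial": i,
                "loss": loss,
                "alignment": feedback_alignment(params.W_out, params.B) if record_alignment else np.nan,
                "rule": cfg.rule,
                "seed": seed_label,
                "diverged": False,
            }
        )

    log(0, compute_loss(run_trial(params, trial_sampler(rng), h0=h0)))
    pending = WeightUpdate.zeros(params)
    in_batch = 0
    for i in range(1, n_trials + 1):
        trial = trial_sampler(rng)
        if cfg.schedule == "online":
            loss = _online_trial(params, trial, h0, cfg)
        else:
            upd, loss = _trial_update(params, trial, h0, cfg)
            if cfg.schedule == "per_trial":
                apply_updates(params, upd, rule=cfg.rule, trial_index=i)
            else:
                pending += upd
                in_batch += 1
                if in_batch == cfg.batch_size:
                    apply_updates(params, pending, rule=cfg.rule, trial_index=i)
                    pending = WeightUpdate.zeros(params)
                    in_batch = 0
        _check_divergence(loss, params, cfg.rule, i)
        log(i, loss)
    return pd.DataFrame.from_records(records)


def train_reinforce(
    params: RNNParams,
    trial_sampler: TrialSampler,
    rcfg: ReinforceConfig,
    n_trials: int,
    rng: np.random.Generator,
    h0: Optional[np.ndarray] = None,
    seed_label: int = 0,
) -> pd.DataFrame:
    """Node-perturbation training loop (recurrent weights only)."""
    if h0 is None:
        h0 = np.zeros(params.n)
    records: List[dict] = []
    records.append(
        {
            "trial": 0,
            "loss": compute_loss(run_trial(params, trial_sampler(rng), h0=h0)),
            "alignment": np.nan,
            "rule": "reinforce",
            "seed": seed_label,
            "diverged": False,
        }
    )
    rbar: Optional[float] = None
    for i in range(1, n_trials + 1):
        trial = trial_sampler(rng)
        upd, R, rbar = reinforce_trial(params, trial, h0, rcfg, rbar, rng)
        apply_updates(params, upd, rule="reinforce", trial_index=i)
        loss = -R
        _check_divergence(loss, params, "reinforce", i)
        records.append(
            {"trial": i, "loss": loss, "alignment": np.nan, "rule": "reinforce",
             "seed": seed_label, "diverged": False}
        )
    return pd.DataFrame.from_records(records)


def training_run(
    init_fn: Callable[[int], Tuple[RNNParams, np.ndarray]],
    trial_sampler: TrialSampler,
    cfg: LearningConfig,
    n_trials: int,
    seeds: Sequence[int],
    record_alignment: bool = True,
) -> pd.DataFrame:
    """Train one network per seed; a diverging seed is flagged, the rest run.

    ``init_fn(seed) -> (params, h0)`` builds the network and its initial
    state for that realisation.
    """
    logs: List[pd.DataFrame] = []
    for seed in seeds:
        params, h0 = init_fn(seed)
        rng = np.random.default_rng(seed)
        try:
            log = train_single(
                params, trial_sampler, cfg, n_trials, rng, h0=h0,
                seed_label=seed, record_alignment=record_alignment,
            )
        except TrainingDivergedError:
            log = pd.DataFrame(
                [{"trial": np.nan, "loss": np.nan, "alignment": np.nan,
                  "rule": cfg.rule, "seed": seed, "diverged": True}]
            )
        logs.append(log)
    return pd.concat(logs, ignore_index=True)


def summarize_log(log: pd.DataFrame) -> pd.DataFrame:
    """Median and 25/75 percentiles of the loss across seeds, per trial."""
    ok = log[~log["diverged"]]
    g = ok.groupby("trial")["loss"]
    return pd.DataFrame(
        {"median": g.median(), "q25": g.quantile(0.25), "q75": g.quantile(0.75)}
    ).reset_index()


def final_loss(log: pd.DataFrame, window: int = 100) -> float:
    """Median across seeds of the median loss over each seed's last
    ``window`` trials."""
    ok = log[~log["diverged"]]
    per_seed = ok.sort_values("trial").groupby("seed")["loss"].apply(lambda s: s.tail(window).median())
    return float(per_seed.median())


def _default_etas() -> tuple:
    return tuple(c * 10.0**k for k in range(-4, 0) for c in (1.0, 3.0))


@dataclass(frozen=True)
class GridSpec:
    """Learning-rate grid: {1,3} x 10^k for k = -4..-1 by default."""

    etas: Sequence[float] = field(default_factory=_default_etas)
    n_seeds: int = 3
    trials: int = 1000

    def __post_init__(self) -> None:
        if len(self.etas) == 0 or min(self.etas) <= 0:
            raise ConfigurationError("etas must be non-empty and positive")


def grid_search(
    init_fn: Callable[[int], Tuple[RNNParams, np.ndarray]],
    trial_sampler: TrialSampler,
    cfg_template: LearningConfig,
    grid: GridSpec,
    base_seed: int = 0,
) -> Tuple[float, pd.DataFrame]:
    """Select the learning rate minimising the final-100-trial median loss.

    eta1 = eta2 = eta3 = eta for every grid point.  Rows that diverged are
    flagged and never selected; if every eta diverges an error is raised.
    """
    from dataclasses import replace

    rows = []
    for eta in grid.etas:
        cfg = replace(cfg_template, eta1=eta, eta2=eta, eta3=eta)
        seeds = [base_seed + k for k in range(grid.n_seeds)]
        log = training_run(init_fn, trial_sampler, cfg, grid.trials, seeds, record_alignment=False)
        diverged = bool(log["diverged"].any())
        fl = np.nan if log["diverged"].all() else final_loss(log)
        rows.append({"eta": eta, "final_loss": fl, "diverged": diverged})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["final_loss"])
    if valid.empty:
        raise TrainingDivergedError("grid_search", -1, "all learning rates diverged")
    best_eta = float(valid.loc[valid["final_loss"].idxmin(), "eta"])
    return best_eta, table


def evaluate_interval_matching(
    params: RNNParams,
    spec: ReadySetGoSpec,
    delays: Sequence[int],
    h0: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Produced-vs-target delays for a trained Ready-Set-Go network.

    For each delay, the produced delay is the peak time of the output
    (searched from the second input pulse to trial end) minus the second
    pulse time.
    """
    rows = []
    for d in delays:
        trial = ready_set_go_trial(spec, delay=int(d))
        traj = run_trial(params, trial, h0=h0)
        t2 = trial.meta["t_second_pulse"]
        peak = peak_time(traj.y_seq[:, 0], (t2 - 1, traj.T - 1))
        rows.append({"delay": int(d), "produced_delay": (peak + 1) - t2})
    return pd.DataFrame(rows)
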