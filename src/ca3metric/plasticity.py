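"""Trace-based Hebbian plasticity on the CA3 recurrent collaterals.

During an exploration session the recurrent weights change as

    dJ_ij(t) = gamma * eta_i(t) * (eta_j(t) - Lambda_j(t))

where ``Lambda_j`` is a trace of the presynaptic cell's recent activity, the
arithmetic mean of its rates over the preceding ``tau`` steps (default 14
steps, 1750 ms at a 125 ms step).  Subtracting the trace makes potentiation
selective for presynaptic cells firing above their own recent average, i.e.
for genuinely overlapping place fields rather than merely high mean rates.

Weights are kept non-negative (reset to zero whenever an update would make
them negative) and, at the end of the session, the incoming weights of every
unit are normalised to sum to one.  While learning is in progress the
recurrent contribution to activity is computed with the weights frozen at
their uniform initial value; the accumulated weights only take effect when
installed at the end of the phase.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .dg import DGPopulation, dg_rates
from .environment import Trajectory
from .network import CA3Network, sequential_activity

__all__ = [
    "TraceState",
    "LearningConfig",
    "update_trace",
    "hebbian_step",
    "normalize_incoming",
    "run_learning_phase",
]


@dataclass
class TraceState:
    """Running presynaptic trace: mean of the last ``tau`` rate vectors.

    Before ``tau`` steps have elapsed the mean is taken over whatever history
    exists; with no history the trace is zero.
    """

    n_units: int
    tau: int = 14
    history: deque = field(default_factory=deque)

    @property
    def trace(self) -> np.ndarray:
        if not self.history:
            return np.zeros(self.n_units)
        return np.mean(self.history, axis=0)


def update_trace(state: TraceState, pre_rates: np.ndarray) -> TraceState:
    """Push a rate vector into the trace window (oldest entry dropped at tau)."""
    pre_rates = np.asarray(pre_rates, dtype=float)
    if pre_rates.shape != (state.n_units,):
        raise ValueError("pre_rates length does not match the trace state")
    hist = deque(state.history, maxlen=None)
    hist.append(pre_rates.copy())
    if len(hist) > state.tau:
        hist.popleft()
    return TraceState(n_units=state.n_units, tau=state.tau, history=hist)


@dataclass
class LearningConfig:
    gamma: float = 0.01
    n_steps: int = 10_000
    tau: int = 14

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.n_steps < 1 or self.tau < 1:
            raise ValueError("n_steps and tau must be positive")


def hebbian_step(
    j_rc: np.ndarray,
    conn_mask: np.ndarray,
    post_rates: np.ndarray,
    pre_rates: np.ndarray,
    trace: np.ndarray,
    gamma: float,
) -> np.ndarray:
    """One associative update of the weight matrix (returns a new matrix).

    For every anatomical synapse (i post, j pre):
    ``J_ij <- [J_ij + gamma * eta_i * (eta_j - Lambda_j)]_+``; entries without
    a synapse are untouched.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    dj = gamma * np.outer(post_rates, pre_rates - trace)
    out = j_rc + np.where(conn_mask.astype(bool), dj, 0.0)
    np.maximum(out, 0.0, out=out)
    # clipping must not resurrect non-synapses; they were >= 0 already
    return out


def normalize_incoming(j_rc: np.ndarray) -> np.ndarray:
    """Rescale each row (one unit's incoming weights) to sum to 1."""
    j_rc = np.asarray(j_rc, dtype=float)
    sums = j_rc.sum(axis=1)
    dead = np.flatnonzero(sums <= 0)
    if dead.size:
        raise ValueError(
            f"cannot normalise: units {dead[:10].tolist()} have no positive "
            "incoming weight"
        )
    return j_rc / sums[:, None]


def run_learning_phase(
    net: CA3Network,
    pop: DGPopulation,
    traj: Trajectory,
    cfg: LearningConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
    chunk: int = 10_000,
) -> CA3Network:
    """Simulate the learning session and return the network with learned weights.

    Activity follows the trajectory sequentially (one update per time step)
    with the recurrent weights frozen at their (uniform) current values, so
    learning does not feed back on the dynamics within the phase.  Weight
    updates accumulate on a separate matrix, clipped at zero after every
    step; at the end the accumulated matrix is normalised row-wise and
    installed in the returned network.
    """
    cfg = cfg or LearningConfig()
    if len(traj) < cfg.n_steps:
        raise ValueError(
            f"trajectory has {len(traj)} steps, fewer than n_steps={cfg.n_steps}"
        )
    rng = np.random.default_rng(seed)
    env = traj.env
    positions = traj.positions[: cfg.n_steps]
    active_ids = pop.active_ids
    mask = net.conn_rc.matrix.astype(bool)
    rc_eff = net.rc_effective()

    # accumulator starts from the current (uniform) weights so that with
    # gamma = 0 the learned network is just the normalised initial one
    acc = np.where(mask, net.j_rc, 0.0)

    tau = cfg.tau
    hist = np.zeros((tau, net.n_ca3))  # ring buffer of past rates
    hist_sum = np.zeros(net.n_ca3)
    n_hist = 0

    state = None
    for start in range(0, cfg.n_steps, chunk):
        stop = min(start + chunk, cfg.n_steps)
        beta = dg_rates(pop, positions[start:stop], env)[:, active_ids] if len(active_ids) else np.zeros((stop - start, 0))
        mf = net.mf_drive(beta, active_ids) if len(active_ids) else np.zeros((stop - start, net.n_ca3))
        noise = (
            rng.normal(0.0, net.noise_sd, size=mf.shape)
            if net.noise_sd > 0
            else None
        )
        rates = sequential_activity(net, mf, noise=noise, rc_eff=rc_eff, init_rates=state)
        state = rates[-1].copy()
        if cfg.gamma > 0:
            for t in range(rates.shape[0]):
                eta = rates[t]
                trace = hist_sum / n_hist if n_hist else np.zeros(net.n_ca3)
                acc += cfg.gamma * np.outer(eta, eta - trace) * mask
                np.maximum(acc, 0.0, out=acc)
                slot = (start + t) % tau
                if n_hist >= tau:
                    hist_sum -= hist[slot]
                else:
                    n_hist += 1
                hist[slot] = eta
                hist_sum += eta
    learned = normalize_incoming(np.where(mask, acc, 0.0))
    return replace(net, j_rc=learned)
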