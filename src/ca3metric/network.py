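"""Threshold-linear CA3 network with mossy-fibre and recurrent-collateral input.

Each CA3 unit fires according to a threshold-linear transfer function of its
total drive

    eta_i = g * [ sum_j c^MF_ij J^MF beta_j
                + sum_k c^RC_ik J^RC_ik eta_k
                + delta_i - T ]_+

where ``[.]_+`` is rectification, ``delta_i`` is a small fast noise, ``T`` a
global activation threshold and ``g`` a global gain.  Inhibition is not
modelled explicitly: at every update the threshold is set so the population
sparsity ``a = <eta>^2 / <eta^2>`` hits its target (default 0.1) and the gain
so the mean rate does (default 0.1).  Because the recurrent term makes the
equation implicit in ``eta``, activity is relaxed by synchronous sweeps with
the threshold/gain control re-applied after every sweep.

The threshold consistent with a target sparsity is found in closed form: with
drives sorted in decreasing order and exactly the top ``k`` units active,
sparsity is a ratio of quadratics in ``T`` whose root is analytic per ``k``;
scanning ``k`` and keeping the root that falls inside its own sorted segment
gives the exact solution, vectorised over many drive vectors at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Connectivity",
    "CA3Network",
    "ActivityState",
    "ControlFailureError",
    "sample_connectivity",
    "sparsity",
    "solve_threshold",
    "adjust_threshold_gain",
    "ca3_activity",
    "iterate_batch_activity",
]

DG_OFF_SCHEDULE: tuple[float, ...] = (1.0, 1.0 / 3.0) + (0.0,) * 13
"""Input-scale schedule for the DG-off reverberation protocol: full DG drive
on the first iteration, one third on the second, none for the remaining 13."""


class ControlFailureError(RuntimeError):
    """Raised when no threshold can attain the requested sparsity."""


@dataclass
class Connectivity:
    """Binary random connectivity with i.i.d. Bernoulli entries."""

    matrix: np.ndarray  # (n_post, n_pre) of 0/1
    c: float  # expected in-degree

    @property
    def n_post(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pre(self) -> int:
        return self.matrix.shape[1]


def sample_connectivity(
    n_pre: int,
    n_post: int,
    c: float,
    exclude_self: bool = False,
    seed: int | np.random.SeedSequence | None = None,
) -> Connectivity:
    """Sample an ``n_post x n_pre`` binary matrix with ``P(1) = c / n_pre``.

    ``exclude_self`` zeroes the diagonal (recurrent matrices must not contain
    autapses).
    """
    if not (0 < c <= n_pre):
        raise ValueError(f"expected in-degree c={c} must be in (0, {n_pre}]")
    rng = np.random.default_rng(seed)
    m = (rng.random((n_post, n_pre)) < c / n_pre).astype(np.uint8)
    if exclude_self:
        n = min(n_pre, n_post)
        m[np.arange(n), np.arange(n)] = 0
    return Connectivity(matrix=m, c=c)


@dataclass
class CA3Network:
    """CA3 layer state: connectivity, weights and the activity-control knobs."""

    conn_mf: Connectivity
    conn_rc: Connectivity
    j_mf: float
    j_rc: np.ndarray  # (N_CA3, N_CA3) non-negative weights (masked by conn_rc)
    noise_sd: float = 0.002
    target_sparsity: float = 0.1
    target_mean: float = 0.1
    n_iter: int = 15
    sparsity_tol: float = 1e-3
    T: float = 0.0
    g: float = 1.0

    @property
    def n_ca3(self) -> int:
        return self.conn_rc.n_post

    @property
    def n_dg(self) -> int:
        return self.conn_mf.n_pre

    def rc_effective(self) -> np.ndarray:
        """Effective recurrent matrix ``c^RC * J^RC`` used in the drive."""
        return self.conn_rc.matrix * self.j_rc

    def mf_drive(self, dg_rates_batch: np.ndarray, active_ids: np.ndarray | None = None) -> np.ndarray:
        """Mossy-fibre drive ``c^MF J^MF beta`` for a batch of DG rate vectors.

        ``dg_rates_batch`` is (n, N_DG), or (n, len(active_ids)) when the
        caller evaluates only the active DG cells.
        """
        w = self.conn_mf.matrix.astype(float)
        if active_ids is not None:
            w = w[:, active_ids]
        return self.j_mf * (dg_rates_batch @ w.T)


def default_network(
    n_dg: int,
    n_ca3: int,
    c_mf: float = 50,
    c_rc: float = 900,
    noise_sd: float = 0.002,
    seed: int | np.random.SeedSequence | None = None,
    j_mf: float = 1.0,
    **kwargs,
) -> CA3Network:
    """Fresh network with uniform weights ``J^MF = 1`` and ``J^RC_0 = 1/C_RC``.

    The mossy-fibre weight is of detonator scale (a single active DG field
    suffices to drive its target): after the end-of-learning normalisation
    pins the recurrent drive to the mean-rate scale, this keeps the
    informative mossy-fibre signal comparable to (not drowned by) the
    recurrent term, which is what makes the DG-driven relaxation contract to
    a fixed point.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_mf, s_rc = ss.spawn(2)
    conn_mf = sample_connectivity(n_dg, n_ca3, c_mf, seed=s_mf)
    conn_rc = sample_connectivity(n_ca3, n_ca3, c_rc, exclude_self=True, seed=s_rc)
    j_rc = np.full((n_ca3, n_ca3), 1.0 / c_rc)
    return CA3Network(
        conn_mf=conn_mf,
        conn_rc=conn_rc,
        j_mf=j_mf,
        j_rc=j_rc,
        noise_sd=noise_sd,
        **kwargs,
    )


@dataclass
class ActivityState:
    rates: np.ndarray
    sparsity: float
    mean_rate: float
    T: float = 0.0
    g: float = 1.0


def sparsity(rates: np.ndarray) -> float:
    """Population sparsity ``<eta>^2 / <eta^2>`` in (0, 1]."""
    rates = np.asarray(rates, dtype=float)
    s2 = np.mean(rates**2)
    if s2 == 0:
        raise ControlFailureError("sparsity undefined for an all-zero rate vector")
    return float(np.mean(rates) ** 2 / s2)


def solve_threshold(
    drive: np.ndarray,
    target_sparsity: float,
    tol: float = 1e-3,
) -> np.ndarray:
    """Exact thresholds making ``sparsity([d - T]_+)`` equal the target, row-wise.

    ``drive`` is (n, N).  With the row sorted in decreasing order
    ``s_1 >= ... >= s_N`` and the top ``k`` units active, the sparsity equals
    ``(S1_k - kT)^2 / (N (S2_k - 2 T S1_k + k T^2))`` with ``S1, S2`` the
    prefix sums of the sorted drives and their squares; equating to the target
    ``a`` gives ``T_k = (S1_k - sqrt(aN (k S2_k - S1_k^2) / (k - aN))) / k``,
    valid when it lands in the segment ``[s_(k+1), s_k)``.  Exactly one ``k``
    is valid except for degenerate (flat) rows, which raise.

    A target of 1 is attainable only asymptotically for non-flat drives, so
    targets are capped at ``1 - tol/2``; the returned threshold then sits
    below the minimum drive with every unit active, as required.
    """
    drive = np.atleast_2d(np.asarray(drive, dtype=float))
    n_rows, N = drive.shape
    if not (0 < target_sparsity <= 1):
        raise ValueError("target sparsity must lie in (0, 1]")
    a = min(target_sparsity, 1.0 - tol / 2.0)
    aN = a * N
    if aN < 1.0 - 1e-12:
        raise ControlFailureError(
            f"target sparsity {target_sparsity} below the 1/N = {1/N:.4g} floor"
        )
    s = -np.sort(-drive, axis=1)  # decreasing
    S1 = np.cumsum(s, axis=1)
    S2 = np.cumsum(s * s, axis=1)
    k = np.arange(1, N + 1, dtype=float)
    denom = k - aN
    var = np.clip(k * S2 - S1 * S1, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (S1 - np.sqrt(aN * var / denom)) / k
    scale = np.maximum(np.abs(s[:, :1]), np.abs(s[:, -1:])) + 1e-30
    eps = 1e-10 * scale
    upper = s + eps
    lower = np.empty_like(s)
    lower[:, :-1] = s[:, 1:]
    lower[:, -1] = -np.inf
    valid = (denom > 0) & np.isfinite(T) & (T <= upper) & (T >= lower - eps)
    ok = valid.any(axis=1)
    if not ok.all():
        bad = np.flatnonzero(~ok)[:5]
        raise ControlFailureError(
            f"no threshold attains sparsity {target_sparsity} for drive rows "
            f"{bad.tolist()} (flat or degenerate drive?)"
        )
    first = valid.argmax(axis=1)
    return T[np.arange(n_rows), first]


def adjust_threshold_gain(
    drive: np.ndarray,
    target_sparsity: float = 0.1,
    target_mean: float = 0.1,
    tol: float = 1e-3,
) -> tuple[float, float, np.ndarray]:
    """Threshold and gain fixing sparsity and mean rate of ``[g (d - T)]_+``.

    Sparsity is gain-independent, so ``T`` is solved first (exactly, see
    :func:`solve_threshold`), then ``g`` rescales the rectified rates so
    their mean equals ``target_mean`` in closed form.
    """
    drive = np.asarray(drive, dtype=float)
    T = float(solve_threshold(drive[None, :], target_sparsity, tol)[0])
    raw = np.maximum(drive - T, 0.0)
    m = raw.mean()
    if m <= 0:
        raise ControlFailureError("no unit active after thresholding")
    g = target_mean / m
    return T, g, g * raw


def _control_rows(
    drive: np.ndarray,
    target_sparsity: float,
    target_mean: float,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise threshold/gain control; returns (T, g, rates)."""
    T = solve_threshold(drive, target_sparsity, tol)
    rates = np.maximum(drive - T[:, None], 0.0)
    m = rates.mean(axis=1)
    if np.any(m <= 0):
        raise ControlFailureError("all-zero rate rows after thresholding")
    g = target_mean / m
    rates *= g[:, None]
    return T, g, rates


def iterate_batch_activity(
    net: CA3Network,
    mf_drive: np.ndarray,
    schedule,
    noise: np.ndarray | None = None,
    init_rates: np.ndarray | None = None,
    rc_eff: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relax many independent time steps at once.

    ``mf_drive`` is (n_steps, N_CA3); each row is one time step, relaxed by
    synchronous sweeps through the input-scale ``schedule`` (one entry per
    sweep) with threshold/gain control after every sweep.  ``noise`` is added
    inside the rectification (one draw per step, held across sweeps).
    Returns (rates, T, g), with rates (n_steps, N_CA3).
    """
    if rc_eff is None:
        rc_eff = net.rc_effective()
    n = mf_drive.shape[0]
    rates = np.zeros_like(mf_drive) if init_rates is None else init_rates.copy()
    if noise is None:
        noise = np.zeros_like(mf_drive)
    T = np.zeros(n)
    g = np.ones(n)
    for scale in schedule:
        drive = rates @ rc_eff.T
        if scale != 0.0:
            drive += scale * mf_drive
        drive += noise
        T, g, rates = _control_rows(
            drive, net.target_sparsity, net.target_mean, net.sparsity_tol
        )
    return rates, T, g


def sequential_activity(
    net: CA3Network,
    mf_drive: np.ndarray,
    noise: np.ndarray | None = None,
    rc_eff: np.ndarray | None = None,
    init_rates: np.ndarray | None = None,
) -> np.ndarray:
    """Activity along a trajectory with one synchronous update per time step.

    The network follows the animal continuously: at step ``t`` the drive is
    ``mf_drive[t] + J^RC eta(t-1) + delta(t)`` and the threshold and gain are
    regulated once, so the recurrent term reflects the previous position's
    activity.  This is the externally driven (DG-on) regime; contrast with
    :func:`iterate_batch_activity`, which relaxes each step independently.
    Returns the (n_steps, N_CA3) rate array; the last row can seed a
    subsequent call.
    """
    if rc_eff is None:
        rc_eff = net.rc_effective()
    n, N = mf_drive.shape
    out = np.empty((n, N))
    prev = np.zeros(N) if init_rates is None else init_rates
    target_a, target_m, tol = net.target_sparsity, net.target_mean, net.sparsity_tol
    for t in range(n):
        drive = mf_drive[t] + rc_eff @ prev
        if noise is not None:
            drive += noise[t]
        T = solve_threshold(drive[None, :], target_a, tol)[0]
        r = np.maximum(drive - T, 0.0)
        m = r.mean()
        if m <= 0:
            raise ControlFailureError(f"all-zero rates at step {t}")
        r *= target_m / m
        out[t] = prev = r
    return out


def ca3_activity(
    net: CA3Network,
    dg_vector: np.ndarray,
    dg_scale: float = 1.0,
    prev_rates: np.ndarray | None = None,
    n_iter: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> ActivityState:
    """CA3 activity at one time step, given the DG rate vector.

    The implicit rate equation is relaxed with ``n_iter`` synchronous sweeps
    (threshold and gain re-controlled after each); ``dg_scale`` scales the
    mossy-fibre term (1 normally, 1/3 or 0 during the DG-off reverberation
    protocol); ``prev_rates`` seeds the recurrent term (zero if omitted).
    Fast noise ``delta_i ~ N(0, noise_sd^2)`` is drawn once per call.
    """
    dg_vector = np.asarray(dg_vector, dtype=float)
    if dg_vector.shape != (net.n_dg,):
        raise ValueError(
            f"dg_vector has length {dg_vector.shape}, expected ({net.n_dg},)"
        )
    if n_iter is None:
        n_iter = net.n_iter
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, net.noise_sd, size=(1, net.n_ca3))
        if net.noise_sd > 0
        else np.zeros((1, net.n_ca3))
    )
    mf = net.mf_drive(dg_vector[None, :])
    init = None if prev_rates is None else np.asarray(prev_rates, dtype=float)[None, :]
    rates, T, g = iterate_batch_activity(
        net, mf, [dg_scale] * n_iter, noise=noise, init_rates=init
    )
    r = rates[0]
    return ActivityState(
        rates=r,
        sparsity=sparsity(r),
        mean_rate=float(r.mean()),
        T=float(T[0]),
        g=float(g[0]),
    )
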