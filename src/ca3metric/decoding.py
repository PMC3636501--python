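"""Template decoding of CA3 activity and spatial confusion matrices.

A training run assigns to each of the ``S = L x L`` spatial bins a reference
population vector (template): the mean activity of the recorded unit sample
over all time steps the animal spent in that bin.  During a test run each
momentary population vector is decoded as the bin whose template is nearest
in Euclidean distance (maximum-likelihood Euclidean decoding); the joint
frequencies of (actual bin, decoded bin) form the confusion matrix.

The translation-averaged *reduced matrix* pools all decoding events with the
same vector displacement between decoded and actual bins, which is
well-defined on the torus; it isolates the translationally invariant
component of the error distribution (a central bump of spatially imprecise
but nearby decodings plus a uniform floor of unstructured errors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dg import DGPopulation, dg_rates
from .environment import TorusEnvironment, Trajectory
from .network import (
    CA3Network,
    DG_OFF_SCHEDULE,
    iterate_batch_activity,
    sequential_activity,
)

__all__ = [
    "TemplateSet",
    "ConfusionMatrix",
    "ReducedMatrix",
    "simulate_rates",
    "build_templates",
    "decode_step",
    "run_test_phase",
    "reduce_confusion",
    "percent_correct",
]


@dataclass
class TemplateSet:
    """Per-bin mean population vectors for an ordered unit sample."""

    templates: np.ndarray  # (S, n_units)
    sample: np.ndarray  # unit ids, ordered
    occupancy: np.ndarray  # per-bin visit counts in the training run

    @property
    def n_bins(self) -> int:
        return self.templates.shape[0]

    def subset(self, unit_ids: np.ndarray) -> "TemplateSet":
        """Templates restricted to a sub-sample of the stored units."""
        pos = np.searchsorted(self.sample, unit_ids)
        if not np.array_equal(self.sample[pos], unit_ids):
            raise KeyError("requested units are not part of this template set")
        return TemplateSet(
            templates=self.templates[:, pos],
            sample=np.asarray(unit_ids),
            occupancy=self.occupancy,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.templates, columns=[f"u{int(u)}" for u in self.sample])
        df.insert(0, "bin", np.arange(self.n_bins))
        return df


@dataclass
class ConfusionMatrix:
    """Decoded-versus-actual bin table accumulated over a test run."""

    counts: np.ndarray  # (S, S) ints; row = actual bin, column = decoded bin

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def row_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def prior(self) -> np.ndarray:
        """Empirical stimulus prior P(s) from test occupancy."""
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty confusion matrix")
        return self.row_counts / total

    @property
    def row_prob(self) -> np.ndarray:
        """Row-normalised P(decoded | actual); unvisited rows raise."""
        rc = self.row_counts
        if np.any(rc == 0):
            bad = np.flatnonzero(rc == 0)
            raise ValueError(f"bins never visited in the test run: {bad.tolist()}")
        return self.counts / rc[:, None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts)


@dataclass
class ReducedMatrix:
    """Displacement-indexed decoding probabilities Q(x - x0) on the L x L torus.

    ``probs[i, j]`` is the probability of a decoding displaced by
    ``(i - L//2, j - L//2)`` bins from the actual position; the origin cell
    (index ``(L//2, L//2)``) holds the correct-decoding mass.  Entries sum
    to 1.
    """

    probs: np.ndarray  # (L, L)

    @property
    def L(self) -> int:
        return self.probs.shape[0]

    @property
    def origin(self) -> tuple[int, int]:
        return (self.L // 2, self.L // 2)

    @property
    def correct_mass(self) -> float:
        return float(self.probs[self.origin])


def simulate_rates(
    net: CA3Network,
    pop: DGPopulation,
    traj: Trajectory,
    dg_mode: str = "on",
    seed: int | np.random.SeedSequence | None = None,
    chunk: int = 10_000,
    dynamics: str = "sequential",
) -> np.ndarray:
    """CA3 rate vectors along a trajectory, (n_steps, N_CA3).

    ``dg_mode='on'``: the network follows the trajectory with one synchronous
    update per time step, the recurrent term carrying the previous step's
    activity (``dynamics='sequential'``, the externally driven protocol);
    ``dynamics='relax'`` instead relaxes every step independently to the
    fixed point of the implicit rate equation (``net.n_iter`` sweeps).
    ``dg_mode='off'``: each step runs the 15-sweep reverberation protocol
    (full DG input on the first sweep, 1/3 on the second, none afterwards)
    and the final configuration is kept; steps are independent.
    """
    if dg_mode not in ("on", "off"):
        raise ValueError(f"dg_mode must be 'on' or 'off', got {dg_mode!r}")
    if dynamics not in ("sequential", "relax"):
        raise ValueError(f"dynamics must be 'sequential' or 'relax', got {dynamics!r}")
    rng = np.random.default_rng(seed)
    schedule = [1.0] * net.n_iter if dg_mode == "on" else list(DG_OFF_SCHEDULE)
    active_ids = pop.active_ids
    rc_eff = net.rc_effective()
    out = np.empty((len(traj), net.n_ca3))
    state = None
    for start in range(0, len(traj), chunk):
        stop = min(start + chunk, len(traj))
        pos = traj.positions[start:stop]
        if len(active_ids):
            beta = dg_rates(pop, pos, traj.env)[:, active_ids]
            mf = net.mf_drive(beta, active_ids)
        else:
            mf = np.zeros((stop - start, net.n_ca3))
        noise = (
            rng.normal(0.0, net.noise_sd, size=mf.shape)
            if net.noise_sd > 0
            else None
        )
        if dg_mode == "on" and dynamics == "sequential":
            out[start:stop] = sequential_activity(
                net, mf, noise=noise, rc_eff=rc_eff, init_rates=state
            )
            state = out[stop - 1].copy()
        else:
            out[start:stop], _, _ = iterate_batch_activity(
                net, mf, schedule,
                noise=noise if noise is not None else np.zeros_like(mf),
                rc_eff=rc_eff,
            )
    return out


def templates_from_rates(
    rates: np.ndarray,
    bins: np.ndarray,
    sample: np.ndarray,
    n_bins: int,
) -> TemplateSet:
    """Average precomputed rates per bin for a unit sample."""
    sample = np.asarray(sample, dtype=np.int64)
    occupancy = np.bincount(bins, minlength=n_bins)
    missing = np.flatnonzero(occupancy == 0)
    if missing.size:
        raise ValueError(
            f"training run never visited bins {missing.tolist()}; "
            "templates are undefined"
        )
    sums = np.zeros((n_bins, len(sample)))
    np.add.at(sums, bins, rates[:, sample])
    return TemplateSet(
        templates=sums / occupancy[:, None], sample=sample, occupancy=occupancy
    )


def build_templates(
    net: CA3Network,
    pop: DGPopulation,
    traj: Trajectory,
    sample: np.ndarray,
    env: TorusEnvironment | None = None,
    dg_mode: str = "on",
    seed: int | np.random.SeedSequence | None = None,
) -> TemplateSet:
    """Run the training phase and build per-bin templates for a unit sample."""
    sample = np.asarray(sample, dtype=np.int64)
    if sample.size == 0:
        raise ValueError("unit sample is empty")
    if sample.min() < 0 or sample.max() >= net.n_ca3:
        raise ValueError("unit sample contains invalid unit ids")
    env = env or traj.env
    rates = simulate_rates(net, pop, traj, dg_mode=dg_mode, seed=seed)
    return templates_from_rates(rates, traj.bins(), sample, env.n_bins)


def decode_step(rates_sample: np.ndarray, templates: TemplateSet) -> int:
    """Nearest-template bin for one population vector (ties -> lowest bin id)."""
    v = np.asarray(rates_sample, dtype=float)
    if v.shape != (templates.templates.shape[1],):
        raise ValueError("rate vector length does not match the template sample")
    d2 = np.sum((templates.templates - v[None, :]) ** 2, axis=1)
    return int(np.argmin(d2))


def _decode_batch(rates: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Vectorised nearest-template argmin (rows of ``rates`` vs template rows)."""
    # |x - t|^2 = |x|^2 - 2 x.t + |t|^2 ; |x|^2 is constant per row
    cross = rates @ templates.T
    d2 = np.sum(templates**2, axis=1)[None, :] - 2.0 * cross
    return np.argmin(d2, axis=1)


def run_test_phase(
    net: CA3Network,
    pop: DGPopulation,
    traj: Trajectory,
    templates: TemplateSet,
    samples: list[np.ndarray],
    dg_mode: str = "on",
    env: TorusEnvironment | None = None,
    seed: int | np.random.SeedSequence | None = None,
    chunk: int = 10_000,
) -> list[ConfusionMatrix]:
    """Decode a test run for several unit samples and accumulate confusions.

    ``templates`` must have been built under the same ``dg_mode`` and must
    contain every unit appearing in ``samples`` (a full-population template
    set is the convenient choice); each sample is decoded against its own
    sliced template set.  Returns one :class:`ConfusionMatrix` per sample.
    """
    env = env or traj.env
    S = env.n_bins
    temp_sets = [templates.subset(np.sort(np.asarray(s, dtype=np.int64))) for s in samples]
    counts = [np.zeros((S, S), dtype=np.int64) for _ in samples]
    bins = traj.bins()
    rates = simulate_rates(net, pop, traj, dg_mode=dg_mode, seed=seed, chunk=chunk)
    for start in range(0, len(traj), chunk):
        stop = min(start + chunk, len(traj))
        actual = bins[start:stop]
        for ci, ts in zip(counts, temp_sets):
            decoded = _decode_batch(rates[start:stop, ts.sample], ts.templates)
            np.add.at(ci, (actual, decoded), 1)
    return [ConfusionMatrix(counts=c) for c in counts]


def reduce_confusion(C: ConfusionMatrix, env: TorusEnvironment) -> ReducedMatrix:
    """Translation-average a confusion matrix into Q(x - x0).

    Every decoding event (actual s, decoded s') contributes at the 2-D
    displacement ``bin(s') - bin(s)`` taken on the L x L torus; displacement
    counts are normalised to total probability 1.
    """
    L = env.L
    if C.counts.shape != (L * L, L * L):
        raise ValueError("confusion matrix size does not match the environment grid")
    total = C.counts.sum()
    if total == 0:
        raise ValueError("confusion matrix has no events")
    s = np.arange(L * L)
    rows_i, rows_j = s // L, s % L
    di = (rows_i[None, :] - rows_i[:, None]) % L  # decoded minus actual
    dj = (rows_j[None, :] - rows_j[:, None]) % L
    # shift so zero displacement maps to the centre cell
    ci = (di + L // 2) % L
    cj = (dj + L // 2) % L
    probs = np.zeros((L, L))
    np.add.at(probs, (ci, cj), C.counts / total)
    return ReducedMatrix(probs=probs)


def percent_correct(C: ConfusionMatrix) -> float:
    """Fraction of correct decodings, sum_s P(s|s) P(s)."""
    return float(np.trace(C.counts) / C.counts.sum())
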