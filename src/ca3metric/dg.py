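"""Dentate-gyrus granule-cell population with multi-field Gaussian place maps.

Only a small random fraction ``p_dg`` of granule cells is active in a given
environment.  An active cell ``j`` carries ``Q_j ~ Poisson(q)`` place fields
at positions drawn uniformly on the torus, and its rate at position ``x`` is
the superposition of identical Gaussian bumps of height ``beta0`` and width
``sigma_f``::

    beta_j(x) = sum_k beta0 * exp(-|x - x_jk|^2 / (2 sigma_f^2))

with ``|.|`` the minimum-image (torus) distance.  Inactive cells are silent
everywhere.  These rates are the only informative drive into CA3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import TorusEnvironment, torus_displacement

__all__ = ["DGCell", "DGPopulation", "sample_dg_population", "dg_rates"]


@dataclass
class DGCell:
    active: bool
    centers: np.ndarray  # (Q, 2) field centres; empty for inactive cells

    @property
    def Q(self) -> int:
        return len(self.centers)


@dataclass
class DGPopulation:
    """Sampled DG population: field centres plus shared field parameters."""

    cells: list[DGCell]
    beta0: float
    sigma_f: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def active_ids(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.cells) if c.active], dtype=np.int64)

    def field_table(self) -> tuple[np.ndarray, np.ndarray]:
        """All fields flattened: (cell ids, centres) arrays.

        Convenient for vectorised rate evaluation; inactive and zero-field
        cells contribute no rows.
        """
        ids = []
        centers = []
        for i, c in enumerate(self.cells):
            if c.active and c.Q > 0:
                ids.append(np.full(c.Q, i, dtype=np.int64))
                centers.append(c.centers)
        if not ids:
            return np.empty(0, dtype=np.int64), np.empty((0, 2))
        return np.concatenate(ids), np.concatenate(centers, axis=0)

    def to_frame(self) -> pd.DataFrame:
        ids, centers = self.field_table()
        return pd.DataFrame({"cell": ids, "x": centers[:, 0], "y": centers[:, 1]})

    def to_csv(self, path) -> None:
        """One row per field, with population parameters in a comment header."""
        with open(path, "w") as fh:
            fh.write(
                f"# n_cells={self.n_cells} beta0={self.beta0} sigma_f={self.sigma_f}\n"
            )
            self.to_frame().to_csv(fh, index=False)


def sample_dg_population(
    n_dg: int,
    q: float = 1.7,
    p_dg: float = 0.033,
    beta0: float = 1.0,
    sigma_f: float = 0.1,
    env: TorusEnvironment | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> DGPopulation:
    """Draw a DG population for one environment.

    Each cell is independently active with probability ``p_dg``; active cells
    receive ``Q ~ Poisson(q)`` field centres uniform on the torus.
    """
    if n_dg < 1:
        raise ValueError("n_dg must be >= 1")
    if not (0.0 <= p_dg <= 1.0):
        raise ValueError(f"p_dg must be in [0, 1], got {p_dg}")
    if q <= 0:
        raise ValueError(f"q must be positive, got {q}")
    if beta0 <= 0 or sigma_f <= 0:
        raise ValueError("beta0 and sigma_f must be positive")
    env = env or TorusEnvironment()
    rng = np.random.default_rng(seed)
    active = rng.random(n_dg) < p_dg
    cells = []
    for i in range(n_dg):
        if active[i]:
            Q = rng.poisson(q)
            centers = rng.random((Q, 2)) * env.side
        else:
            centers = np.empty((0, 2))
        cells.append(DGCell(active=bool(active[i]), centers=centers))
    return DGPopulation(cells=cells, beta0=beta0, sigma_f=sigma_f)


def dg_rates(
    pop: DGPopulation,
    p: np.ndarray,
    env: TorusEnvironment | None = None,
) -> np.ndarray:
    """DG rate vector(s) at position(s) ``p``.

    ``p`` may be a single position (shape (2,)) giving a vector of length
    ``n_cells``, or a batch (n, 2) giving an (n, n_cells) array.  Gaussians
    are evaluated with the minimum-image displacement; for ``sigma_f`` well
    below the environment side the neglected periodic images are negligible.
    """
    env = env or TorusEnvironment()
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = p[None, :] if single else p
    out = np.zeros((len(pts), pop.n_cells))
    ids, centers = pop.field_table()
    if len(ids):
        # (n, F, 2) displacements -> squared torus distance per field
        d = torus_displacement(centers[None, :, :], pts[:, None, :], env)
        r2 = np.einsum("nfk,nfk->nf", d, d)
        contrib = pop.beta0 * np.exp(-r2 / (2.0 * pop.sigma_f**2))
        np.add.at(out.T, ids, contrib.T)
    return out[0] if single else out
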