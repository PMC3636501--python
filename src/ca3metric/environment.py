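"""Periodic square environment, random-walk trajectories, and spatial binning.

The simulated animal explores a square box of side ``side`` metres realised as
a torus (periodic boundary conditions), so there are no walls and occupancy is
asymptotically uniform.  Positions are continuous; a regular ``L x L`` grid of
square bins (``S = L**2`` bins, row-major order) is used only at analysis time
for template building and decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TorusEnvironment",
    "Trajectory",
    "generate_trajectory",
    "torus_displacement",
    "bin_index",
]


@dataclass(frozen=True)
class TorusEnvironment:
    """Square environment with periodic boundary conditions.

    Parameters
    ----------
    side:
        Side length in metres (area ``side**2``).  Default 1.0 m.
    L:
        Number of bins per side for the analysis grid.  Default 8, giving
        64 bins of 12.5 cm.
    """

    side: float = 1.0
    L: int = 8

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError(f"side must be positive, got {self.side}")
        if self.L < 2:
            raise ValueError(f"L must be at least 2, got {self.L}")

    @property
    def n_bins(self) -> int:
        """Total number of spatial bins ``S = L**2``."""
        return self.L * self.L

    @property
    def bin_size(self) -> float:
        return self.side / self.L

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Map coordinates into ``[0, side)`` componentwise."""
        return np.mod(positions, self.side)


@dataclass
class Trajectory:
    """A persistent random walk on the torus.

    ``positions`` has shape (n_steps, 2); ``headings`` (n_steps,) holds the
    movement direction used to reach each position.  Consecutive positions are
    exactly ``step_length`` apart in torus distance by construction.
    """

    positions: np.ndarray
    headings: np.ndarray
    step_length: float = 0.025
    dt: float = 0.125
    env: TorusEnvironment = field(default_factory=TorusEnvironment)

    def __len__(self) -> int:
        return len(self.positions)

    def bins(self) -> np.ndarray:
        """Row-major bin index of every position."""
        return bin_index(self.positions, self.env)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: columns t, x, y, heading, bin."""
        return pd.DataFrame(
            {
                "t": np.arange(len(self)),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "heading": self.headings,
                "bin": self.bins(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_trajectory(
    env: TorusEnvironment,
    n_steps: int,
    step_length: float = 0.025,
    heading_noise_sd: float = 0.35,
    seed: int | np.random.SeedSequence | None = None,
    start: tuple[float, float] = (0.0, 0.0),
    start_heading: float = 0.0,
) -> Trajectory:
    """Simulate a persistent random walk.

    Each step advances ``step_length`` along the current heading; the heading
    evolves as ``heading(t) = heading(t-1) + eps`` with
    ``eps ~ Normal(0, heading_noise_sd**2)``, so the walk keeps moving in a
    direction similar to the previous step with a small amount of noise.
    Coordinates are wrapped on the torus.

    The default step (2.5 cm per 125 ms step) corresponds to a 20 cm/s
    exploratory speed.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if step_length <= 0:
        raise ValueError(f"step_length must be positive, got {step_length}")
    if step_length >= env.side:
        raise ValueError("step_length must be smaller than the environment side")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, heading_noise_sd, size=n_steps)
    headings = start_heading + np.cumsum(noise)
    steps = step_length * np.stack([np.cos(headings), np.sin(headings)], axis=1)
    positions = env.wrap(np.asarray(start, dtype=float) + np.cumsum(steps, axis=0))
    return Trajectory(
        positions=positions,
        headings=headings,
        step_length=step_length,
        env=env,
    )


def torus_displacement(p1: np.ndarray, p2: np.ndarray, env: TorusEnvironment) -> np.ndarray:
    """Minimum-image displacement ``p2 - p1`` on the torus.

    Each component lies in ``[-side/2, side/2)``.  Broadcasts over leading
    dimensions.
    """
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    half = env.side / 2.0
    return np.mod(d + half, env.side) - half


def bin_index(p: np.ndarray, env: TorusEnvironment) -> np.ndarray | int:
    """Row-major index of the half-open grid bin containing ``p``.

    Bin ``(i, j)`` covers ``[i*side/L, (i+1)*side/L) x [j*side/L, ...)`` with
    ``i`` indexing the x coordinate; the returned id is ``i * L + j``.
    Periodic in both coordinates.
    """
    p = np.asarray(p, dtype=float)
    idx = np.floor(np.mod(p, env.side) / env.bin_size).astype(np.int64)
    # guard against floating roundoff at the upper bin edge
    idx = np.clip(idx, 0, env.L - 1)
    flat = idx[..., 0] * env.L + idx[..., 1]
    if flat.ndim == 0:
        return int(flat)
    return flat
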