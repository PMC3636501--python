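"""Global topology of the spatial map: correlation distances and Sammon MDS.

The 64 full-population templates are points in an N_CA3-dimensional space.
Their pairwise similarity (Pearson correlation) defines a distance matrix
``d_ij = 1 - r_ij``; a metric multidimensional scaling with the Sammon
criterion embeds the templates in 3-D so the embedded Euclidean distances
reproduce the correlation distances as closely as possible, with stress

    E = (1 / sum_{i<j} D_ij) * sum_{i<j} (D_ij - dhat_ij)^2 / D_ij

weighting relative errors, which preserves local structure.  For a faithful
spatial map on a periodic box the embedding is a (slightly crumpled) torus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import TemplateSet

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "correlation_distance_matrix",
    "classical_mds",
    "sammon_stress",
    "sammon_map",
]


@dataclass
class DistanceMatrix:
    d: np.ndarray  # (S, S) symmetric, non-negative, zero diagonal

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        self.d = d

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class Embedding:
    coords: np.ndarray  # (S, dim)
    stress: float


def correlation_distance_matrix(
    templates: TemplateSet | np.ndarray,
    form: str = "one_minus_r",
) -> DistanceMatrix:
    """Pairwise template distances ``1 - r`` (or ``sqrt(2(1-r))``).

    ``r`` is the Pearson correlation between template rows; distances are
    clipped at zero so numerically tiny negative values cannot appear.
    """
    X = templates.templates if isinstance(templates, TemplateSet) else np.asarray(templates, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 template rows")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance template rows: {bad.tolist()}")
    r = np.corrcoef(X)
    if form == "one_minus_r":
        d = 1.0 - r
    elif form == "sqrt":
        d = np.sqrt(np.clip(2.0 * (1.0 - r), 0.0, None))
    else:
        raise ValueError("form must be 'one_minus_r' or 'sqrt'")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=np.clip(d, 0.0, None))


def classical_mds(D: DistanceMatrix, dim: int = 3) -> np.ndarray:
    """Torgerson's classical scaling of a distance matrix (used as init)."""
    n = D.n
    d2 = D.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)[None, :]


def _pair_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def sammon_stress(coords: np.ndarray, D: DistanceMatrix) -> float:
    """Evaluate the Sammon stress of a configuration against D."""
    d = D.d
    iu = np.triu_indices(D.n, k=1)
    dij = d[iu]
    if np.any(dij <= 0):
        raise ValueError("Sammon stress requires positive off-diagonal distances")
    dhat = _pair_distances(coords)[iu]
    c = dij.sum()
    return float(np.sum((dij - dhat) ** 2 / dij) / c)


def _sammon_gradient(coords: np.ndarray, d: np.ndarray, c: float) -> np.ndarray:
    dhat = _pair_distances(coords)
    np.fill_diagonal(dhat, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = (d - dhat) / (d * dhat)
    np.fill_diagonal(coef, 0.0)
    diff = coords[:, None, :] - coords[None, :, :]
    # dE/dx_i = (-2/c) * sum_j coef_ij * (x_i - x_j)
    return (-2.0 / c) * np.einsum("ij,ijk->ik", coef, diff)


def sammon_map(
    D: DistanceMatrix,
    dim: int = 3,
    n_iter: int = 500,
    seed: int | np.random.SeedSequence | None = None,
    init: np.ndarray | None = None,
    lr: float = 0.1,
    jitter: float = 1e-6,
) -> Embedding:
    """Minimise the Sammon stress by gradient descent with step halving.

    Initialised from classical MDS (plus a tiny seeded jitter to break exact
    degeneracies); each iteration takes a gradient step and halves the step
    size until the stress does not increase, so accepted stress values
    decrease monotonically.
    """
    if init is None:
        init = classical_mds(D, dim)
        rng = np.random.default_rng(seed)
        init = init + jitter * rng.standard_normal(init.shape)
    coords = init.astype(float).copy()
    d = D.d.copy()
    iu = np.triu_indices(D.n, k=1)
    if np.any(d[iu] <= 0):
        raise ValueError("Sammon mapping requires positive off-diagonal distances")
    c = d[iu].sum()
    scale = np.median(d[iu])
    stress = sammon_stress(coords, D)
    step = lr * scale
    for _ in range(n_iter):
        grad = _sammon_gradient(coords, d, c)
        gnorm = np.linalg.norm(grad)
        if not np.isfinite(gnorm):
            raise RuntimeError("Sammon optimisation produced non-finite gradient")
        if gnorm < 1e-14:
            break
        direction = grad / gnorm
        s = step
        improved = False
        for _ in range(30):
            trial = coords - s * direction
            new = sammon_stress(trial, D)
            if new <= stress:
                coords, stress = trial, new
                improved = True
                step = s * 1.5  # allow the step to grow again
                break
            s *= 0.5
        if not improved:
            break
    if not np.isfinite(stress):
        raise RuntimeError("Sammon optimisation diverged to non-finite stress")
    return Embedding(coords=coords, stress=float(stress))
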