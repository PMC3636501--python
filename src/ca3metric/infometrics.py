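"""Information measures, bound curves, bump fits, and the metric resolution index.

The confusion matrix of a decoder over ``S`` stimuli yields two summary
numbers: the percent correct ``f_cor`` and the mutual information ``I``
(plug-in estimate, base 2).  At fixed ``f_cor`` the information is bracketed
by closed-form bounds — errors spread evenly over all wrong stimuli
(minimum), concentrated on a single wrong stimulus (biased maximum), or, for
an unbiased classifier, spread over ``1/f_cor`` stimuli chosen as often as
the correct one (unbiased maximum).  The *metric content*
``lambda = (I - I_min) / (I_max - I_min)`` locates the measured information
inside that bracket.

For spatial stimuli on a periodic grid, the translation-averaged reduced
matrix shows a central Gaussian bump (width ``w``, volume ``a``, peak ``pc``)
over a uniform floor.  Reference confusion matrices built from ``1/a``
Gaussian bumps of adjustable width ``sigma`` interpolate between a spatially
exact code (``sigma = 0``) and one whose entire bump width is genuine spatial
imprecision (``sigma = w``).  Solving ``sigma`` so the reference information
matches the measured full-matrix information defines the *metric resolution*

    chi = 1 - sigma / w,

the fraction of the apparent bump width not attributable to true spatial
blur of the code.  When the network runs on recurrent activity alone,
deterministic drift displaces decodings into neighbouring bins; the reference
bumps are then each replaced by two adjacent half-height bumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .decoding import ConfusionMatrix, ReducedMatrix

__all__ = [
    "InfoCurve",
    "SigmoidFit",
    "BumpFit",
    "MetricResolutionResult",
    "mutual_information",
    "reduced_information",
    "info_min",
    "info_max_bias",
    "info_max_unbiased",
    "metric_content",
    "fit_sigmoid",
    "fit_gaussian_bump",
    "reference_information",
    "solve_metric_resolution",
]


# ---------------------------------------------------------------------------
# plug-in information


def _plugin_mi(joint: np.ndarray) -> float:
    """Mutual information (bits) of a joint distribution; 0 log 0 := 0."""
    joint = np.asarray(joint, dtype=float)
    pr = joint.sum(axis=0)
    ps = joint.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (ps[:, None] * pr[None, :])
        terms = np.where(joint > 0, joint * np.log2(np.where(joint > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def mutual_information(C: ConfusionMatrix | np.ndarray) -> float:
    """Mutual information (bits) between actual and decoded bin.

    Accepts a :class:`ConfusionMatrix` (joint = row-normalised table times the
    empirical prior) or a raw joint-probability array.
    """
    if isinstance(C, ConfusionMatrix):
        joint = C.row_prob * C.prior[:, None]
    else:
        joint = np.asarray(C, dtype=float)
        joint = joint / joint.sum()
    return _plugin_mi(joint)


def reduced_information(R: ReducedMatrix) -> float:
    """Information (bits) carried by the reduced matrix.

    The reduced matrix defines a translation-invariant channel whose every
    row is a translate of Q; with a uniform prior the decoded-bin marginal is
    uniform, so ``I = log2 S - H(Q)``.
    """
    q = R.probs.ravel()
    S = q.size
    h = -np.sum(q[q > 0] * np.log2(q[q > 0]))
    return float(np.log2(S) - h)


# ---------------------------------------------------------------------------
# closed-form bounds at fixed percent correct


def _h2(f: float) -> float:
    if f <= 0.0 or f >= 1.0:
        return 0.0
    return float(-f * np.log2(f) - (1 - f) * np.log2(1 - f))


def info_min(S: int, f_cor: float) -> float:
    """Information floor: errors spread evenly over the S - 1 wrong stimuli."""
    if not (0 < f_cor <= 1):
        raise ValueError("f_cor must be in (0, 1]")
    if f_cor == 1.0:
        return float(np.log2(S))
    return float(np.log2(S) - _h2(f_cor) - (1 - f_cor) * np.log2(S - 1))


def info_max_bias(S: int, f_cor: float) -> float:
    """Information ceiling: all errors on a single wrong stimulus."""
    if not (0 < f_cor <= 1):
        raise ValueError("f_cor must be in (0, 1]")
    return float(np.log2(S) - _h2(f_cor))


def info_max_unbiased(S: int, f_cor: float) -> float:
    """Unbiased ceiling: wrong stimuli at most as frequent as the correct one."""
    if not (0 < f_cor <= 1):
        raise ValueError("f_cor must be in (0, 1]")
    return float(np.log2(S) + np.log2(f_cor))


def metric_content(I: float, I_min: float, I_max: float) -> float:
    """Normalised position of I between its bounds, (I - I_min)/(I_max - I_min)."""
    if I_max <= I_min:
        raise ValueError("degenerate bounds: I_max must exceed I_min")
    return (I - I_min) / (I_max - I_min)


# ---------------------------------------------------------------------------
# sigmoid fits of sample-size dependence


@dataclass
class SigmoidFit:
    """Fitted sigmoid dependence on sample size n.

    ``form='info'``: I_sat / (1 + (n0/n)^b)  with params (I_sat, n0, b).
    ``form='pcor'``: f_min + (f_max - f_min) / (1 + (n0/n)^b)
    with params (f_min, f_max, n0, b).
    """

    form: str
    params: tuple
    residual: float
    degenerate: bool = False

    def predict(self, n) -> np.ndarray | float:
        n = np.asarray(n, dtype=float)
        if self.form == "info":
            sat, n0, b = self.params
            out = sat / (1.0 + (n0 / n) ** b)
        else:
            lo, hi, n0, b = self.params
            out = lo + (hi - lo) / (1.0 + (n0 / n) ** b)
        return float(out) if out.ndim == 0 else out


@dataclass
class InfoCurve:
    """Information (or percent correct) as a function of sample size."""

    sizes: np.ndarray
    values: np.ndarray
    fit: SigmoidFit | None = None


def fit_sigmoid(sizes, values, form: str = "info") -> SigmoidFit:
    """Least-squares sigmoid fit of information or percent correct vs n."""
    sizes = np.asarray(sizes, dtype=float)
    values = np.asarray(values, dtype=float)
    if form not in ("info", "pcor"):
        raise ValueError("form must be 'info' or 'pcor'")
    if sizes.size < 4:
        raise ValueError("need at least 4 points to fit")
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    spread = values.max() - values.min()
    if spread < 1e-12 * max(1.0, abs(values.max())):
        # constant data: the exponent is unidentifiable
        params = (
            (values.mean(), np.median(sizes), 0.0)
            if form == "info"
            else (values.mean(), values.mean(), np.median(sizes), 0.0)
        )
        return SigmoidFit(form=form, params=params, residual=0.0, degenerate=True)

    if form == "info":

        def model(n, sat, n0, b):
            return sat / (1.0 + (n0 / n) ** b)

        p0 = (values.max() * 1.1, np.median(sizes), 1.0)
        bounds = ([0.0, 1e-6, 1e-6], [np.inf, np.inf, 20.0])
    else:

        def model(n, lo, hi, n0, b):
            return lo + (hi - lo) / (1.0 + (n0 / n) ** b)

        p0 = (max(values.min(), 1e-6), min(values.max() * 1.05, 1.0), np.median(sizes), 1.0)
        bounds = ([0.0, 0.0, 1e-6, 1e-6], [1.0, 1.5, np.inf, 20.0])

    try:
        popt, _ = optimize.curve_fit(
            model, sizes, values, p0=p0, bounds=bounds, maxfev=20_000
        )
    except RuntimeError as err:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"sigmoid fit failed to converge: {err}") from err
    resid = float(np.linalg.norm(model(sizes, *popt) - values))
    return SigmoidFit(form=form, params=tuple(popt), residual=resid)


# ---------------------------------------------------------------------------
# Gaussian bump fit of the reduced matrix


@dataclass
class BumpFit:
    """Central-bump parameters of a reduced matrix.

    ``pc``: fitted height at zero displacement (probability, bump + floor);
    ``w``: Gaussian width in bin units; ``a``: discrete volume of the
    Gaussian part; ``baseline``: uniform floor level.  ``sub_resolution``
    flags fits whose width collapsed below the bin scale.
    """

    pc: float
    w: float
    a: float
    baseline: float
    residual: float = 0.0
    sub_resolution: bool = False


def _displacement_r2(L: int) -> np.ndarray:
    """Squared torus displacement (bin units) with the origin at index 0."""
    d = np.minimum(np.arange(L), L - np.arange(L)).astype(float)
    return d[:, None] ** 2 + d[None, :] ** 2


def _centered_r2(L: int) -> np.ndarray:
    """Squared displacement with the origin at the centre cell (L//2, L//2)."""
    return np.roll(_displacement_r2(L), (L // 2, L // 2), axis=(0, 1))


def fit_gaussian_bump(R: ReducedMatrix, w_floor: float = 0.35) -> BumpFit:
    """Fit ``baseline + A exp(-r^2 / 2 w^2)`` to a reduced matrix.

    The Gaussian is isotropic, centred on the zero-displacement cell, and
    evaluated at bin centres on the displacement torus.  Returns the peak
    height ``pc = A + baseline``, the width ``w`` (bins), the discrete bump
    volume ``a = A * sum(exp(...))`` and the floor level.

    Below ``w_floor`` (bins) the discretised Gaussian places negligible mass
    outside the origin cell, so the width is not identifiable from gridded
    data; such fits are flagged ``sub_resolution``.
    """
    L = R.L
    r2 = _centered_r2(L)
    data = R.probs

    def model(params):
        A, w, base = params
        return base + A * np.exp(-r2 / (2.0 * w * w))

    base0 = float(np.median(data))
    A0 = max(float(R.correct_mass - base0), 1e-6)
    x0 = np.array([A0, 1.0, max(base0, 1e-9)])
    res = optimize.least_squares(
        lambda p: (model(p) - data).ravel(),
        x0,
        bounds=([0.0, 1e-6, 0.0], [np.inf, float(L), 1.0]),
        xtol=1e-14,
        ftol=1e-14,
    )
    if not res.success:
        raise RuntimeError(f"bump fit failed: {res.message}")
    A, w, base = res.x
    vol = float(A * np.exp(-r2 / (2.0 * w * w)).sum())
    return BumpFit(
        pc=float(A + base),
        w=float(w),
        a=vol,
        baseline=float(base),
        residual=float(np.linalg.norm(res.fun)),
        sub_resolution=bool(w < w_floor),
    )


# ---------------------------------------------------------------------------
# sigma-parameterised reference information curves


def _bump_kernel(L: int, sigma: float) -> np.ndarray:
    """Discretised unit-volume bump with its peak at flat index 0.

    ``sigma = 0`` degenerates to a point mass (spatially exact code).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        k = np.zeros(L * L)
        k[0] = 1.0
        return k
    k = np.exp(-_displacement_r2(L) / (2.0 * sigma * sigma)).ravel()
    return k / k.sum()


def _kernel_translates(L: int, sigma: float) -> np.ndarray:
    """(S, S) matrix whose row ``s`` is the bump kernel centred on bin ``s``."""
    base = _bump_kernel(L, sigma).reshape(L, L)
    S = L * L
    out = np.empty((S, S))
    for s in range(S):
        out[s] = np.roll(base, (s // L, s % L), axis=(0, 1)).ravel()
    return out


def _axis_neighbor(L: int, locs: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Flat index of the axis neighbour of each bin in direction 0..3."""
    i, j = locs // L, locs % L
    di = np.array([1, -1, 0, 0])[dirs]
    dj = np.array([0, 0, 1, -1])[dirs]
    return ((i + di) % L) * L + (j + dj) % L


def draw_reference_placements(
    S: int,
    n_bumps: int,
    n_draws: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random bump locations and drift directions for reference matrices.

    Returns ``locs`` (n_draws, S, n_bumps) — bump 0 is always the correct bin
    ``s``, the others are distinct wrong bins — and ``dirs`` of the same
    shape, uniform over the four axis directions (used only when drifting).
    """
    locs = np.empty((n_draws, S, n_bumps), dtype=np.int64)
    locs[:, :, 0] = np.arange(S)[None, :]
    for d in range(n_draws):
        for s in range(S):
            if n_bumps > 1:
                others = rng.choice(S - 1, size=n_bumps - 1, replace=False)
                others = others + (others >= s)  # skip the correct bin
                locs[d, s, 1:] = others
    dirs = rng.integers(0, 4, size=(n_draws, S, n_bumps))
    return locs, dirs


def bump_volumes(a: float) -> np.ndarray:
    """Per-bump volumes realising total mass 1 with bumps of volume ``a``.

    ``1/a`` is rarely an integer: the construction uses ``floor(1/a)`` bumps
    of volume ``a`` plus, when needed, one fractional bump carrying the
    remaining mass, so the reference varies continuously with ``a`` instead
    of jumping at integer reciprocals.
    """
    full = int(np.floor(1.0 / a + 1e-12))
    rem = 1.0 - full * a
    if rem > 1e-9:
        return np.concatenate([np.full(full, a), [rem]])
    return np.full(full, a)


def _reference_matrix(
    K: np.ndarray,
    L: int,
    volumes: np.ndarray,
    locs: np.ndarray,
    dirs: np.ndarray | None,
) -> np.ndarray:
    """One model confusion matrix from bump placements (rows sum to 1)."""
    S = K.shape[0]
    rows = np.zeros((S, S))
    for b, vol in enumerate(volumes):
        if dirs is None:
            rows += vol * K[locs[:, b]]
        else:
            nbr = _axis_neighbor(L, locs[:, b], dirs[:, b])
            rows += 0.5 * vol * (K[locs[:, b]] + K[nbr])
    return rows / rows.sum(axis=1, keepdims=True)


def reference_information(
    S: int,
    a: float,
    sigma: float,
    n_bumps: int | None = None,
    mode: str = "max",
    drift: bool = False,
    n_draws: int = 50,
    seed: int | np.random.Generator | None = None,
    placements: tuple[np.ndarray, np.ndarray] | None = None,
    K: np.ndarray | None = None,
) -> float:
    """Information (bits) of a model confusion matrix with bump structure.

    ``mode='min'``: a single bump of volume ``a`` (width ``sigma``) on the
    correct bin plus the remaining ``1 - a`` spread evenly over all bins —
    the information floor given the bump.  ``mode='max'``: ``1/a`` bumps of
    volume ``a`` (a fractional trailing bump absorbs any remainder, see
    :func:`bump_volumes`), one on the correct bin and the rest on distinct
    random wrong bins — the unbiased ceiling.  ``drift=True`` replaces every
    bump by two half-height
    copies, one in a random adjacent bin, modelling attractor drift across
    bin boundaries.  The information is the plug-in value under a uniform
    stimulus prior, averaged over ``n_draws`` random placements.

    ``placements``/``K`` allow callers to reuse random placements and kernel
    translates across sigma values (common random numbers make the curve
    monotone in sigma, which the bisection in
    :func:`solve_metric_resolution` relies on).
    """
    L = int(round(np.sqrt(S)))
    if L * L != S:
        raise ValueError("S must be a perfect square (L x L grid)")
    if not (0 < a <= 1):
        raise ValueError("bump volume a must be in (0, 1]")
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    if K is None:
        K = _kernel_translates(L, sigma)

    if mode == "min":
        rows = a * K + (1.0 - a) / S
        if drift:
            # drift applies to the central bump as well
            rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
            mis = []
            for _ in range(n_draws):
                dirs = rng.integers(0, 4, size=S)
                nbr = _axis_neighbor(L, np.arange(S), dirs)
                r = 0.5 * a * (K[np.arange(S)] + K[nbr]) + (1.0 - a) / S
                r = r / r.sum(axis=1, keepdims=True)
                mis.append(_plugin_mi(r / S))
            return float(np.mean(mis))
        rows = rows / rows.sum(axis=1, keepdims=True)
        return _plugin_mi(rows / S)

    volumes = bump_volumes(a)
    if n_bumps is not None:
        volumes = volumes[:n_bumps] if n_bumps <= len(volumes) else volumes
    if len(volumes) > S:
        raise ValueError(
            f"{len(volumes)} bumps exceed the number of bins S={S}"
        )
    if placements is None:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        placements = draw_reference_placements(S, len(volumes), n_draws, rng)
    locs, dirs = placements
    mis = []
    for d in range(locs.shape[0]):
        rows = _reference_matrix(K, L, volumes, locs[d], dirs[d] if drift else None)
        mis.append(_plugin_mi(rows / S))
    return float(np.mean(mis))


# ---------------------------------------------------------------------------
# metric resolution


@dataclass
class MetricResolutionResult:
    """Per-sample-size metric resolution and its constancy summary."""

    sizes: np.ndarray
    chi: np.ndarray
    sigma: np.ndarray
    w: np.ndarray
    a: np.ndarray
    info: np.ndarray  # measured information used per size
    lam: np.ndarray | None = None  # non-spatial metric content, if f_cor given
    warnings: list = field(default_factory=list)

    @property
    def chi_mean(self) -> float:
        return float(np.mean(self.chi))

    @property
    def chi_sd(self) -> float:
        return float(np.std(self.chi))

    @property
    def sigma_over_w(self) -> np.ndarray:
        return self.sigma / self.w


class MetricRangeError(RuntimeError):
    """Measured information falls outside the reference bracket."""


def solve_metric_resolution(
    info_curve: InfoCurve,
    bump_fits: list[BumpFit],
    S: int,
    drift: bool = False,
    n_draws: int = 50,
    seed: int | np.random.SeedSequence | None = None,
    use_fit: bool = True,
    pcor_curve: InfoCurve | None = None,
    tol_bits: float = 1e-3,
    out_of_range: str = "raise",
) -> MetricResolutionResult:
    """Solve the bump dispersion sigma and metric resolution chi per sample size.

    For each sample size the measured full-matrix information (from the fitted
    sigmoid curve by default, raw values with ``use_fit=False``) is matched to
    the max-mode reference information with that size's bump volume ``a`` and
    dispersion ``sigma`` bisected in ``[0, w]``; then ``chi = 1 - sigma/w``.
    Reference placements are drawn once per size and shared across sigma
    evaluations.  Raises :class:`MetricRangeError` when the measured value
    escapes the bracket [reference(sigma=w), reference(sigma=0)].

    If ``pcor_curve`` is given, the non-spatial metric content ``lambda`` is
    also reported per size from the closed-form bounds at the corresponding
    percent correct.
    """
    sizes = np.asarray(info_curve.sizes, dtype=float)
    if len(bump_fits) != sizes.size:
        raise ValueError("need one bump fit per sample size")
    L = int(round(np.sqrt(S)))
    rng = np.random.default_rng(seed)
    chi = np.empty(sizes.size)
    sig = np.empty(sizes.size)
    warnings_list: list[str] = []
    ws = np.array([bf.w for bf in bump_fits])
    avols = np.array([bf.a for bf in bump_fits])
    info_meas = np.empty(sizes.size)
    for i, n in enumerate(sizes):
        if use_fit:
            if info_curve.fit is None:
                raise ValueError("use_fit=True requires a fitted info curve")
            I_meas = float(info_curve.fit.predict(n))
        else:
            I_meas = float(info_curve.values[i])
        info_meas[i] = I_meas
        a = min(max(avols[i], 1e-6), 1.0)
        w = ws[i]
        n_bumps = len(bump_volumes(a))
        if n_bumps > S:
            raise MetricRangeError(
                f"size {n}: bump volume a={a:.4g} implies more bumps than bins"
            )
        placements = draw_reference_placements(S, n_bumps, n_draws, rng)

        def ref(s: float) -> float:
            return reference_information(
                S, a, s, n_bumps=n_bumps, mode="max", drift=drift,
                placements=placements, K=_kernel_translates(L, s),
            )

        hi = ref(0.0)
        lo = ref(w)
        if I_meas > hi + tol_bits or I_meas < lo - tol_bits:
            side = "sigma=0 ceiling" if I_meas > hi else "sigma=w floor"
            msg = (
                f"size {n}: measured information {I_meas:.3f} bits falls outside "
                f"the reference bracket [{lo:.3f}, {hi:.3f}] ({side})"
            )
            if out_of_range == "raise":
                raise MetricRangeError(msg)
            if out_of_range != "clamp":
                raise ValueError("out_of_range must be 'raise' or 'clamp'")
            warnings_list.append(msg)
        if I_meas >= hi:
            s_star = 0.0
        elif I_meas <= lo:
            s_star = w
        else:
            s_star = optimize.brentq(
                lambda s: ref(s) - I_meas, 0.0, w, xtol=1e-4 * max(w, 1e-6)
            )
        sig[i] = s_star
        chi[i] = 1.0 - s_star / w
    lam = None
    if pcor_curve is not None:
        lam = np.empty(sizes.size)
        for i, n in enumerate(sizes):
            f = (
                float(pcor_curve.fit.predict(n))
                if (use_fit and pcor_curve.fit is not None)
                else float(pcor_curve.values[i])
            )
            f = min(max(f, 1.0 / S + 1e-9), 1.0 - 1e-12)
            lam[i] = metric_content(
                info_meas[i], info_min(S, f), info_max_unbiased(S, f)
            )
    return MetricResolutionResult(
        sizes=sizes, chi=chi, sigma=sig, w=ws, a=avols, info=info_meas, lam=lam,
        warnings=warnings_list,
    )
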