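"""End-to-end experiment orchestration: learn -> templates -> test -> analysis.

A single :class:`ExperimentConfig` carries every model and protocol parameter
with the full-scale defaults (45,000 DG units, 1,500 CA3 units, 10,000
learning steps, 100,000 template steps, 400,000 test steps).  Presets scale
the protocol down while keeping connection densities and all dynamical
parameters fixed:

``paper``
    the full-scale protocol;
``desk``
    4,500 DG / 300 CA3 units, 50,000 test steps — reproduces the headline
    analysis on one CPU in minutes;
``tiny``
    1,000 DG / 100 CA3 units and short phases — a smoke-scale run.

Every stochastic stage draws its seed from a single root seed through named
``SeedSequence`` children, so a config reproduces its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .decoding import (
    ConfusionMatrix,
    ReducedMatrix,
    TemplateSet,
    build_templates,
    percent_correct,
    reduce_confusion,
    run_test_phase,
)
from .dg import DGPopulation, sample_dg_population
from .environment import TorusEnvironment, generate_trajectory
from .infometrics import (
    BumpFit,
    InfoCurve,
    MetricResolutionResult,
    fit_gaussian_bump,
    fit_sigmoid,
    mutual_information,
    reduced_information,
    solve_metric_resolution,
)
from .mds import Embedding, correlation_distance_matrix, sammon_map
from .network import CA3Network, default_network
from .plasticity import LearningConfig, run_learning_phase

__all__ = ["ExperimentConfig", "ExperimentResult", "PRESETS", "run_experiment"]

log = logging.getLogger("ca3metric")

PRESETS: dict[str, dict] = {
    "paper": {},
    "desk": {
        "n_dg": 4_500,
        "n_ca3": 300,
        "c_rc": 180,
        "test_steps": 50_000,
    },
    "tiny": {
        "n_dg": 1_000,
        "n_ca3": 100,
        "c_rc": 60,
        "learn_steps": 2_000,
        "template_steps": 10_000,
        "test_steps": 20_000,
        "sample_sizes": (1, 2, 4, 8, 16, 32, 64),
        "n_samples": 5,
        "n_reference_draws": 20,
    },
}


@dataclass
class ExperimentConfig:
    """All model, protocol and analysis parameters for one experiment."""

    # architecture
    n_dg: int = 45_000
    n_ca3: int = 1_500
    c_mf: float = 50.0
    c_rc: float = 900.0
    # DG population
    p_dg: float = 0.033
    q: float = 1.7
    beta0: float = 1.0
    sigma_f: float = 0.1
    # activity control
    target_sparsity: float = 0.1
    target_mean: float = 0.1
    noise_sd: float = 0.002
    n_iter: int = 15
    # recurrent plasticity
    gamma: float = 0.01
    tau: int = 14
    # environment and trajectory
    side: float = 1.0
    L: int = 8
    step_length: float = 0.025
    dt: float = 0.125
    heading_noise_sd: float = 0.35
    # phase lengths (time steps)
    learn_steps: int = 10_000
    template_steps: int = 100_000
    test_steps: int = 400_000
    # decoding samples
    sample_sizes: tuple = (1, 2, 4, 8, 16, 32, 64, 128, 256)
    n_samples: int = 10
    # analysis
    n_reference_draws: int = 50
    dg_modes: tuple = ("on", "off")
    seed: int = 0
    preset: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_dg", "n_ca3", "learn_steps", "template_steps", "test_steps",
                     "n_samples", "n_reference_draws", "n_iter", "tau", "L"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not (0 < self.p_dg <= 1):
            raise ValueError("p_dg must be in (0, 1]")
        if self.c_mf > self.n_dg or self.c_rc > self.n_ca3:
            raise ValueError("expected in-degrees cannot exceed layer sizes")
        for m in self.dg_modes:
            if m not in ("on", "off"):
                raise ValueError(f"unknown dg_mode {m!r}")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "ExperimentConfig":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        kw = dict(PRESETS[name])
        kw.update(overrides)
        return cls(preset=name, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sample_sizes"] = list(self.sample_sizes)
        d["dg_modes"] = list(self.dg_modes)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "sample_sizes" in d:
            d["sample_sizes"] = tuple(d["sample_sizes"])
        if "dg_modes" in d:
            d["dg_modes"] = tuple(d["dg_modes"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @property
    def sizes(self) -> list[int]:
        """Sample sizes actually usable (capped at the CA3 population)."""
        return [s for s in self.sample_sizes if s <= self.n_ca3]


# named seed-sequence children, in a frozen order
_SEED_STAGES = (
    "dg", "network", "learn_traj", "learn_noise", "samples", "mds",
    "template_traj_on", "template_noise_on", "test_traj_on", "test_noise_on",
    "reference_on",
    "template_traj_off", "template_noise_off", "test_traj_off", "test_noise_off",
    "reference_off",
)


def stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_SEED_STAGES))
    return dict(zip(_SEED_STAGES, children))


@dataclass
class ModeResult:
    """Decoding and information analysis for one DG condition."""

    templates: TemplateSet
    confusions: dict[int, list[ConfusionMatrix]]  # size -> one per sample
    reduced: dict[int, ReducedMatrix]  # size -> sample-averaged reduced matrix
    info_curve: InfoCurve
    pcor_curve: InfoCurve
    reduced_curve: InfoCurve
    bump_fits: list[BumpFit]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    env: TorusEnvironment
    network: CA3Network
    population: DGPopulation
    samples: dict[int, list[np.ndarray]]
    modes: dict[str, ModeResult]
    chi: dict[str, MetricResolutionResult]
    embedding: Embedding | None
    elapsed: dict[str, float] = field(default_factory=dict)


def draw_samples(
    sizes: list[int], n_samples: int, n_units: int, seed
) -> dict[int, list[np.ndarray]]:
    """Independent unit samples (without replacement) for each sample size."""
    rng = np.random.default_rng(seed)
    return {
        s: [np.sort(rng.choice(n_units, size=s, replace=False)) for _ in range(n_samples)]
        for s in sizes
    }


def _analyze_mode(
    cfg: ExperimentConfig,
    env: TorusEnvironment,
    templates: TemplateSet,
    confusions_flat: list[ConfusionMatrix],
    sizes: list[int],
) -> ModeResult:
    """Average information quantities over samples and fit the size curves."""
    n_rep = cfg.n_samples
    by_size = {
        s: confusions_flat[i * n_rep:(i + 1) * n_rep] for i, s in enumerate(sizes)
    }
    mi, pc, red_info, reduced, bumps = [], [], [], {}, []
    for s in sizes:
        mats = by_size[s]
        mi.append(float(np.mean([mutual_information(c) for c in mats])))
        pc.append(float(np.mean([percent_correct(c) for c in mats])))
        reds = [reduce_confusion(c, env) for c in mats]
        red_info.append(float(np.mean([reduced_information(r) for r in reds])))
        avg = ReducedMatrix(probs=np.mean([r.probs for r in reds], axis=0))
        reduced[s] = avg
        bumps.append(fit_gaussian_bump(avg))
    sizes_arr = np.array(sizes, dtype=float)
    info_curve = InfoCurve(sizes_arr, np.array(mi), fit_sigmoid(sizes, mi, "info"))
    pcor_curve = InfoCurve(sizes_arr, np.array(pc), fit_sigmoid(sizes, pc, "pcor"))
    reduced_curve = InfoCurve(
        sizes_arr, np.array(red_info), fit_sigmoid(sizes, red_info, "info")
    )
    return ModeResult(
        templates=templates,
        confusions=by_size,
        reduced=reduced,
        info_curve=info_curve,
        pcor_curve=pcor_curve,
        reduced_curve=reduced_curve,
        bump_fits=bumps,
    )


def run_experiment(
    cfg: ExperimentConfig,
    out_dir=None,
    run_mds: bool = True,
) -> ExperimentResult:
    """Execute the full protocol described by ``cfg``.

    Phases: sample the DG population and connectivity; learning session
    (trace-Hebbian plasticity, weights installed at the end); per DG
    condition a template-building run and a decoding test run over unit
    samples of increasing size; information/bump analysis and the metric
    resolution solve; Sammon MDS of the DG-on full-population templates.
    If ``out_dir`` is given, all outputs plus a manifest are written there
    (see :mod:`ca3metric.io`).
    """
    seeds = stage_seeds(cfg.seed)
    env = TorusEnvironment(side=cfg.side, L=cfg.L)
    elapsed: dict[str, float] = {}
    t0 = time.perf_counter()

    pop = sample_dg_population(
        cfg.n_dg, cfg.q, cfg.p_dg, cfg.beta0, cfg.sigma_f, env, seed=seeds["dg"]
    )
    net0 = default_network(
        cfg.n_dg, cfg.n_ca3, cfg.c_mf, cfg.c_rc,
        noise_sd=cfg.noise_sd, seed=seeds["network"],
        target_sparsity=cfg.target_sparsity, target_mean=cfg.target_mean,
        n_iter=cfg.n_iter,
    )
    log.info("sampled DG population (%d active cells) and connectivity",
             len(pop.active_ids))

    learn_traj = generate_trajectory(
        env, cfg.learn_steps, cfg.step_length, cfg.heading_noise_sd,
        seed=seeds["learn_traj"],
    )
    net = run_learning_phase(
        net0, pop, learn_traj,
        LearningConfig(gamma=cfg.gamma, n_steps=cfg.learn_steps, tau=cfg.tau),
        seed=seeds["learn_noise"],
    )
    elapsed["learning"] = time.perf_counter() - t0
    log.info("learning phase done (%d steps, %.1f s)",
             cfg.learn_steps, elapsed["learning"])

    sizes = cfg.sizes
    samples = draw_samples(sizes, cfg.n_samples, cfg.n_ca3, seeds["samples"])
    flat_samples = [s for size in sizes for s in samples[size]]

    modes: dict[str, ModeResult] = {}
    for mode in cfg.dg_modes:
        t1 = time.perf_counter()
        ttraj = generate_trajectory(
            env, cfg.template_steps, cfg.step_length, cfg.heading_noise_sd,
            seed=seeds[f"template_traj_{mode}"],
        )
        templates = build_templates(
            net, pop, ttraj, np.arange(cfg.n_ca3), env,
            dg_mode=mode, seed=seeds[f"template_noise_{mode}"],
        )
        elapsed[f"templates_{mode}"] = time.perf_counter() - t1
        log.info("templates (%s) built in %.1f s", mode, elapsed[f"templates_{mode}"])

        t1 = time.perf_counter()
        test_traj = generate_trajectory(
            env, cfg.test_steps, cfg.step_length, cfg.heading_noise_sd,
            seed=seeds[f"test_traj_{mode}"],
        )
        confusions = run_test_phase(
            net, pop, test_traj, templates, flat_samples,
            dg_mode=mode, env=env, seed=seeds[f"test_noise_{mode}"],
        )
        elapsed[f"test_{mode}"] = time.perf_counter() - t1
        log.info("test phase (%s) done in %.1f s", mode, elapsed[f"test_{mode}"])
        modes[mode] = _analyze_mode(cfg, env, templates, confusions, sizes)

    chi: dict[str, MetricResolutionResult] = {}
    if "on" in modes:
        chi["on"] = solve_metric_resolution(
            modes["on"].info_curve, modes["on"].bump_fits, env.n_bins,
            drift=False, n_draws=cfg.n_reference_draws,
            seed=seeds["reference_on"], pcor_curve=modes["on"].pcor_curve,
            out_of_range="clamp",
        )
        log.info("chi (DG on): mean %.3f sd %.3f", chi["on"].chi_mean, chi["on"].chi_sd)
    if "off" in modes:
        # the reference bump shape for the DG-off condition reuses the
        # (a, w) parameters fitted on the DG-on reduced matrix; drift is
        # modelled by splitting every bump into two adjacent half bumps
        bump_source = modes["on"].bump_fits if "on" in modes else modes["off"].bump_fits
        chi["off"] = solve_metric_resolution(
            modes["off"].info_curve, bump_source, env.n_bins,
            drift=True, n_draws=cfg.n_reference_draws,
            seed=seeds["reference_off"], pcor_curve=modes["off"].pcor_curve,
            out_of_range="clamp",
        )
        log.info("chi (DG off): mean %.3f sd %.3f", chi["off"].chi_mean, chi["off"].chi_sd)

    embedding = None
    if run_mds and "on" in modes:
        t1 = time.perf_counter()
        dist = correlation_distance_matrix(modes["on"].templates)
        embedding = sammon_map(dist, dim=3, n_iter=500, seed=seeds["mds"])
        elapsed["mds"] = time.perf_counter() - t1
        log.info("Sammon stress: %.4f", embedding.stress)

    elapsed["total"] = time.perf_counter() - t0
    result = ExperimentResult(
        config=cfg, env=env, network=net, population=pop, samples=samples,
        modes=modes, chi=chi, embedding=embedding, elapsed=elapsed,
    )
    if out_dir is not None:
        from .io import write_result

        write_result(result, out_dir)
    return result
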