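"""Delimited-text serialisation of experiment state and results.

Everything is written as plain text (CSV/TSV/JSON) so runs can be archived,
diffed and re-read without binary dependencies.  A run directory contains::

    config.json                 the full ExperimentConfig
    manifest.json               config hash, package version, file list
    state/                      DG population, connectivity, weights
    templates_{mode}.csv        per-bin full-population templates
    confusion_{mode}_n{n}.txt   sample-averaged confusion probabilities
    reduced_{mode}_n{n}.txt     sample-averaged reduced matrices
    analysis_{mode}.csv         per-size information/bump/chi table
    fits_{mode}.json            sigmoid and bump fit parameters
    embedding.csv               3-D Sammon coordinates per bin

Outputs contain no timestamps, so identical configs produce byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decoding import TemplateSet
from .dg import DGCell, DGPopulation
from .experiment import ExperimentConfig, ExperimentResult
from .infometrics import BumpFit
from .network import CA3Network, Connectivity

__all__ = [
    "write_result",
    "save_state",
    "load_state",
    "save_templates",
    "load_templates",
    "config_hash",
]


def config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_matrix(path: Path, m: np.ndarray, header: dict) -> None:
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
        np.savetxt(fh, m, fmt="%.10g")


def _read_matrix(path: Path) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        first = fh.readline()
        header = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
        m = np.loadtxt(fh)
    return m, header


# ---------------------------------------------------------------------------
# network / population state


def save_state(path, net: CA3Network, pop: DGPopulation) -> None:
    """Write connectivity, weights and the DG population under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, conn in (("conn_mf", net.conn_mf), ("conn_rc", net.conn_rc)):
        post, pre = np.nonzero(conn.matrix)
        pd.DataFrame({"post": post, "pre": pre}).to_csv(path / f"{name}.csv", index=False)
    post, pre = np.nonzero(net.conn_rc.matrix)
    pd.DataFrame(
        {"post": post, "pre": pre, "weight": net.j_rc[post, pre]}
    ).to_csv(path / "j_rc.csv", index=False, float_format="%.12g")
    scalars = {
        "n_dg": net.n_dg,
        "n_ca3": net.n_ca3,
        "c_mf": net.conn_mf.c,
        "c_rc": net.conn_rc.c,
        "j_mf": net.j_mf,
        "noise_sd": net.noise_sd,
        "target_sparsity": net.target_sparsity,
        "target_mean": net.target_mean,
        "n_iter": net.n_iter,
        "beta0": pop.beta0,
        "sigma_f": pop.sigma_f,
        "n_dg_cells": pop.n_cells,
    }
    with open(path / "scalars.json", "w") as fh:
        json.dump(scalars, fh, indent=1, sort_keys=True)
    pop.to_csv(path / "dg_fields.csv")
    active = np.zeros(pop.n_cells, dtype=int)
    active[pop.active_ids] = 1
    pd.DataFrame({"cell": np.arange(pop.n_cells), "active": active}).to_csv(
        path / "dg_active.csv", index=False
    )


def load_state(path) -> tuple[CA3Network, DGPopulation]:
    path = Path(path)
    with open(path / "scalars.json") as fh:
        sc = json.load(fh)
    n_dg, n_ca3 = int(sc["n_dg"]), int(sc["n_ca3"])

    def read_conn(name, shape, c):
        df = pd.read_csv(path / f"{name}.csv")
        m = np.zeros(shape, dtype=np.uint8)
        m[df["post"].to_numpy(), df["pre"].to_numpy()] = 1
        return Connectivity(matrix=m, c=c)

    conn_mf = read_conn("conn_mf", (n_ca3, n_dg), sc["c_mf"])
    conn_rc = read_conn("conn_rc", (n_ca3, n_ca3), sc["c_rc"])
    jdf = pd.read_csv(path / "j_rc.csv")
    j_rc = np.zeros((n_ca3, n_ca3))
    j_rc[jdf["post"].to_numpy(), jdf["pre"].to_numpy()] = jdf["weight"].to_numpy()
    net = CA3Network(
        conn_mf=conn_mf,
        conn_rc=conn_rc,
        j_mf=sc["j_mf"],
        j_rc=j_rc,
        noise_sd=sc["noise_sd"],
        target_sparsity=sc["target_sparsity"],
        target_mean=sc["target_mean"],
        n_iter=int(sc["n_iter"]),
    )
    fields = pd.read_csv(path / "dg_fields.csv", comment="#")
    active = pd.read_csv(path / "dg_active.csv")
    cells = []
    grouped = {int(k): v[["x", "y"]].to_numpy() for k, v in fields.groupby("cell")}
    for i in range(int(sc["n_dg_cells"])):
        is_active = bool(active["active"].iloc[i])
        centers = grouped.get(i, np.empty((0, 2)))
        cells.append(DGCell(active=is_active, centers=centers))
    pop = DGPopulation(cells=cells, beta0=sc["beta0"], sigma_f=sc["sigma_f"])
    return net, pop


# ---------------------------------------------------------------------------
# templates


def save_templates(path, templates: TemplateSet) -> None:
    df = templates.to_frame()
    df.insert(1, "occupancy", templates.occupancy)
    df.to_csv(path, index=False, float_format="%.10g")


def load_templates(path) -> TemplateSet:
    df = pd.read_csv(path)
    unit_cols = [c for c in df.columns if c.startswith("u")]
    return TemplateSet(
        templates=df[unit_cols].to_numpy(),
        sample=np.array([int(c[1:]) for c in unit_cols], dtype=np.int64),
        occupancy=df["occupancy"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# analysis tables


def _fit_params(fit) -> dict:
    if fit is None:
        return {}
    return {
        "form": fit.form,
        "params": [float(p) for p in fit.params],
        "residual": fit.residual,
        "degenerate": fit.degenerate,
    }


def _bump_dict(b: BumpFit) -> dict:
    return {
        "pc": b.pc, "w": b.w, "a": b.a, "baseline": b.baseline,
        "residual": b.residual, "sub_resolution": b.sub_resolution,
    }


def analysis_table(result: ExperimentResult, mode: str) -> pd.DataFrame:
    """Per-size summary: n, I_full, I_reduced, f_cor, pc, w, a, lambda, sigma, chi."""
    mr = result.modes[mode]
    sizes = mr.info_curve.sizes.astype(int)
    chi = result.chi.get(mode)
    rows = {
        "n": sizes,
        "I_full": mr.info_curve.values,
        "I_reduced": mr.reduced_curve.values,
        "f_cor": mr.pcor_curve.values,
        "pc": [b.pc for b in mr.bump_fits],
        "w": [b.w for b in mr.bump_fits],
        "a": [b.a for b in mr.bump_fits],
    }
    if chi is not None:
        rows["lambda"] = chi.lam if chi.lam is not None else np.full(len(sizes), np.nan)
        rows["sigma"] = chi.sigma
        rows["chi"] = chi.chi
    return pd.DataFrame(rows)


def write_result(result: ExperimentResult, out_dir) -> None:
    """Write every result artefact of an experiment run to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    cfg.to_json(out / "config.json")
    save_state(out / "state", result.network, result.population)
    files = ["config.json"]
    for mode, mr in result.modes.items():
        save_templates(out / f"templates_{mode}.csv", mr.templates)
        files.append(f"templates_{mode}.csv")
        for s in mr.info_curve.sizes.astype(int):
            avg = np.mean(
                [c.counts / c.counts.sum() for c in mr.confusions[int(s)]], axis=0
            )
            _write_matrix(
                out / f"confusion_{mode}_n{s}.txt", avg,
                {"dg_mode": mode, "sample_size": int(s),
                 "n_samples": cfg.n_samples, "test_steps": cfg.test_steps,
                 "seed": cfg.seed},
            )
            _write_matrix(
                out / f"reduced_{mode}_n{s}.txt", mr.reduced[int(s)].probs,
                {"dg_mode": mode, "sample_size": int(s), "seed": cfg.seed},
            )
            files += [f"confusion_{mode}_n{s}.txt", f"reduced_{mode}_n{s}.txt"]
        analysis_table(result, mode).to_csv(
            out / f"analysis_{mode}.csv", index=False, float_format="%.8g"
        )
        fits = {
            "info": _fit_params(mr.info_curve.fit),
            "pcor": _fit_params(mr.pcor_curve.fit),
            "reduced_info": _fit_params(mr.reduced_curve.fit),
            "bumps": {int(s): _bump_dict(b)
                      for s, b in zip(mr.info_curve.sizes.astype(int), mr.bump_fits)},
        }
        chi = result.chi.get(mode)
        if chi is not None:
            fits["chi"] = {
                "mean": chi.chi_mean, "sd": chi.chi_sd,
                "per_size": {int(n): float(c) for n, c in zip(chi.sizes, chi.chi)},
                "sigma_per_size": {int(n): float(s) for n, s in zip(chi.sizes, chi.sigma)},
                "warnings": chi.warnings,
            }
        with open(out / f"fits_{mode}.json", "w") as fh:
            json.dump(fits, fh, indent=1, sort_keys=True)
        files += [f"analysis_{mode}.csv", f"fits_{mode}.json"]
    if result.embedding is not None:
        L = result.env.L
        bins = np.arange(result.env.n_bins)
        df = pd.DataFrame(result.embedding.coords, columns=["x", "y", "z"])
        df.insert(0, "bin", bins)
        # grid-line metadata: row/col let plotting code join orthogonal
        # directions of the environment
        df["row"] = bins // L
        df["col"] = bins % L
        df.to_csv(out / "embedding.csv", index=False, float_format="%.8g")
        with open(out / "embedding_stress.json", "w") as fh:
            json.dump({"stress": result.embedding.stress}, fh)
        files += ["embedding.csv", "embedding_stress.json"]
    manifest = {
        "package": "ca3metric",
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "preset": cfg.preset,
        "files": sorted(files),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
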