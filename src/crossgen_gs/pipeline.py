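"""Run configuration and end-to-end orchestration.

A run is described by a strict YAML/dict config: either a ``sim`` block
(synthetic population) or explicit input paths, plus parameter blocks for
QC, kernel blending, REML, the validation approaches and the cambial-age
sweep. ``run_pipeline`` executes simulate -> phenotypes -> qc -> kernels ->
fits -> validation/sweep, writes every declared output, and records a
manifest (config hash, seed, versions, per-stage timings and output
checksums) sufficient to re-execute the run.
"""
from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, blup, io, phenotypes, validation
from .relationships import blend, build_A, build_G, impute_missing, qc_filter
from .synthetic_data import SimConfig, simulate_population

__all__ = ["RunConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "sim", "inputs", "qc", "blend_weight", "reml", "approaches", "models",
    "trait", "sweep", "seed", "outdir", "adjust_with_kernel",
}


@dataclass
class RunConfig:
    seed: int
    outdir: str
    sim: dict | None = None
    inputs: dict | None = None
    qc: dict = field(default_factory=dict)
    blend_weight: float = 0.98
    reml: dict = field(default_factory=lambda: {"algorithm": "em", "tol": 1e-6, "max_iter": 500})
    approaches: list = field(default_factory=lambda: ["A", "B", "C"])
    models: list = field(default_factory=lambda: ["ABLUP", "GBLUP"])
    trait: str = "density"
    sweep: dict | None = None
    adjust_with_kernel: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw or "outdir" not in raw:
            raise ValueError("config requires 'seed' and 'outdir'")
        if ("sim" in raw) == ("inputs" in raw):
            raise ValueError("config needs exactly one of 'sim' or 'inputs'")
        cfg = cls(**raw)
        if cfg.inputs:
            for key, path in cfg.inputs.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"input {key}: {path} does not exist")
        return cfg

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": [],
        "outputs": {},
        "completed": False,
    }
    t0 = time.time()

    def stage_done(name):
        manifest["stages"].append({"stage": name, "t_elapsed_s": round(time.time() - t0, 3)})

    def emit(name, path):
        manifest["outputs"][name] = {
            "path": str(path), "sha256": io.file_checksum(path)
        }

    try:
        # --- data stage ------------------------------------------------
        if config.sim is not None:
            sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
            sim = simulate_population(sim_cfg)
            pedigree, genotypes = sim.pedigree, sim.genotypes
            rings, design = sim.ring_table, sim.design
            io.write_pedigree(pedigree, out / "pedigree.csv")
            io.write_genotypes_tsv(genotypes, out / "genotypes.tsv")
            io.write_rings(rings, out / "rings.csv")
            io.write_design(design, out / "design.csv")
            io.write_truth(sim, out / "truth.json")
            for name in ("pedigree.csv", "genotypes.tsv", "rings.csv",
                         "design.csv", "truth.json"):
                emit(name, out / name)
        else:
            pedigree = io.read_pedigree(config.inputs["pedigree"])
            genotypes = io.read_genotypes(config.inputs["genotypes"])
            rings = io.read_rings(config.inputs["rings"])
            design = io.read_design(config.inputs["design"])
        stage_done("data")

        # --- qc + kernels ----------------------------------------------
        genotypes_qc, report = qc_filter(genotypes, **config.qc)
        (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=1))
        emit("qc_report.json", out / "qc_report.json")
        genotypes_qc = impute_missing(genotypes_qc)
        G = blend(build_G(genotypes_qc), config.blend_weight)
        A = build_A(pedigree)
        io.write_relationship_matrix(G, out / "G.tsv")
        io.write_relationship_matrix(A, out / "A.tsv")
        emit("G.tsv", out / "G.tsv")
        emit("A.tsv", out / "A.tsv")
        stage_done("kernels")

        # --- phenotypes -------------------------------------------------
        traits = phenotypes.derive_traits(rings, "whole-core", trait=config.trait)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            adj = phenotypes.adjust_phenotypes(
                traits, design, relationship=G if config.adjust_with_kernel else None
            )
        adj.to_csv(out / "adjusted.csv", index=False)
        emit("adjusted.csv", out / "adjusted.csv")
        adjusted = pd.Series(adj["adjusted"].to_numpy(), index=adj["id"].to_numpy())
        cohorts = pd.Series(design["cohort"].to_numpy(), index=design["id"].to_numpy())
        stage_done("phenotypes")

        # --- validation --------------------------------------------------
        results = []
        reml_opts = {k: config.reml[k] for k in ("algorithm", "tol", "max_iter")
                     if k in config.reml}
        for model in config.models:
            kernel = G if model.upper() == "GBLUP" else A
            for approach in config.approaches:
                results.extend(
                    validation.run_approach(
                        approach, model.upper(), adjusted, cohorts, kernel,
                        trait=config.trait, **reml_opts,
                    )
                )
        vframe = validation.results_to_frame(results)
        vframe.to_csv(out / "validation.tsv", sep="\t", index=False)
        emit("validation.tsv", out / "validation.tsv")
        stage_done("validation")

        # --- sweep --------------------------------------------------------
        if config.sweep:
            g0_ids = design.loc[design["cohort"] == "G0", "id"]
            g0_rings = rings[rings["id"].isin(g0_ids)]
            adj_j = phenotypes.derive_traits(rings, "juvenile", trait=config.trait)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                adj_j = phenotypes.adjust_phenotypes(adj_j, design, relationship=None)
            juv = pd.Series(adj_j["adjusted"].to_numpy(), index=adj_j["id"].to_numpy())
            targets = {}
            for trial in sorted(design.loc[design["cohort"] != "G0", "trial"].unique()):
                ids = design.loc[design["trial"] == trial, "id"]
                windows = config.sweep.get("windows", ["juvenile-10", "whole-core"])
                if "whole-core" in windows:
                    targets[(trial, "whole-core")] = adjusted.loc[adjusted.index.isin(ids)]
                if "juvenile-10" in windows:
                    targets[(trial, "juvenile-10")] = juv.loc[juv.index.isin(ids)]
            sweep_rows = []
            ring_lo, ring_hi = config.sweep.get("rings", [1, 21])
            for mode in config.sweep.get("modes", ["AWE", "SAD"]):
                sweep_rows.extend(
                    validation.early_training_sweep(
                        g0_rings, targets, G, mode,
                        rings=range(ring_lo, ring_hi + 1),
                    )
                )
            sframe = validation.results_to_frame(sweep_rows)
            sframe.to_csv(out / "sweep.tsv", sep="\t", index=False)
            emit("sweep.tsv", out / "sweep.tsv")
            stage_done("sweep")

        manifest["completed"] = True
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
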