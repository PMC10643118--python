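"""End-to-end run orchestration.

A single TOML run configuration drives hallucinate -> score -> filter ->
pocket -> cluster stages with one master seed; per-stage RNG streams are
spawned from it so reordering stages cannot silently reshuffle
randomness.  Every output file is listed in a manifest JSON and is
reproducible from config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from pseudocycle.structure_io import RepeatSpec, write_pdb
from pseudocycle.repeat_geometry import repeat_screw
from pseudocycle.closure_scoring import (
    DEFAULT_CLOSURE_CUTOFF, DEFAULT_PLDDT_CUTOFF, LossWeights, closure_score)
from pseudocycle.mcmc_engine import (
    CANONICAL_AA, MCMCConfig, run_trajectory, toy_predictor)
from pseudocycle.pocket_finder import detect_largest_cavity
from pseudocycle.compare_cluster import cluster_scaffolds, pairwise_tm_matrix

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "out_dir", "n_units", "unit_length", "n_trajectories",
    "steps", "temperature", "n_mut_min", "n_mut_max", "alphabet",
    "w_closure", "w_confidence", "closure_cutoff", "plddt_cutoff",
    "predictor", "pocket_spacing", "pocket_probe", "pocket_close_radius",
    "pocket_contact_cutoff", "intra_tm_threshold", "stages",
}
_DEFAULT_STAGES = ("hallucinate", "pocket", "cluster")


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run (all module defaults
    in one document; unknown keys are rejected at load time)."""

    n_units: int
    unit_length: int
    seed: int = 0
    out_dir: str = "pseudocycle_run"
    n_trajectories: int = 5
    steps: int = 300
    temperature: float = 0.03
    n_mut_min: int = 1
    n_mut_max: int = 3
    alphabet: str = CANONICAL_AA
    w_closure: float = 1.0
    w_confidence: float = 1.0
    closure_cutoff: float = DEFAULT_CLOSURE_CUTOFF
    plddt_cutoff: float = DEFAULT_PLDDT_CUTOFF
    predictor: str = "toy"
    pocket_spacing: float = 1.0
    pocket_probe: float = 1.4
    pocket_close_radius: float = 4.0
    pocket_contact_cutoff: float = 4.5
    intra_tm_threshold: float = 0.85
    stages: tuple[str, ...] = _DEFAULT_STAGES

    def __post_init__(self) -> None:
        # validate against module invariants up front
        self.repeat_spec  # RepeatSpec bounds
        self.mcmc_config(self.seed)
        unknown = set(self.stages) - set(_DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @property
    def repeat_spec(self) -> RepeatSpec:
        return RepeatSpec(self.n_units, self.unit_length)

    def mcmc_config(self, seed: int) -> MCMCConfig:
        return MCMCConfig(
            steps=self.steps, temperature=self.temperature,
            n_mut_min=self.n_mut_min, n_mut_max=self.n_mut_max,
            seed=seed, alphabet=self.alphabet,
            weights=LossWeights(self.w_closure, self.w_confidence))

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _get_predictor(name: str):
    if name == "toy":
        return toy_predictor
    raise ValueError(
        f"unknown predictor {name!r}; external predictors plug in through "
        "the StructurePredictor contract in pseudocycle.mcmc_engine")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write a manifest.

    Returns the manifest dict; on a stage failure the manifest marks the
    stage failed and downstream stages are skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.repeat_spec
    predictor = _get_predictor(config.predictor)
    seed_root = np.random.SeedSequence(config.seed)
    stage_seeds = {name: s.generate_state(1)[0] % (2 ** 31)
                   for name, s in zip(_DEFAULT_STAGES,
                                      seed_root.spawn(len(_DEFAULT_STAGES)))}
    manifest: dict = {
        "package": "pseudocycle",
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stages": {},
        "files": [],
    }

    def _log_event(stage: str, **fields) -> None:
        logger.info(json.dumps({"stage": stage, **fields}))

    best_structures = []
    halted = False
    for stage in config.stages:
        t0 = time.monotonic()
        entry: dict = {"status": "skipped" if halted else "running"}
        manifest["stages"][stage] = entry
        if halted:
            continue
        try:
            if stage == "hallucinate":
                rng = np.random.default_rng(stage_seeds[stage])
                summary = []
                for i in range(config.n_trajectories):
                    traj_seed = int(rng.integers(2 ** 31))
                    cfg = config.mcmc_config(traj_seed)
                    records, best_seq, best_struct = run_trajectory(
                        spec, predictor, cfg)
                    df = pd.DataFrame([dataclasses.asdict(r)
                                       for r in records])
                    csv = out / f"trajectory_{i:03d}.csv"
                    df.to_csv(csv, index=False)
                    pdb = out / f"best_{i:03d}.pdb"
                    write_pdb(best_struct, pdb)
                    fasta = out / f"best_{i:03d}.fasta"
                    fasta.write_text(
                        f">design_{i:03d} N={spec.n_units} "
                        f"L={spec.unit_length}\n{best_seq.full}\n")
                    _, deltas = repeat_screw(best_struct, spec)
                    cres = closure_score(deltas)
                    converged = (cres.closure_score < config.closure_cutoff
                                 and records[-1].plddt >= 0.0)
                    summary.append({
                        "trajectory": i, "seed": traj_seed,
                        "closure_score": cres.closure_score,
                        "final_loss": records[-1].best_so_far,
                        "converged": bool(converged)})
                    manifest["files"] += [str(csv), str(pdb), str(fasta)]
                    best_structures.append(best_struct)
                    _log_event(stage, trajectory=i,
                               closure=cres.closure_score)
                entry["trajectories"] = summary
            elif stage == "pocket":
                pockets = []
                for i, s in enumerate(best_structures):
                    grid, pocket = detect_largest_cavity(
                        s, spacing=config.pocket_spacing,
                        close_radius=config.pocket_close_radius,
                        probe=config.pocket_probe)
                    path = out / f"pocket_{i:03d}.json"
                    path.write_text(json.dumps({
                        "volume_A3": pocket.volume_A3,
                        "n_voxels": int(len(pocket.voxels)),
                        "contact_residues": pocket.contact_residues}))
                    pockets.append({"design": i,
                                    "volume_A3": pocket.volume_A3})
                    manifest["files"].append(str(path))
                entry["pockets"] = pockets
            elif stage == "cluster":
                if len(best_structures) >= 2:
                    tm = pairwise_tm_matrix(best_structures)
                    report = cluster_scaffolds(
                        best_structures, [spec] * len(best_structures),
                        intra_tm_threshold=config.intra_tm_threshold,
                        tm_matrix=tm)
                    path = out / "cluster_report.json"
                    path.write_text(json.dumps({
                        "assignments": {str(k): v for k, v in
                                        report.assignments.items()},
                        "n_clusters": report.n_clusters,
                        "singleton_fraction": report.singleton_fraction,
                        "mean_intra_tm": report.mean_intra_tm,
                        "sd_intra_tm": report.sd_intra_tm}, default=float))
                    manifest["files"].append(str(path))
                    entry["n_clusters"] = report.n_clusters
                else:
                    entry["note"] = "fewer than 2 structures; nothing to do"
            entry["status"] = "ok"
        except Exception as exc:  # halt downstream stages, keep manifest
            logger.exception("stage %s failed", stage)
            entry["status"] = "failed"
            entry["error"] = str(exc)
            halted = True
        entry["wall_time_s"] = round(time.monotonic() - t0, 3)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=float))
    manifest["files"].append(str(manifest_path))
    return manifest
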