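"""Sequence-space Metropolis MCMC hallucination over repeat-symmetric
sequences.

Starting from a random L-residue unit repeated N times, each step mutates
one to three unit positions, propagates the substitutions to every unit,
predicts a structure with any predictor satisfying the contract, scores
cyclic closure and confidence, and accepts or rejects by the standard
Metropolis criterion.  A deterministic toy predictor provides a solvable
optimization landscape for testing and calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from pseudocycle.structure_io import ProteinStructure, RepeatSpec
from pseudocycle.repeat_geometry import repeat_screw
from pseudocycle.closure_scoring import (
    ClosureResult, ConfidenceMetrics, LossWeights,
    closure_score, hallucination_loss)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = set("AILMFVWY")
CHARGED = set("DEKR")

# Predictor contract: full sequence + repeat spec -> (structure of equal
# length, confidence metrics); deterministic for a fixed sequence.
Predictor = Callable[[str, RepeatSpec], tuple[ProteinStructure,
                                              ConfidenceMetrics]]


class PredictorContractError(RuntimeError):
    """Raised when a predictor violates its contract."""


@dataclass(frozen=True)
class SymmetricSequence:
    """An L-residue unit repeated N times."""

    unit: str
    n_units: int

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("unit sequence must be non-empty")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")

    @property
    def full(self) -> str:
        return self.unit * self.n_units

    def __len__(self) -> int:
        return len(self.unit) * self.n_units


@dataclass(frozen=True)
class MCMCConfig:
    """Hallucination run settings.

    ``temperature`` is the Metropolis temperature on the O(1) loss scale;
    substitution counts per step are drawn uniformly from
    [n_mut_min, n_mut_max].
    """

    steps: int = 300
    temperature: float = 0.03
    n_mut_min: int = 1
    n_mut_max: int = 3
    seed: int = 0
    alphabet: str = CANONICAL_AA
    weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 1 <= self.n_mut_min <= self.n_mut_max:
            raise ValueError("need 1 <= n_mut_min <= n_mut_max")
        if len(set(self.alphabet)) != len(self.alphabet) or not self.alphabet:
            raise ValueError("alphabet must be non-empty without duplicates")


@dataclass(frozen=True)
class TrajectoryRecord:
    step: int
    proposed_unit: str
    loss: float
    closure_score: float
    plddt: float
    accepted: bool
    best_so_far: float


def random_unit_sequence(L: int, alphabet: str = CANONICAL_AA,
                         seed: int = 0) -> str:
    """Uniform i.i.d. random unit sequence, reproducible under the seed."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    rng = np.random.default_rng(seed)
    letters = list(alphabet)
    return "".join(rng.choice(letters) for _ in range(L))


def propose_mutation(seq: SymmetricSequence, cfg: MCMCConfig,
                     rng: np.random.Generator) -> SymmetricSequence:
    """Mutate k ~ Uniform[n_mut_min, n_mut_max] distinct unit positions to
    different residues; the substitutions appear at the same offset in
    every unit, so the full-sequence Hamming distance is exactly k*N."""
    if len(cfg.alphabet) < 2:
        raise ValueError("alphabet must contain at least two residues "
                         "to propose a substitution")
    L = len(seq.unit)
    k = int(rng.integers(cfg.n_mut_min, min(cfg.n_mut_max, L) + 1))
    positions = rng.choice(L, size=k, replace=False)
    unit = list(seq.unit)
    for pos in positions:
        choices = [a for a in cfg.alphabet if a != unit[pos]]
        unit[pos] = choices[int(rng.integers(len(choices)))]
    return SymmetricSequence("".join(unit), seq.n_units)


def metropolis_accept(delta_loss: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis rule: always accept non-positive loss changes,
    otherwise accept with probability exp(-delta/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_loss <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_loss / temperature))


def toy_predictor(sequence: str, spec: RepeatSpec
                  ) -> tuple[ProteinStructure, ConfidenceMetrics]:
    """Deterministic test-double structure predictor.

    Maps the unit's hydrophobic fraction h (AILMFVWY) and charged
    fraction c (DEKR) onto closure deviations of a synthetic C_N backbone:
    delta_rise = 10*|h - 0.4| Angstrom, delta_rotation = 40*|c - 0.25|
    degrees, pLDDT = 100*max(0, 1 - |h - 0.4| - |c - 0.25|).  The global
    optimum (perfect closure, pLDDT 100) sits at h = 0.4, c = 0.25.
    """
    from pseudocycle.synthetic_backbones import CyclicBackboneSpec, build_cyclic

    if len(sequence) != spec.total_length:
        raise ValueError(
            f"sequence length {len(sequence)} != N*L = {spec.total_length}")
    unit = sequence[:spec.unit_length]
    h = sum(a in HYDROPHOBIC for a in unit) / len(unit)
    c = sum(a in CHARGED for a in unit) / len(unit)
    bspec = CyclicBackboneSpec(
        n_units=spec.n_units, unit_template="H" * spec.unit_length,
        inject_rise=10.0 * abs(h - 0.4),
        inject_rotation=40.0 * abs(c - 0.25),
        seed=0, sequence=unit)
    structure, _ = build_cyclic(bspec)
    plddt = 100.0 * max(0.0, 1.0 - abs(h - 0.4) - abs(c - 0.25))
    return structure, ConfidenceMetrics(plddt=plddt)


def _evaluate(sequence: SymmetricSequence, spec: RepeatSpec,
              predictor: Predictor, cfg: MCMCConfig,
              cache: dict) -> tuple[float, ClosureResult, ConfidenceMetrics,
                                    ProteinStructure]:
    full = sequence.full
    if full in cache:
        return cache[full]
    structure, conf = predictor(full, spec)
    if len(structure) != len(full):
        raise PredictorContractError(
            f"predictor returned {len(structure)} residues for a "
            f"{len(full)}-residue sequence")
    _, deltas = repeat_screw(structure, spec)
    result = closure_score(deltas)
    loss = hallucination_loss(result, conf, cfg.weights)
    cache[full] = (loss, result, conf, structure)
    return cache[full]


def run_trajectory(spec: RepeatSpec, predictor: Predictor,
                   cfg: MCMCConfig
                   ) -> tuple[list[TrajectoryRecord], SymmetricSequence,
                              ProteinStructure]:
    """Run one seeded Metropolis trajectory; returns the per-step log and
    the best-loss sequence/structure encountered.

    Predictions are cached by full sequence, so re-proposing a previously
    scored sequence costs no predictor call.
    """
    rng = np.random.default_rng(cfg.seed)
    unit = random_unit_sequence(
        spec.unit_length, cfg.alphabet,
        seed=int(rng.integers(2 ** 31)))
    current = SymmetricSequence(unit, spec.n_units)
    cache: dict = {}
    cur_loss, cur_res, cur_conf, cur_struct = _evaluate(
        current, spec, predictor, cfg, cache)
    best_seq, best_loss, best_struct = current, cur_loss, cur_struct

    records: list[TrajectoryRecord] = []
    for step in range(1, cfg.steps + 1):
        proposal = propose_mutation(current, cfg, rng)
        loss, res, conf, struct = _evaluate(
            proposal, spec, predictor, cfg, cache)
        accepted = metropolis_accept(loss - cur_loss, cfg.temperature, rng)
        if accepted:
            current, cur_loss, cur_res, cur_conf, cur_struct = (
                proposal, loss, res, conf, struct)
        if loss < best_loss:
            best_seq, best_loss, best_struct = proposal, loss, struct
        records.append(TrajectoryRecord(
            step=step, proposed_unit=proposal.unit, loss=loss,
            closure_score=res.closure_score, plddt=conf.plddt,
            accepted=accepted, best_so_far=best_loss))
    return records, best_seq, best_struct


@dataclass(frozen=True)
class FilterEntry:
    index: int
    rmsd_A: float
    plddt: float
    ptm: Optional[float]
    retained: bool


def filter_designs(pairs: Sequence[tuple[ProteinStructure, ProteinStructure,
                                         ConfidenceMetrics]],
                   rmsd_cutoff: float = 2.0
                   ) -> tuple[list[int], list[FilterEntry]]:
    """Retain design/prediction pairs whose superposed CA RMSD is at most
    the cutoff (default 2.0 A); returns retained indices and a per-design
    report."""
    from pseudocycle.compare_cluster import kabsch_rmsd

    retained: list[int] = []
    report: list[FilterEntry] = []
    for i, (design, predicted, conf) in enumerate(pairs):
        if len(design) != len(predicted):
            raise ValueError(
                f"pair {i}: length mismatch {len(design)} vs {len(predicted)}")
        rmsd = kabsch_rmsd(design.ca_coords(), predicted.ca_coords()).rmsd_A
        keep = rmsd <= rmsd_cutoff
        if keep:
            retained.append(i)
        report.append(FilterEntry(index=i, rmsd_A=rmsd, plddt=conf.plddt,
                                  ptm=conf.ptm, retained=keep))
    return retained, report
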