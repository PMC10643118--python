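"""Synthetic repeat-backbone generator with exactly known ground truth.

Builds ideal-geometry backbones from secondary-structure templates and
replicates one unit N times with a screw operation whose rotation and
rise are known by construction, so closure-scoring code can be tested
against exact targets.  Units are placed rigidly — there is no loop
closure between units; the chain-break geometry at unit boundaries is
tolerated because closure scoring uses only intra-unit residue frames.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from pseudocycle.structure_io import (
    BackboneResidue, ProteinStructure, RepeatSpec)
from pseudocycle.repeat_geometry import ScrewParams

# Ideal backbone internal coordinates (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

# (phi, psi) per secondary-structure state.
DIHEDRALS = {
    "H": (-57.0, -47.0),
    "E": (-120.0, 120.0),
    "L": (-80.0, 150.0),
}


@dataclass(frozen=True)
class CyclicBackboneSpec:
    """Recipe for a synthetic N-repeat backbone with known screw truth.

    ``inject_rise`` (Angstrom per unit) and ``inject_rotation`` (degrees
    added to the ideal 360/N) are the ground-truth closure deviations.
    """

    n_units: int
    unit_template: str
    ring_radius: float = 12.0
    inject_rise: float = 0.0
    inject_rotation: float = 0.0
    seed: int = 0
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not 2 <= self.n_units <= 7:
            raise ValueError(f"n_units {self.n_units} outside [2, 7]")
        L = len(self.unit_template)
        if not 15 <= L <= 78:
            raise ValueError(f"unit length {L} outside [15, 78]")
        if set(self.unit_template) - set("HEL"):
            raise ValueError(
                f"invalid template characters in {self.unit_template!r}")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")
        if self.sequence is not None and len(self.sequence) != L:
            raise ValueError("sequence length must match template length")

    @property
    def repeat_spec(self) -> RepeatSpec:
        return RepeatSpec(self.n_units, len(self.unit_template))


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float
                ) -> np.ndarray:
    """Place atom d bonded to c with angle b-c-d and torsion a-b-c-d
    (natural extension reference frame)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.cos(tor) * math.sin(ang),
                        bond * math.sin(tor) * math.sin(ang)])
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def build_unit(template: str, seed: int = 0, sequence: Optional[str] = None,
               jitter_deg: float = 3.0) -> ProteinStructure:
    """Build one ideal-geometry unit from an SS template over {H, E, L}.

    Helix residues use (phi, psi) = (-57, -47), strands (-120, 120),
    loops (-80, 150), each with small seeded uniform jitter (at most
    ``jitter_deg`` degrees) so repeated units are realistic but exactly
    reproducible under a fixed seed.
    """
    bad = set(template) - set("HEL")
    if bad:
        raise ValueError(f"invalid template characters: {sorted(bad)}")
    L = len(template)
    if sequence is None:
        sequence = "A" * L
    if len(sequence) != L:
        raise ValueError("sequence length must match template length")
    rng = np.random.default_rng(seed)
    phis, psis = [], []
    for ss in template:
        phi0, psi0 = DIHEDRALS[ss]
        phis.append(phi0 + rng.uniform(-jitter_deg, jitter_deg))
        psis.append(psi0 + rng.uniform(-jitter_deg, jitter_deg))

    # Seed the first residue explicitly, then extend by internal coordinates.
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords = [(n0, ca0, c0)]
    for i in range(1, L):
        n_prev, ca_prev, c_prev = coords[-1]
        n_i = _place_atom(n_prev, ca_prev, c_prev,
                          BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i,
                           BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place_atom(c_prev, n_i, ca_i,
                          BOND_CA_C, ANGLE_N_CA_C, phis[i])
        coords.append((n_i, ca_i, c_i))

    residues = []
    for i, (n_i, ca_i, c_i) in enumerate(coords):
        if i + 1 < L:
            next_n = coords[i + 1][0]
            o_i = _place_atom(next_n, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            o_i = _place_atom(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O,
                              psis[i] + 180.0)
        residues.append(BackboneResidue(
            index=i + 1, aa=sequence[i],
            n_xyz=n_i, ca_xyz=ca_i, c_xyz=c_i, o_xyz=o_i))
    return ProteinStructure(residues)


def build_cyclic(spec: CyclicBackboneSpec
                 ) -> tuple[ProteinStructure, ScrewParams]:
    """Assemble an N-repeat backbone by screw replication of one unit.

    The unit centroid is placed ``ring_radius`` Angstrom from the global z
    axis and copy i receives rotation i*(360/N + inject_rotation) about z
    plus translation i*inject_rise along z.  The ground-truth per-unit
    screw parameters are returned alongside the chain.
    """
    L = len(spec.unit_template)
    unit_seq = spec.sequence
    unit = build_unit(spec.unit_template, seed=spec.seed, sequence=unit_seq)
    centroid = unit.ca_coords().mean(axis=0)
    offset = np.array([spec.ring_radius, 0.0, 0.0]) - centroid
    unit = unit.transformed(np.eye(3), offset)

    angle = 360.0 / spec.n_units + spec.inject_rotation
    rot_step = Rotation.from_euler("z", angle, degrees=True).as_matrix()
    residues: list[BackboneResidue] = []
    R = np.eye(3)
    t = np.zeros(3)
    for i in range(spec.n_units):
        placed = unit.transformed(R, t)
        for j, res in enumerate(placed.residues):
            residues.append(BackboneResidue(
                index=i * L + j + 1, aa=res.aa, n_xyz=res.n_xyz,
                ca_xyz=res.ca_xyz, c_xyz=res.c_xyz, o_xyz=res.o_xyz))
        R = rot_step @ R
        t = rot_step @ t + np.array([0.0, 0.0, spec.inject_rise])

    canon_angle = angle if angle <= 180.0 else 360.0 - angle
    truth = ScrewParams(axis=np.array([0.0, 0.0, 1.0]),
                        angle_deg=canon_angle,
                        rise_A=abs(spec.inject_rise),
                        axis_point=np.zeros(3),
                        degenerate=canon_angle < 1.0)
    return ProteinStructure(residues), truth


@dataclass
class PseudoAtomSet:
    """A bare set of heavy-atom positions (pocket-detection fixture)."""

    coords: np.ndarray

    def heavy_atoms(self) -> np.ndarray:
        return self.coords


def build_hollow_shell(radius: float, atom_count: Optional[int] = None,
                       seed: int = 0) -> PseudoAtomSet:
    """Fibonacci-sphere shell of pseudo-atoms enclosing a known void.

    With the default atom count the surface spacing is ~1.5 A, well below
    the closing radius, so the interior void is watertight to the cavity
    detector.  A spacing above 2.5 A triggers a sparse-coverage warning.
    """
    if radius <= 3.0:
        raise ValueError("radius must exceed 3 A")
    if atom_count is None:
        atom_count = max(64, int(4.0 * math.pi * radius ** 2 / 1.5 ** 2))
    area_per_atom = 4.0 * math.pi * radius ** 2 / atom_count
    spacing = math.sqrt(area_per_atom)
    if spacing > 2.5:
        warnings.warn(
            f"sparse shell coverage: ~{spacing:.2f} A between atoms")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 1.0)  # seeded azimuthal phase
    golden = math.pi * (3.0 - math.sqrt(5.0))
    i = np.arange(atom_count)
    z = 1.0 - 2.0 * (i + 0.5) / atom_count
    r_xy = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = golden * i + 2.0 * math.pi * phase
    pts = radius * np.column_stack(
        [r_xy * np.cos(theta), r_xy * np.sin(theta), z])
    return PseudoAtomSet(coords=pts)
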