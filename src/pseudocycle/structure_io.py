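"""Protein structure and sequence I/O.

Backbone-centric PDB reading/writing and partitioning of a chain into
repeat units.  Coordinates are stored in Angstrom in a right-handed global
frame; residue indexing is 1-based and ranges are inclusive.  Only one
chain is processed per call; multi-chain files require an explicit chain
selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Raised for structurally invalid or empty inputs."""


@dataclass
class BackboneResidue:
    """One residue's backbone: N, CA, C (O and CB optional), in Angstrom."""

    index: int
    aa: str
    n_xyz: np.ndarray
    ca_xyz: np.ndarray
    c_xyz: np.ndarray
    o_xyz: Optional[np.ndarray] = None
    cb_xyz: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.n_xyz = np.asarray(self.n_xyz, dtype=float)
        self.ca_xyz = np.asarray(self.ca_xyz, dtype=float)
        self.c_xyz = np.asarray(self.c_xyz, dtype=float)
        if self.o_xyz is not None:
            self.o_xyz = np.asarray(self.o_xyz, dtype=float)
        if self.cb_xyz is not None:
            self.cb_xyz = np.asarray(self.cb_xyz, dtype=float)

    def validate(self) -> None:
        """Check finiteness, distinctness, and backbone bond-length sanity."""
        pts = [self.n_xyz, self.ca_xyz, self.c_xyz]
        if not all(np.all(np.isfinite(p)) for p in pts):
            raise StructureError(f"residue {self.index}: non-finite coordinates")
        if (np.allclose(self.n_xyz, self.ca_xyz)
                or np.allclose(self.ca_xyz, self.c_xyz)
                or np.allclose(self.n_xyz, self.c_xyz)):
            raise StructureError(f"residue {self.index}: coincident backbone atoms")
        for name, d in (("N-CA", np.linalg.norm(self.n_xyz - self.ca_xyz)),
                        ("CA-C", np.linalg.norm(self.ca_xyz - self.c_xyz))):
            if not 1.0 <= d <= 2.5:
                raise StructureError(
                    f"residue {self.index}: {name} bond length {d:.2f} A "
                    "outside [1.0, 2.5] A")

    def heavy_atoms(self) -> np.ndarray:
        """All stored heavy-atom coordinates, shape (k, 3)."""
        pts = [self.n_xyz, self.ca_xyz, self.c_xyz]
        if self.o_xyz is not None:
            pts.append(self.o_xyz)
        if self.cb_xyz is not None:
            pts.append(self.cb_xyz)
        return np.asarray(pts)


@dataclass
class ProteinStructure:
    """An ordered single-chain backbone model."""

    residues: list[BackboneResidue] = field(default_factory=list)
    chain_id: str = "A"

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """CA coordinates, shape (len, 3)."""
        return np.asarray([r.ca_xyz for r in self.residues])

    def heavy_atoms(self) -> np.ndarray:
        """All heavy-atom coordinates, shape (n_atoms, 3)."""
        if not self.residues:
            return np.empty((0, 3))
        return np.vstack([r.heavy_atoms() for r in self.residues])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "ProteinStructure":
        """A copy with `x -> R x + t` applied to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)

        def mv(p: Optional[np.ndarray]) -> Optional[np.ndarray]:
            return None if p is None else R @ p + t

        res = [BackboneResidue(r.index, r.aa, mv(r.n_xyz), mv(r.ca_xyz),
                               mv(r.c_xyz), mv(r.o_xyz), mv(r.cb_xyz))
               for r in self.residues]
        return ProteinStructure(res, self.chain_id)

    def validate(self) -> None:
        for r in self.residues:
            r.validate()


@dataclass(frozen=True)
class RepeatSpec:
    """Repeat architecture: N units of L residues each.

    Default bounds follow the design campaign's search space: N in [2, 7],
    L in [15, 78], total length at most 156 residues.
    """

    n_units: int
    unit_length: int
    n_bounds: tuple[int, int] = (2, 7)
    l_bounds: tuple[int, int] = (15, 78)
    max_length: int = 156

    def __post_init__(self) -> None:
        lo_n, hi_n = self.n_bounds
        lo_l, hi_l = self.l_bounds
        if not lo_n <= self.n_units <= hi_n:
            raise ValueError(f"n_units {self.n_units} outside [{lo_n}, {hi_n}]")
        if not lo_l <= self.unit_length <= hi_l:
            raise ValueError(
                f"unit_length {self.unit_length} outside [{lo_l}, {hi_l}]")
        if self.n_units * self.unit_length > self.max_length:
            raise ValueError(
                f"total length {self.n_units * self.unit_length} exceeds "
                f"{self.max_length}")

    @property
    def total_length(self) -> int:
        return self.n_units * self.unit_length

    @property
    def ideal_rotation_deg(self) -> float:
        """Per-unit rotation of a perfectly closed cycle: 360/N degrees."""
        return 360.0 / self.n_units


_BACKBONE_ORDER = ("N", "CA", "C", "O", "CB")


def read_pdb(path: str | Path, chain: Optional[str] = None) -> ProteinStructure:
    """Read a single protein chain's backbone from a PDB file.

    Residues missing any of N/CA/C are dropped with a warning; non-standard
    residues are dropped with a warning; only the first altloc is kept;
    insertion codes are rejected.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
    except OSError:
        raise
    except Exception as exc:  # malformed content
        raise OSError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms = pdb.get_structure(model=1, altloc="first", extra_fields=["b_factor"])
    atoms = atoms[bst.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise StructureError(f"{path}: no protein residues found")

    chains = np.unique(atoms.chain_id).tolist()
    if chain is None:
        if len(chains) > 1:
            raise StructureError(
                f"{path}: multiple chains {chains}; select one with `chain`")
        chain = chains[0]
    elif chain not in chains:
        raise StructureError(f"{path}: chain {chain!r} not found (have {chains})")
    atoms = atoms[atoms.chain_id == chain]
    if np.any(atoms.ins_code != ""):
        raise StructureError(f"{path}: insertion codes are not supported")

    residues: list[BackboneResidue] = []
    for start in bst.get_residue_starts(atoms):
        res_id = int(atoms.res_id[start])
        res_name = str(atoms.res_name[start])
        sel = atoms[(atoms.res_id == res_id)]
        if res_name not in THREE_TO_ONE:
            warnings.warn(f"dropping non-standard residue {res_name} {res_id}")
            continue
        coords = {}
        for name in _BACKBONE_ORDER:
            hit = sel[sel.atom_name == name]
            if hit.array_length():
                coords[name] = np.array(hit.coord[0], dtype=float)
        if not all(k in coords for k in ("N", "CA", "C")):
            warnings.warn(
                f"dropping residue {res_name} {res_id}: incomplete backbone")
            continue
        residues.append(BackboneResidue(
            index=res_id, aa=THREE_TO_ONE[res_name],
            n_xyz=coords["N"], ca_xyz=coords["CA"], c_xyz=coords["C"],
            o_xyz=coords.get("O"), cb_xyz=coords.get("CB")))
    return ProteinStructure(residues, chain_id=str(chain))


def _to_atom_array(structure: ProteinStructure) -> bst.AtomArray:
    rows = []
    for res in structure.residues:
        named = [("N", res.n_xyz, "N"), ("CA", res.ca_xyz, "C"),
                 ("C", res.c_xyz, "C")]
        if res.o_xyz is not None:
            named.append(("O", res.o_xyz, "O"))
        if res.cb_xyz is not None:
            named.append(("CB", res.cb_xyz, "C"))
        for atom_name, xyz, element in named:
            rows.append((res.index, res.aa, atom_name, xyz, element))
    arr = bst.AtomArray(len(rows))
    arr.coord = np.asarray([r[3] for r in rows], dtype=np.float32)
    arr.chain_id = np.full(len(rows), structure.chain_id)
    arr.res_id = np.asarray([r[0] for r in rows], dtype=int)
    arr.res_name = np.asarray([ONE_TO_THREE[r[1]] for r in rows])
    arr.atom_name = np.asarray([r[2] for r in rows])
    arr.element = np.asarray([r[4] for r in rows])
    arr.hetero = np.zeros(len(rows), dtype=bool)
    arr.set_annotation("occupancy", np.ones(len(rows)))
    arr.set_annotation("b_factor", np.zeros(len(rows)))
    return arr


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a backbone model as standard ATOM records (occupancy 1.00)."""
    if len(structure) == 0:
        raise StructureError("cannot write an empty structure")
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    pdb.write(str(Path(path)))


def split_repeats(structure: ProteinStructure, spec: RepeatSpec
                  ) -> list[tuple[int, int]]:
    """Partition the chain into N contiguous unit ranges of length L.

    Ranges are 1-based inclusive positions into the residue list (not author
    residue numbers).
    """
    n, L = spec.n_units, spec.unit_length
    if len(structure) != n * L:
        raise StructureError(
            f"length mismatch: expected N*L = {n}*{L} = {n * L} residues, "
            f"got {len(structure)}")
    return [(i * L + 1, (i + 1) * L) for i in range(n)]
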