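"""Central-pocket annotation by grid-based cavity detection.

The structure is reduced to polyalanine (backbone + CB), voxelized on a
regular grid, and the largest internal cavity is found by a two-stage
procedure: morphological closing of the protein mask seals the mouths of
solvent-open channels, then a flood fill from the grid border labels the
exterior; cavity voxels are those empty in the original mask but
unreachable from outside.  Residues lining the cavity are reported as the
pocket contacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from pseudocycle.structure_io import BackboneResidue, ProteinStructure

DEFAULT_SPACING = 1.0      # A per voxel
DEFAULT_ATOM_RADIUS = 1.8  # uniform heavy-atom radius, A
DEFAULT_PROBE = 1.4        # water probe, A
DEFAULT_CLOSE_RADIUS = 4.0  # morphological closing ball, A
DEFAULT_CONTACT_CUTOFF = 4.5  # pocket-lining residue cutoff, A
DEFAULT_MIN_VOLUME = 5.0   # smallest cavity worth reporting, A^3

# Voxel labels.
EMPTY, PROTEIN, EXTERIOR, CAVITY = 0, 1, 2, 3

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class OccupancyGrid:
    """Labelled voxel grid enclosing the structure plus a guaranteed-
    exterior border margin."""

    spacing: float
    origin: np.ndarray
    labels: np.ndarray  # int array over {EMPTY, PROTEIN, EXTERIOR, CAVITY}

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian centers of voxels given as an (n, 3) index array."""
        return self.origin + (np.asarray(indices) + 0.5) * self.spacing


@dataclass
class Pocket:
    """The largest internal cavity: voxel set, volume, lining residues."""

    voxels: np.ndarray  # (n, 3) voxel indices
    volume_A3: float
    contact_residues: list[int]

    @property
    def is_empty(self) -> bool:
        return len(self.voxels) == 0


# Ideal CB placement coefficients in the (b, c, b x c) frame with
# b = CA - N, c = C - CA; yields |CA-CB| ~ 1.52 A at tetrahedral geometry.
_CB_COEF = (-0.58273431, 0.56802827, -0.54067466)


def ideal_cb(n_xyz: np.ndarray, ca_xyz: np.ndarray, c_xyz: np.ndarray
             ) -> np.ndarray:
    """CB position at ideal tetrahedral geometry from backbone N/CA/C."""
    b = ca_xyz - n_xyz
    c = c_xyz - ca_xyz
    a = np.cross(b, c)
    ka, kb, kc = _CB_COEF
    return ka * a + kb * b + kc * c + ca_xyz


def to_polyalanine(structure: ProteinStructure) -> ProteinStructure:
    """Reduce to polyalanine: every residue becomes Ala with only backbone
    atoms plus CB; a missing CB (e.g. glycine) is constructed at ideal
    tetrahedral geometry.  Idempotent."""
    residues = []
    for res in structure.residues:
        cb = res.cb_xyz if res.cb_xyz is not None else ideal_cb(
            res.n_xyz, res.ca_xyz, res.c_xyz)
        residues.append(BackboneResidue(
            index=res.index, aa="A", n_xyz=res.n_xyz, ca_xyz=res.ca_xyz,
            c_xyz=res.c_xyz, o_xyz=res.o_xyz, cb_xyz=cb))
    return ProteinStructure(residues, structure.chain_id)


def _heavy_atoms(structure) -> np.ndarray:
    if hasattr(structure, "heavy_atoms"):
        return np.asarray(structure.heavy_atoms(), dtype=float)
    return np.asarray(structure, dtype=float)


def _ball(radius_voxels: float) -> np.ndarray:
    r = int(np.ceil(radius_voxels))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    return dx * dx + dy * dy + dz * dz <= radius_voxels ** 2


def detect_largest_cavity(structure,
                          spacing: float = DEFAULT_SPACING,
                          close_radius: float = DEFAULT_CLOSE_RADIUS,
                          probe: float = DEFAULT_PROBE,
                          atom_radius: float = DEFAULT_ATOM_RADIUS,
                          min_volume: float = DEFAULT_MIN_VOLUME,
                          ) -> tuple[OccupancyGrid, Pocket]:
    """Find the largest internal cavity of a (polyalanine) structure.

    Accepts a ProteinStructure (converted to polyalanine internally), any
    object with a ``heavy_atoms()`` method, or a bare (n, 3) coordinate
    array.  Returns the labelled grid and the largest cavity component
    (26-connectivity); an empty Pocket, not an error, when no cavity
    exists.

    Components smaller than ``min_volume`` (cubic Angstrom) are discarded:
    the closing step inevitably traps single-voxel dimples on the molecular
    surface, and no physically meaningful pocket is that small.
    """
    if isinstance(structure, ProteinStructure):
        structure = to_polyalanine(structure)
    atoms = _heavy_atoms(structure)
    if atoms.size == 0:
        raise ValueError("no heavy atoms to grid")

    margin = 2 * spacing + atom_radius + probe
    lo = atoms.min(axis=0) - margin
    hi = atoms.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    idx = np.indices(shape).reshape(3, -1).T
    centers = lo + (idx + 0.5) * spacing

    tree = cKDTree(atoms)
    dist, _ = tree.query(centers, k=1)
    protein = (dist <= atom_radius + probe).reshape(shape)

    closed = ndimage.binary_closing(
        protein, structure=_ball(close_radius / spacing))

    # exterior = non-protein voxels of the closed mask reachable from border
    open_space = ~closed
    lab, n_lab = ndimage.label(open_space, structure=_CONN26)
    border_labels = np.unique(np.concatenate([
        lab[0].ravel(), lab[-1].ravel(),
        lab[:, 0].ravel(), lab[:, -1].ravel(),
        lab[:, :, 0].ravel(), lab[:, :, -1].ravel()]))
    border_labels = border_labels[border_labels > 0]
    exterior = np.isin(lab, border_labels)

    cavity_mask = (~protein) & (~exterior)
    labels = np.full(shape, EMPTY, dtype=np.int8)
    labels[protein] = PROTEIN
    labels[exterior & ~protein] = EXTERIOR

    grid = OccupancyGrid(spacing=spacing, origin=lo, labels=labels)
    if not cavity_mask.any():
        return grid, Pocket(np.empty((0, 3), dtype=int), 0.0, [])

    clab, n_comp = ndimage.label(cavity_mask, structure=_CONN26)
    sizes = ndimage.sum_labels(cavity_mask, clab, index=np.arange(1, n_comp + 1))
    best_size = sizes.max()
    if best_size * spacing ** 3 < min_volume:
        return grid, Pocket(np.empty((0, 3), dtype=int), 0.0, [])
    # tie-break on lowest minimum flat voxel index for determinism
    candidates = np.flatnonzero(sizes == best_size) + 1
    if len(candidates) > 1:
        flat = clab.ravel()
        best = min(candidates,
                   key=lambda c: int(np.flatnonzero(flat == c)[0]))
    else:
        best = int(candidates[0])
    voxels = np.argwhere(clab == best)
    labels[tuple(voxels.T)] = CAVITY
    volume = float(len(voxels)) * spacing ** 3
    pocket = Pocket(voxels=voxels, volume_A3=volume, contact_residues=[])
    if isinstance(structure, ProteinStructure):
        pocket.contact_residues = pocket_residues(structure, grid, pocket)
    return grid, pocket


def pocket_residues(structure: ProteinStructure, grid: OccupancyGrid,
                    pocket: Pocket,
                    cutoff: float = DEFAULT_CONTACT_CUTOFF) -> list[int]:
    """Residue indices with any heavy atom within ``cutoff`` Angstrom of a
    cavity voxel center, sorted ascending."""
    if pocket.is_empty or cutoff <= 0:
        return []
    centers = grid.voxel_centers(pocket.voxels)
    tree = cKDTree(centers)
    out = []
    for res in structure.residues:
        d, _ = tree.query(res.heavy_atoms(), k=1)
        if np.min(d) <= cutoff:
            out.append(res.index)
    return sorted(out)
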