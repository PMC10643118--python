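"""Shared fixtures: synthetic scaffolds and perturbation helpers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pseudocycle.structure_io import BackboneResidue, ProteinStructure
from pseudocycle.synthetic_backbones import CyclicBackboneSpec, build_cyclic

# Ten mutually distinct length-100 scaffold recipes (n_units, template,
# ring radius); all pairwise averaged TM scores are below the 0.45
# singleton threshold (verified in the comparison tests).
DISTINCT_RECIPES = [
    (5, "H" * 20, 10.0),
    (5, "E" * 16 + "L" * 4, 9.0),
    (5, "H" * 8 + "L" * 4 + "E" * 5 + "L" * 3, 11.0),
    (4, "H" * 25, 12.0),
    (4, "E" * 10 + "L" * 5 + "E" * 10, 8.0),
    (2, "H" * 22 + "L" * 6 + "H" * 22, 14.0),
    (5, "E" * 7 + "L" * 3 + "H" * 7 + "L" * 3, 8.0),
    (4, "H" * 10 + "L" * 5 + "H" * 10, 13.0),
    (2, "E" * 20 + "L" * 10 + "E" * 20, 10.0),
    (5, "L" * 3 + "H" * 14 + "L" * 3, 12.0),
]


def perturb(structure: ProteinStructure, sd: float, seed: int
            ) -> ProteinStructure:
    """Add iid Gaussian noise (sd per coordinate, Angstrom) to all atoms."""
    rng = np.random.default_rng(seed)

    def jig(p):
        return None if p is None else p + rng.normal(0.0, sd, 3)

    return ProteinStructure(
        [BackboneResidue(r.index, r.aa, jig(r.n_xyz), jig(r.ca_xyz),
                         jig(r.c_xyz), jig(r.o_xyz), jig(r.cb_xyz))
         for r in structure.residues],
        structure.chain_id)


def rigid_move(structure: ProteinStructure, seed: int) -> ProteinStructure:
    """Apply a random global rigid motion."""
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=seed).as_matrix()
    t = rng.normal(0.0, 15.0, 3)
    return structure.transformed(R, t)


@pytest.fixture(scope="session")
def base_scaffolds() -> list[ProteinStructure]:
    """The ten distinct length-100 base scaffolds."""
    return [build_cyclic(CyclicBackboneSpec(n, t, ring_radius=r, seed=i))[0]
            for i, (n, t, r) in enumerate(DISTINCT_RECIPES)]


@pytest.fixture(scope="session")
def c5_backbone() -> ProteinStructure:
    """A perfect C5 backbone, 5 x 20 helical residues."""
    structure, _ = build_cyclic(CyclicBackboneSpec(5, "H" * 20))
    return structure
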