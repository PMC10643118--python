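"""Screw-axis geometry of repeat proteins.

Per-residue coordinate frames are built from backbone N/CA/C atoms; the
rigid transform mapping one repeat unit onto the next is estimated by
quaternion-averaging the per-residue relative transforms; its screw
decomposition yields the per-unit rotation about and rise along the
helical (symmetry) axis.  A perfectly closed C_N backbone has rotation
360/N degrees and rise 0.

All transforms are expressed as global-frame (left-action) motions
``x -> R x + t``, so for an exactly symmetric structure every matched
residue pair yields the identical transform and averaging is well-posed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from pseudocycle.structure_io import (
    BackboneResidue, ProteinStructure, RepeatSpec, StructureError)

if TYPE_CHECKING:
    from pseudocycle.closure_scoring import ClosureDeltas

DEGENERACY_ANGLE_DEG = 1.0


class GeometryError(ValueError):
    """Raised for degenerate geometric inputs."""


@dataclass
class Frame:
    """A local coordinate frame: origin plus right-handed orthonormal basis.

    ``basis`` holds the basis vectors as columns.
    """

    origin: np.ndarray
    basis: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        if not np.allclose(self.basis @ self.basis.T, np.eye(3), atol=1e-9):
            raise GeometryError("frame basis is not orthonormal")
        if not math.isclose(float(np.linalg.det(self.basis)), 1.0, abs_tol=1e-9):
            raise GeometryError("frame basis is not right-handed")


@dataclass
class RigidTransform:
    """A global-frame rigid motion stored as unit quaternion + translation.

    Quaternion convention is scalar-first (w, x, y, z) with canonical sign
    w >= 0.
    """

    quat: np.ndarray
    trans: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.quat, dtype=float)
        norm = np.linalg.norm(q)
        if abs(norm - 1.0) > 1e-9:
            if norm < 1e-12:
                raise GeometryError("zero quaternion")
            q = q / norm
        if q[0] < 0:
            q = -q
        self.quat = q
        self.trans = np.asarray(self.trans, dtype=float)

    @classmethod
    def from_matrix(cls, rotation: np.ndarray, translation: np.ndarray
                    ) -> "RigidTransform":
        q_xyzw = Rotation.from_matrix(rotation).as_quat()
        return cls(np.r_[q_xyzw[3], q_xyzw[:3]], translation)

    @property
    def rotation_matrix(self) -> np.ndarray:
        w, x, y, z = self.quat
        return Rotation.from_quat([x, y, z, w]).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation_matrix.T + self.trans

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> R_self (R_other x + t_other) + t_self."""
        R1, R2 = self.rotation_matrix, other.rotation_matrix
        return RigidTransform.from_matrix(
            R1 @ R2, R1 @ other.trans + self.trans)

    def inverse(self) -> "RigidTransform":
        R = self.rotation_matrix
        return RigidTransform.from_matrix(R.T, -R.T @ self.trans)


@dataclass
class ScrewParams:
    """Screw (helical) invariants of a rigid transform.

    ``angle_deg`` is the rotation about the screw axis in (0, 180];
    ``rise_A`` the absolute translation along it in Angstrom;
    ``axis_point`` a point the axis passes through.  ``degenerate`` marks
    near-zero rotation, where the axis is undefined and the rise is
    reported as the full translation norm.
    """

    axis: np.ndarray
    angle_deg: float
    rise_A: float
    axis_point: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        if self.rise_A < 0:
            raise GeometryError("rise must be non-negative")
        if not self.degenerate:
            if not math.isclose(float(np.linalg.norm(self.axis)), 1.0,
                                abs_tol=1e-6):
                raise GeometryError("screw axis must be a unit vector")
            if not 0.0 < self.angle_deg <= 180.0 + 1e-9:
                raise GeometryError(
                    f"angle {self.angle_deg} outside (0, 180] degrees")


def residue_frame(res: BackboneResidue) -> Frame:
    """Local frame from backbone atoms: origin at CA, x along CA->C,
    z along (C-CA) x (N-CA), y completing the right-handed triad."""
    ca, c, n = res.ca_xyz, res.c_xyz, res.n_xyz
    x = c - ca
    nx = np.linalg.norm(x)
    z = np.cross(x, n - ca)
    nz = np.linalg.norm(z)
    if nx < 1e-6 or nz < 1e-6:
        raise GeometryError(
            f"residue {res.index}: collinear or coincident backbone atoms")
    x = x / nx
    z = z / nz
    y = np.cross(z, x)
    return Frame(origin=ca, basis=np.column_stack([x, y, z]))


def relative_transform(src: Frame, dst: Frame) -> RigidTransform:
    """The global-frame motion carrying src's placement onto dst's.

    R = B_dst B_src^T and t = o_dst - R o_src, so applying the result to
    src's origin/basis reproduces dst exactly.
    """
    R = dst.basis @ src.basis.T
    t = dst.origin - R @ src.origin
    return RigidTransform.from_matrix(R, t)


def average_transforms(transforms: Sequence[RigidTransform]) -> RigidTransform:
    """Average rigid transforms: sign-aligned arithmetic quaternion mean
    (renormalized) plus arithmetic mean translation.

    Quaternions are sign-aligned to the first element before averaging;
    a spread above 90 degrees triggers a warning because the chordal mean
    then poorly represents the set.
    """
    if len(transforms) == 0:
        raise ValueError("cannot average an empty list of transforms")
    quats = np.array([t.quat for t in transforms], dtype=float)
    ref = quats[0]
    dots = quats @ ref
    quats[dots < 0] *= -1.0
    if np.any(np.abs(quats @ ref) < math.cos(math.radians(45.0))):
        warnings.warn("quaternion spread exceeds 90 degrees; "
                      "average may be ill-conditioned")
    mean_q = quats.mean(axis=0)
    norm = np.linalg.norm(mean_q)
    if norm < 1e-6:
        raise GeometryError("ambiguous quaternion average (mean norm ~ 0)")
    mean_t = np.mean([t.trans for t in transforms], axis=0)
    return RigidTransform(mean_q / norm, mean_t)


def average_transforms_eigen(transforms: Sequence[RigidTransform]
                             ) -> RigidTransform:
    """Quaternion average via the eigen-decomposition (Markley) method.

    Serves as an independent cross-check of :func:`average_transforms`;
    both agree closely for tightly clustered rotations.
    """
    if len(transforms) == 0:
        raise ValueError("cannot average an empty list of transforms")
    quats = np.array([t.quat for t in transforms], dtype=float)
    M = quats.T @ quats
    eigval, eigvec = np.linalg.eigh(M)
    q = eigvec[:, -1]
    mean_t = np.mean([t.trans for t in transforms], axis=0)
    return RigidTransform(q, mean_t)


def screw_decompose(M: RigidTransform) -> ScrewParams:
    """Decompose a rigid transform into its screw invariants.

    The rotation angle comes from the quaternion scalar part
    (theta = 2 arccos w, in [0, 180] under the canonical sign), the axis
    from the vector part.  The rise is the absolute translation component
    along the axis; the axis point solves the in-plane fixed-point
    equation (I - R) p = t_perp.  Rotations below 1 degree are flagged
    degenerate: the axis is undefined and the rise reported as ||t||.
    """
    w = float(np.clip(M.quat[0], -1.0, 1.0))
    v = M.quat[1:]
    angle_deg = math.degrees(2.0 * math.acos(w))
    t = M.trans
    if angle_deg < DEGENERACY_ANGLE_DEG:
        return ScrewParams(axis=np.zeros(3), angle_deg=angle_deg,
                           rise_A=float(np.linalg.norm(t)),
                           axis_point=np.zeros(3), degenerate=True)
    axis = v / np.linalg.norm(v)
    rise = abs(float(t @ axis))
    t_perp = t - (t @ axis) * axis
    R = M.rotation_matrix
    # (I - R) is singular along the axis; the perpendicular component of t
    # lies in its range, so least squares gives an exact in-plane solution.
    p, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    p = p - (p @ axis) * axis
    return ScrewParams(axis=axis, angle_deg=angle_deg, rise_A=rise,
                       axis_point=p, degenerate=False)


def screw_compose(axis: np.ndarray, angle_deg: float, rise_A: float,
                  axis_point: Optional[np.ndarray] = None) -> RigidTransform:
    """Build the rigid transform of a screw motion (inverse of
    :func:`screw_decompose`): rotation by angle about an axis through
    axis_point, plus translation rise along the axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if axis_point is None:
        axis_point = np.zeros(3)
    axis_point = np.asarray(axis_point, dtype=float)
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    t = axis_point - R @ axis_point + rise_A * axis
    return RigidTransform.from_matrix(R, t)


def repeat_screw(structure: ProteinStructure, spec: RepeatSpec
                 ) -> tuple[ScrewParams, "ClosureDeltas"]:
    """Estimate the per-unit screw transform of an N-repeat backbone and
    its deviation from ideal cyclic closure.

    For every matched residue pair (residue k of unit i -> residue k of
    unit i+1) the relative transform of the local frames is computed; all
    (N-1)*L transforms are pooled into one quaternion average, which is
    screw-decomposed.  The returned deltas are |rise - 0| and
    |angle - 360/N|.
    """
    from pseudocycle.closure_scoring import ClosureDeltas

    n, L = spec.n_units, spec.unit_length
    if len(structure) != n * L:
        raise StructureError(
            f"length mismatch: expected {n * L} residues, got {len(structure)}")
    frames = [residue_frame(r) for r in structure.residues]
    transforms = [
        relative_transform(frames[i * L + k], frames[(i + 1) * L + k])
        for i in range(n - 1) for k in range(L)
    ]
    mean = average_transforms(transforms)
    screw = screw_decompose(mean)
    if screw.degenerate:
        delta_rot = abs(spec.ideal_rotation_deg - screw.angle_deg)
        delta_rise = screw.rise_A  # already ||t|| in the degenerate branch
    else:
        delta_rot = abs(screw.angle_deg - spec.ideal_rotation_deg)
        delta_rise = screw.rise_A
    return screw, ClosureDeltas(delta_rise_A=delta_rise,
                                delta_rotation_deg=delta_rot)
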