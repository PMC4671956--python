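"""Euclidean primitives for pocket-geometry analysis.

Distances, bond/σ-hole angles, IUPAC dihedrals, rigid (Kabsch) superposition,
per-residue displacement profiles, and internal-to-Cartesian atom placement.
All angles cross this module's boundary in degrees; radians never do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "DegenerateGeometryError",
    "SuperpositionError",
    "RigidTransform",
    "distance",
    "angle",
    "dihedral",
    "kabsch_superpose",
    "displacement_profile",
    "place_atom",
]

# sin(theta) below this marks a triple as colinear
_COLINEAR_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    """Raised when points are too close or colinear for the requested measure."""


class SuperpositionError(ValueError):
    """Raised when a point set cannot support a rigid superposition."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body motion x -> rotation @ x + translation."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector, Angstrom

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        trans = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or trans.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(rot) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to one point or an N x 3 array of points."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _vec(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("coordinates must be finite")
    return v


def distance(a, b) -> float:
    """Euclidean distance |a - b| in Angstrom."""
    return float(np.linalg.norm(_vec(a) - _vec(b)))


def angle(a, b, c) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    u = _vec(a) - _vec(b)
    v = _vec(c) - _vec(b)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _COLINEAR_TOL or nv < _COLINEAR_TOL:
        raise DegenerateGeometryError("zero-length arm in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(a, b, c, d) -> float:
    """Torsion angle of the chain a-b-c-d, degrees in (-180, 180].

    IUPAC sign convention: looking from b to c, the angle is positive when
    d is rotated clockwise from a (right-handed about b->c); cis = 0.
    """
    b0 = _vec(a) - _vec(b)
    b1 = _vec(c) - _vec(b)
    b2 = _vec(d) - _vec(c)
    nb1 = np.linalg.norm(b1)
    if nb1 < _COLINEAR_TOL:
        raise DegenerateGeometryError("central atoms b and c coincide")
    b1u = b1 / nb1
    # components of b0/b2 perpendicular to the central bond
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < _COLINEAR_TOL or np.linalg.norm(w) < _COLINEAR_TOL:
        raise DegenerateGeometryError("colinear atom triple in dihedral")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    # atan2 yields [-180, 180]; fold -180 onto +180 for the half-open range
    if ang <= -180.0:
        ang = 180.0
    return ang


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal proper rigid superposition of mobile onto reference.

    Returns the transform and the attained RMSD (Angstrom). Requires N >= 3
    non-colinear matched points.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise SuperpositionError("mobile and reference must be matched N x 3 arrays")
    n = mob.shape[0]
    if n < 3:
        raise SuperpositionError("need at least 3 points for superposition")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # reject colinear sets: rank of the centered cloud must be >= 2
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (colinear) point set")
    rot_obj, _ = Rotation.align_vectors(ref_c, mob_c)
    rot = rot_obj.as_matrix()
    translation = ref.mean(axis=0) - rot @ mob.mean(axis=0)
    transform = RigidTransform(rot, translation)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(mob) - ref) ** 2, axis=1))))
    return transform, rmsd


def displacement_profile(model_a, model_b, fit_selection, report_selection) -> dict:
    """Per-residue maximum backbone displacement of model_a relative to model_b.

    model_a is superposed onto model_b on the Calpha atoms of ``fit_selection``
    (a sequence of (chain_id, res_seq)); for each residue of
    ``report_selection`` the maximum post-fit displacement over the backbone
    atoms N, CA, C, O is returned, keyed by (chain_id, res_seq).
    """
    from .structio import get_atom  # local import to avoid a cycle

    fit_mob = np.array([get_atom(model_a, ch, rs, "CA").coords for ch, rs in fit_selection])
    fit_ref = np.array([get_atom(model_b, ch, rs, "CA").coords for ch, rs in fit_selection])
    transform, _ = kabsch_superpose(fit_mob, fit_ref)

    backbone = ("N", "CA", "C", "O")
    profile: dict[tuple[str, int], float] = {}
    for ch, rs in report_selection:
        disps = []
        for name in backbone:
            xa = transform.apply(get_atom(model_a, ch, rs, name).coords)
            xb = np.asarray(get_atom(model_b, ch, rs, name).coords, dtype=float)
            disps.append(float(np.linalg.norm(xa - xb)))
        profile[(ch, rs)] = max(disps)
    return profile


def place_atom(a, b, c, bond_length: float, bond_angle: float, dihedral_angle: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to the frame a-b-c.

    The returned point satisfies distance(c, d) = bond_length,
    angle(b, c, d) = bond_angle and dihedral(a, b, c, d) = dihedral_angle
    (degrees). Standard natural-extension (NeRF) construction.
    """
    a, b, c = _vec(a), _vec(b), _vec(c)
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    if not 0.0 < bond_angle < 180.0:
        raise ValueError("bond_angle must lie in (0, 180) degrees")
    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    if nbc < _COLINEAR_TOL or np.linalg.norm(ab) < _COLINEAR_TOL:
        raise DegenerateGeometryError("degenerate reference frame")
    bc_u = bc / nbc
    n = np.cross(ab, bc_u)
    nn = np.linalg.norm(n)
    if nn < _COLINEAR_TOL:
        raise DegenerateGeometryError("reference atoms a, b, c are colinear")
    n_u = n / nn
    m_u = np.cross(n_u, bc_u)

    theta = np.radians(bond_angle)
    phi = np.radians(dihedral_angle)
    # local displacement: along -bc for the supplement of the bond angle
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    frame = np.column_stack([bc_u, m_u, n_u])
    return c + frame @ d_local
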