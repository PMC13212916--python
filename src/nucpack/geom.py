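"""Torsion-based descriptors of nucleotide conformation.

This module computes the five endocyclic torsions of the furanose ring
(nu0..nu4), the pseudorotation phase angle P and amplitude tau_m of the
sugar pucker, the glycosidic torsion chi, and the 2'/3'-endo-like pucker
class used to key the pucker-dependent rotamer library.

Conventions
-----------
* Raw dihedrals follow the IUPAC right-hand sign convention and live in
  (-180, 180].
* chi and P are reported in [0, 360), the domain on which the chi-angle
  mixture models are fitted.
* The pseudorotation phase follows the Altona-Sundaralingam formalism:
  ``tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72))``
  with 180 deg added whenever nu2 < 0, so that mirror-related twist
  conformers map to distinct phases and P covers the full circle.
"""

from __future__ import annotations

import enum
import math
from typing import TYPE_CHECKING, NamedTuple, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .structure import Residue

__all__ = [
    "GeometryError",
    "PuckerClass",
    "TorsionSet",
    "PuckerState",
    "dihedral",
    "endocyclic_torsions",
    "pseudorotation_phase",
    "pucker_amplitude",
    "pucker_state",
    "chi_angle",
    "classify_pucker",
    "circular_difference",
    "superpose",
    "rotation_about_axis",
    "RING_ATOMS",
    "NU_QUADRUPLES",
]


class GeometryError(ValueError):
    """Raised for degenerate or incomplete geometry."""


class PuckerClass(enum.Enum):
    """Coarse sugar-pucker class derived from the phase angle P."""

    ENDO2 = "2'-endo-like"
    ENDO3 = "3'-endo-like"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class TorsionSet(NamedTuple):
    """The five endocyclic furanose torsions, degrees in (-180, 180]."""

    nu0: float
    nu1: float
    nu2: float
    nu3: float
    nu4: float


class PuckerState(NamedTuple):
    """Full pucker descriptor of one sugar."""

    P: float
    tau_m: float
    pucker_class: PuckerClass
    torsions: TorsionSet


#: Furanose ring atoms every nucleotide must expose.
RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")

#: Atom quadruples defining nu0..nu4 (standard furanose convention).
NU_QUADRUPLES = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)

# 2 * (sin 36 + sin 72) -- denominator constant of the phase formula
_PHASE_DENOM = 2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, degrees in (-180, 180].

    The sign follows the right-hand (IUPAC) convention: looking from
    ``p2`` to ``p3``, a clockwise rotation of the far bond is positive.

    Raises
    ------
    GeometryError
        If any of the three bond vectors is (near) zero length or the
        construction is collinear, leaving the torsion undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-9:
            raise GeometryError("zero-length bond vector in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear atoms: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _wrap360(angle: float) -> float:
    """Map an angle in degrees onto [0, 360)."""
    a = angle % 360.0
    return a if a < 360.0 else 0.0


def circular_difference(a: float, b: float) -> float:
    """Minimal absolute circular difference of two angles, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def endocyclic_torsions(res: "Residue") -> TorsionSet:
    """Measure nu0..nu4 of the furanose ring of one nucleotide.

    Raises
    ------
    GeometryError
        If a ring atom is missing; the message names residue and atom.
    """
    for name in RING_ATOMS:
        if name not in res.atoms:
            raise GeometryError(
                f"residue {res.chain_id}/{res.seq_id} ({res.name}) lacks ring atom {name}"
            )
    pos = {name: res.atoms[name].position for name in RING_ATOMS}
    return TorsionSet(
        *(dihedral(pos[a], pos[b], pos[c], pos[d]) for a, b, c, d in NU_QUADRUPLES)
    )


def pseudorotation_phase(t: TorsionSet) -> float:
    """Pseudorotation phase P in degrees, [0, 360).

    Uses the Altona-Sundaralingam inverse formula; the atan2 branch
    implements the +180 deg correction for negative nu2 so that the
    phase distinguishes mirror-image twist conformers. nu2 = 0 resolves
    to 90 or 270 deg by the sign of the numerator.
    """
    if all(abs(v) < 1e-12 for v in t):
        raise GeometryError("planar ring: pseudorotation phase undefined")
    num = (t.nu4 + t.nu1) - (t.nu3 + t.nu0)
    den = _PHASE_DENOM * t.nu2
    return _wrap360(math.degrees(math.atan2(num, den)))


# cos(P + 144 (j - 2)) phase offsets of the cosine pucker model, j = 0..4
_COS_OFFSETS = np.array([-288.0, -144.0, 0.0, 144.0, 288.0])


def pucker_amplitude(t: TorsionSet, P: float) -> float:
    """Pseudorotation amplitude tau_m >= 0 in degrees.

    For |cos P| > 0.1 this inverts nu2 = tau_m cos P directly.  Near
    P = 90/270 deg that division is ill-conditioned, so tau_m is instead
    obtained by least squares over all five torsions against the cosine
    model nu_j = tau_m cos(P + 144 (j - 2)).
    """
    c = math.cos(math.radians(P))
    if abs(c) > 0.1:
        tau = t.nu2 / c
    else:
        cj = np.cos(np.radians(P + _COS_OFFSETS))
        tau = float(np.dot(np.asarray(t), cj) / np.dot(cj, cj))
    return max(tau, 0.0)


def classify_pucker(P: float) -> PuckerClass:
    """Classify a phase angle as 2'-endo-like or 3'-endo-like.

    The 2'-endo-like region is [80, 260); everything else on the circle
    (phases near the 3'-endo pole) is 3'-endo-like.  The classification
    is total: the boundary at 80 deg belongs to ENDO2, 260 deg to ENDO3.
    """
    if not 0.0 <= P < 360.0:
        raise GeometryError(f"phase angle {P} outside [0, 360)")
    return PuckerClass.ENDO2 if 80.0 <= P < 260.0 else PuckerClass.ENDO3


def pucker_state(res: "Residue") -> PuckerState:
    """Convenience wrapper: torsions -> (P, tau_m, class) for one residue."""
    t = endocyclic_torsions(res)
    P = pseudorotation_phase(t)
    return PuckerState(P, pucker_amplitude(t, P), classify_pucker(P), t)


def chi_angle(res: "Residue") -> float:
    """Glycosidic torsion chi in degrees, [0, 360).

    Defined over O4'-C1'-N9-C4 for purines and O4'-C1'-N1-C2 for
    pyrimidines.
    """
    quad = ("O4'", "C1'", "N9", "C4") if res.is_purine else ("O4'", "C1'", "N1", "C2")
    for name in quad:
        if name not in res.atoms:
            raise GeometryError(
                f"residue {res.chain_id}/{res.seq_id} ({res.name}) lacks chi atom {name}"
            )
    return _wrap360(dihedral(*(res.atoms[n].position for n in quad)))


def rotation_about_axis(direction, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a direction vector."""
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise GeometryError("zero-length rotation axis")
    x, y, z = d / n
    c = math.cos(math.radians(angle_deg))
    s = math.sin(math.radians(angle_deg))
    cc = 1.0 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )


def superpose(movable: Sequence, fixed: Sequence):
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps the movable set onto the fixed
    set with minimal RMSD.  The rotation is proper (det = +1).

    Raises
    ------
    GeometryError
        On length mismatch, fewer than three points, or collinear sets.
    """
    mov = np.asarray(movable, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    if mov.shape != fix.shape or mov.ndim != 2 or mov.shape[1] != 3:
        raise GeometryError("superpose requires two equal-length (n, 3) point sets")
    if mov.shape[0] < 3:
        raise GeometryError("superpose requires at least 3 points")
    mc = mov.mean(axis=0)
    fc = fix.mean(axis=0)
    a = mov - mc
    b = fix - fc
    # collinearity check: rank of either centred set < 2
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set in superpose")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = fc - rot @ mc
    moved = (rot @ mov.T).T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fix) ** 2, axis=1))))
    return rot, trans, rmsd
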