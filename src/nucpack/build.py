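"""Nucleotide building on a rigid backbone.

Rebuilding a nucleotide position proceeds in the following steps:

a. classify the position as 2'-endo-like or 3'-endo-like from its
   pseudorotation phase;
b. strip the residue to its main-chain atoms (phosphate group plus
   O3', C3', C4', C5');
c. superpose idealized sugar templates — three for 3'-endo-like
   positions, four for 2'-endo-like ones, spanning the neighbouring
   envelope/twist conformers on the pseudorotation wheel — onto the
   main-chain anchor atoms C3', C4', C5';
d. attach idealized nucleobases at each chi angle listed in the
   rotamer library (and for each requested nucleoside identity);
e. optionally fine-tune each chi by user-specified delta-chi
   increments; and
f. optionally apply a backrub rotation of the whole nucleotide about
   the C3'-C4' axis (or the P(i)-P(i+1) axis).

The product is a combinatorial candidate set whose size is the exact
product  n_rotamers x n_sugars x n_H x |dchi| x |backrub|  summed over
the allowed nucleosides.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import bases, synth
from .geom import (
    GeometryError,
    PuckerClass,
    dihedral,
    pucker_state,
    rotation_about_axis,
    superpose,
)
from .libfit import RotamerLibrary
from .structure import Atom, Residue, RIBONUCLEOSIDES

logger = logging.getLogger(__name__)

__all__ = [
    "MAINCHAIN_ATOMS",
    "SugarTemplate",
    "BuildConfig",
    "RotamerCandidate",
    "strip_to_mainchain",
    "sugar_conformers_for",
    "place_sugar",
    "attach_base_atoms",
    "attach_base",
    "expand_chi",
    "backrub",
    "enumerate_candidates",
]

#: The nucleotide main-chain atoms kept on a rigid backbone.
MAINCHAIN_ATOMS = frozenset({"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"})

#: Sugar-template names and canonical pseudorotation phases per pucker
#: class.  3E (P=18), 2E (162) and 2T1 (144) are canonical textbook
#: values; the remaining conformers follow the 18-deg-per-conformer
#: spacing of the pseudorotation wheel.
TEMPLATE_PHASES: Dict[PuckerClass, Tuple[Tuple[str, float], ...]] = {
    PuckerClass.ENDO3: (("3T2", 0.0), ("3E", 18.0), ("3T4", 36.0)),
    PuckerClass.ENDO2: (("2T3", 180.0), ("2E", 162.0), ("2T1", 144.0), ("1E", 126.0)),
}

#: Default template amplitudes: the modes of observed tau_m distributions.
TAU_M_DEFAULT = {"ribose": 40.0, "deoxyribose": 37.0}


@dataclass(frozen=True)
class SugarTemplate:
    """An idealized sugar conformer used for template superposition."""

    name: str
    canonical_P: float
    tau_m: float
    kind: str  # "ribose" | "deoxyribose"

    @property
    def residue(self) -> Residue:
        return _template_residue(self.name, self.canonical_P, self.tau_m, self.kind)


@lru_cache(maxsize=64)
def _template_residue(name: str, P: float, tau_m: float, kind: str) -> Residue:
    res = synth.ideal_sugar(P, tau_m, kind)
    measured = pucker_state(res).P
    if min(abs(measured - P), 360 - abs(measured - P)) > 2.0:
        raise GeometryError(
            f"template {name}: measured P {measured:.2f} deviates from {P}"
        )
    return res


def sugar_conformers_for(
    pucker_class: PuckerClass, kind: str = "deoxyribose", tau_m: Optional[float] = None
) -> List[SugarTemplate]:
    """The alternative sugar conformers offered at a position.

    3'-endo-like positions receive three templates, 2'-endo-like
    positions four (their observed phase distribution is broader).
    """
    tau = TAU_M_DEFAULT[kind] if tau_m is None else tau_m
    return [
        SugarTemplate(name, P, tau, kind) for name, P in TEMPLATE_PHASES[pucker_class]
    ]


@dataclass(frozen=True)
class BuildConfig:
    """Candidate-expansion settings.

    ``dchi``/``backrub_angles`` of ``(0,)`` disable the respective
    expansion; when enabled, the identity value 0 must be included so
    the unperturbed rotamer stays in the candidate set.
    """

    dchi: Tuple[float, ...] = (0.0,)
    backrub_angles: Tuple[float, ...] = (0.0,)
    backrub_axis: str = "C3C4"  # or "PP"
    h_placements: int = 1
    allowed_nucleosides: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if 0.0 not in self.dchi:
            raise ValueError("dchi expansion must include the identity increment 0")
        if 0.0 not in self.backrub_angles:
            raise ValueError("backrub expansion must include the identity angle 0")
        if self.backrub_axis not in ("C3C4", "PP"):
            raise ValueError(f"unknown backrub axis {self.backrub_axis!r}")
        if self.h_placements < 1:
            raise ValueError("h_placements must be >= 1")


@dataclass
class RotamerCandidate:
    """One full-atom candidate nucleotide with build provenance."""

    residue: Residue
    nucleoside: str
    sugar_name: str
    chi_base: float
    dchi: float = 0.0
    backrub_angle: float = 0.0
    h_variant: int = 0
    library_probability: float = 1.0

    @property
    def chi_target(self) -> float:
        return (self.chi_base + self.dchi) % 360.0

    def sidechain_atoms(self) -> List[Atom]:
        return [a for a in self.residue.atoms.values() if a.name not in MAINCHAIN_ATOMS]

    def copy(self) -> "RotamerCandidate":
        return RotamerCandidate(
            self.residue.copy(), self.nucleoside, self.sugar_name, self.chi_base,
            self.dchi, self.backrub_angle, self.h_variant, self.library_probability,
        )


def strip_to_mainchain(res: Residue) -> Residue:
    """Delete every atom except the nucleotide main-chain set.

    Missing main-chain atoms (e.g. the phosphate of a 5'-terminal
    residue) are logged, not raised; the operation is idempotent.
    """
    out = Residue(res.name, res.chain_id, res.seq_id)
    for name in sorted(MAINCHAIN_ATOMS):
        if name in res.atoms:
            out.add(res.atoms[name].copy())
        else:
            logger.warning(
                "residue %s/%s: main-chain atom %s missing", res.chain_id, res.seq_id, name
            )
    return out


def place_sugar(template: SugarTemplate, mainchain: Residue) -> Residue:
    """Superpose a sugar template onto the main-chain anchors C3', C4', C5'.

    The transformed template contributes the sugar atoms; the chain's
    phosphate group and O3'/O5' are kept untouched.
    """
    for anchor in ("C3'", "C4'", "C5'"):
        if anchor not in mainchain.atoms:
            raise GeometryError(
                f"residue {mainchain.chain_id}/{mainchain.seq_id} lacks anchor {anchor}"
            )
    anchors = ("C3'", "C4'", "C5'")
    tmpl = template.residue
    rot, trans, _ = superpose(tmpl.coords(anchors), mainchain.coords(anchors))
    moved = tmpl.transform(rot, trans)
    out = Residue(mainchain.name, mainchain.chain_id, mainchain.seq_id)
    for name in ("P", "OP1", "OP2", "O5'", "O3'"):
        if name in mainchain.atoms:
            out.add(mainchain.atoms[name].copy())
    for name, atom in moved.atoms.items():
        if name not in ("O5'", "O3'"):
            out.add(atom.copy())
    return out


def attach_base_atoms(res: Residue, nucleoside: str, chi: float) -> None:
    """Attach an idealized nucleobase to the residue's sugar, in place.

    The glycosidic nitrogen is placed along the free tetrahedral
    direction at C1' on the beta face at 1.48 A; the base plane is
    oriented so that the external bisector of the nitrogen's ring
    bonds points back along the glycosidic bond, and the remaining
    rotation about the bond is fixed so the measured chi equals the
    request (to well below 0.01 deg).
    """
    if nucleoside not in synth.NUCLEOSIDES_ORDER:
        raise ValueError(f"unknown nucleoside {nucleoside!r}")
    d = synth.glycosidic_direction(res)
    c1 = res.atoms["C1'"].position
    n_pos = c1 + synth.GLYCOSIDIC_BOND_LENGTH * d

    coords = bases.base_coordinates(nucleoside)
    n_name = bases.glycosidic_atom(nucleoside)
    letter = bases.base_kind(nucleoside)
    nb = ("C4", "C8") if letter in ("A", "G") else ("C2", "C6")
    e = -sum(coords[x] / np.linalg.norm(coords[x]) for x in nb)
    e /= np.linalg.norm(e)
    # rotate the base so its external bisector at N points toward C1'
    target = -d
    axis = np.cross(e, target)
    if np.linalg.norm(axis) < 1e-12:
        rot = np.eye(3) if np.dot(e, target) > 0 else rotation_about_axis(
            np.array([0.0, 0.0, 1.0]), 180.0
        )
    else:
        ang = math.degrees(math.atan2(np.linalg.norm(axis), float(np.dot(e, target))))
        rot = rotation_about_axis(axis, ang)
    placed = {name: rot @ p + n_pos for name, p in coords.items()}

    partner = bases.chi_partner_atom(nucleoside)
    o4 = res.atoms["O4'"].position
    axis_dir = n_pos - c1

    def measure(pos) -> float:
        return dihedral(o4, c1, pos[n_name], pos[partner]) % 360.0

    def rotated(pos, by_deg: float):
        r = rotation_about_axis(axis_dir, by_deg)
        return {n: r @ (p - n_pos) + n_pos for n, p in pos.items()}

    chi0 = measure(placed)
    probe = 10.0
    gain = (((measure(rotated(placed, probe)) - chi0) + 180.0) % 360.0) - 180.0
    delta = ((chi % 360.0) - chi0 + 180.0) % 360.0 - 180.0
    placed = rotated(placed, delta * probe / gain)
    for name, p in placed.items():
        res.add(Atom(name, name[0], p))


def attach_base(
    sugar: Residue, nucleoside: str, chi: float, sugar_name: str = "",
    library_probability: float = 1.0,
) -> RotamerCandidate:
    """Attach a base to a placed sugar and wrap the result as a candidate."""
    res = sugar.copy()
    res.name = nucleoside
    attach_base_atoms(res, nucleoside, chi)
    return RotamerCandidate(
        res, nucleoside, sugar_name, chi % 360.0,
        library_probability=library_probability,
    )


def _base_atom_names(cand: RotamerCandidate) -> Tuple[str, ...]:
    return bases.base_atom_names(cand.nucleoside)


def expand_chi(cand: RotamerCandidate, dchi: Sequence[float]) -> List[RotamerCandidate]:
    """One candidate per delta-chi increment; base rotated about the
    glycosidic bond, sugar untouched."""
    out = []
    res = cand.residue
    c1 = res.atoms["C1'"].position
    n_pos = res.atoms[bases.glycosidic_atom(cand.nucleoside)].position
    axis_dir = n_pos - c1
    base_names = _base_atom_names(cand)
    # calibrate the sign of the chi response once
    probe_rot = rotation_about_axis(axis_dir, 1.0)
    partner = bases.chi_partner_atom(cand.nucleoside)
    o4 = res.atoms["O4'"].position
    chi0 = dihedral(o4, c1, n_pos, res.atoms[partner].position)
    probed = probe_rot @ (res.atoms[partner].position - n_pos) + n_pos
    gain = ((dihedral(o4, c1, n_pos, probed) - chi0 + 180.0) % 360.0) - 180.0
    for inc in dchi:
        new = cand.copy()
        if inc != 0.0:
            r = rotation_about_axis(axis_dir, inc / gain)
            for name in base_names:
                atom = new.residue.atoms[name]
                atom.position = r @ (atom.position - n_pos) + n_pos
        new.dchi = float(inc)
        out.append(new)
    return out


def backrub(
    cand: RotamerCandidate,
    angle: float,
    axis: str = "C3C4",
    next_p_position: Optional[np.ndarray] = None,
) -> RotamerCandidate:
    """Rigidly rotate the whole nucleotide about a backbone axis.

    ``C3C4`` rotates about the line through the residue's own C3' and
    C4' atoms; ``PP`` rotates about the line through the residue's P
    and the following residue's P (which must be supplied).  Atoms on
    the axis are invariant by construction.
    """
    new = cand.copy()
    new.backrub_angle = float(angle)
    if angle == 0.0:
        return new
    res = new.residue
    if axis == "C3C4":
        p0 = res.atoms["C3'"].position.copy()
        p1 = res.atoms["C4'"].position.copy()
    elif axis == "PP":
        if "P" not in res.atoms:
            raise GeometryError("PP backrub axis requires the residue's phosphate")
        if next_p_position is None:
            raise GeometryError("PP backrub axis requires the next residue's P position")
        p0 = res.atoms["P"].position.copy()
        p1 = np.asarray(next_p_position, dtype=float)
    else:
        raise ValueError(f"unknown backrub axis {axis!r}")
    rot = rotation_about_axis(p1 - p0, angle)
    for atom in res.atoms.values():
        atom.position = rot @ (atom.position - p0) + p0
    return new


def enumerate_candidates(
    position: Residue,
    library: RotamerLibrary,
    cfg: BuildConfig = BuildConfig(),
    pucker_class: Optional[PuckerClass] = None,
    next_p_position: Optional[np.ndarray] = None,
) -> List[RotamerCandidate]:
    """Full candidate set for one designable position.

    The count obeys, per allowed nucleoside,
    ``n_rotamers x n_sugars x h_placements x |dchi| x |backrub|``.
    """
    if pucker_class is None:
        pucker_class = pucker_state(position).pucker_class
    mainchain = strip_to_mainchain(position)
    allowed = cfg.allowed_nucleosides or (position.name,)
    out: List[RotamerCandidate] = []
    for nucleoside in allowed:
        kind = "ribose" if nucleoside in RIBONUCLEOSIDES else "deoxyribose"
        cls_key = pucker_class.name if library.flavor == "pucker" else None
        rotamers = library.group(nucleoside, cls_key)
        if not rotamers:
            raise ValueError(
                f"library has no entries for ({nucleoside}, {cls_key or 'ANY'})"
            )
        templates = sugar_conformers_for(pucker_class, kind)
        for template in templates:
            sugar = place_sugar(template, mainchain)
            for entry in rotamers:
                base_cand = attach_base(
                    sugar, nucleoside, float(entry.chi), template.name, entry.probability
                )
                for cand in expand_chi(base_cand, cfg.dchi):
                    for h in range(cfg.h_placements):
                        hv = _with_h_variant(cand, h, cfg.h_placements)
                        for angle in cfg.backrub_angles:
                            out.append(
                                backrub(hv, angle, cfg.backrub_axis, next_p_position)
                            )
    return out


def _with_h_variant(cand: RotamerCandidate, h: int, n_h: int) -> RotamerCandidate:
    """Tag (and, for ribose 2'-OH, realise) the h-th hydrogen placement.

    With ``n_h`` = 3 and an O2' present, the hydroxyl hydrogen is
    placed at the three staggered torsions about the C2'-O2' bond;
    otherwise the variant is bookkeeping only.
    """
    new = cand.copy()
    new.h_variant = h
    res = new.residue
    if n_h > 1 and "O2'" in res.atoms:
        torsion = 60.0 + 120.0 * h
        pos = synth.nerf(
            res.atoms["C1'"].position,
            res.atoms["C2'"].position,
            res.atoms["O2'"].position,
            0.96, 109.5, torsion,
        )
        res.add(Atom("HO2'", "H", pos))
    return new
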