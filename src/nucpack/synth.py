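"""Synthetic structure fixtures: ideal sugars, nucleotides and duplexes.

Everything here is generated geometry — idealized furanose rings at a
requested pseudorotation phase/amplitude, single nucleotides with a
prescribed glycosidic torsion, short Watson-Crick duplexes built from
helical-wheel placement, and chi-angle populations drawn from mixture
definitions.  The fixtures are deterministic under a fixed seed and are
validated by the same descriptor code they exercise.

The duplex generator uses simple helical parameters (rise/twist and a
planar Watson-Crick pair template), not fiber-diffraction standards:
base pairs are ideally coplanar, and the sugar-phosphate backbone is
placed per-residue rather than covalently threaded between residues.
It is adequate for H-bond/stacking fixtures and rebuilding tests, and
is documented as idealized.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from . import bases
from .geom import GeometryError, dihedral, rotation_about_axis
from .libfit import RotamerEntry, RotamerLibrary
from .structure import Atom, Residue, Structure

__all__ = [
    "nerf",
    "ideal_sugar",
    "ideal_nucleotide",
    "toy_duplex",
    "stacked_dimer",
    "chi_population",
    "example_library",
    "glycosidic_direction",
    "beta_face_normal",
    "GLYCOSIDIC_BOND_LENGTH",
]

GLYCOSIDIC_BOND_LENGTH = 1.48

_RING = ("O4'", "C1'", "C2'", "C3'", "C4'")
_RING_BONDS = ((0, 1, 1.414), (1, 2, 1.528), (2, 3, 1.525), (3, 4, 1.523), (4, 0, 1.446))
_RING_ANGLES = (  # internal angle at atom i between its two ring neighbours
    (4, 0, 1, 109.7),
    (0, 1, 2, 106.1),
    (1, 2, 3, 101.5),
    (2, 3, 4, 102.6),
    (3, 4, 0, 105.5),
)
# torsion quadruples in ring-index form, nu0..nu4
_RING_TORSIONS = ((4, 0, 1, 2), (0, 1, 2, 3), (1, 2, 3, 4), (2, 3, 4, 0), (3, 4, 0, 1))


def nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given A, B, C with |CD|, angle BCD and torsion ABCD."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def _angle(p1, p2, p3) -> float:
    u = p1 - p2
    v = p3 - p2
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosv, -1.0, 1.0)))


def _cosine_torsions(P: float, tau_m: float) -> np.ndarray:
    """Endocyclic torsion targets nu_j = tau_m cos(P + 144 (j - 2))."""
    j = np.arange(5)
    return tau_m * np.cos(np.radians(P + 144.0 * (j - 2)))


@lru_cache(maxsize=256)
def _ring_coordinates(P: float, tau_m: float) -> Tuple[Tuple[float, float, float], ...]:
    """Closed furanose ring whose torsions best fit the cosine pucker model.

    The ring is found by least squares over the five atom positions:
    torsion targets are weighted strongly, ideal bond lengths strongly,
    and ideal bond angles softly (the five torsions and five angles are
    not simultaneously satisfiable in a closed ring, and the torsions
    carry the pucker).  Several puckering-phase starting guesses are
    tried and the best converged solution is kept; the whole procedure
    is deterministic.
    """
    targets = _cosine_torsions(P, tau_m)
    bond_i = np.array([b[0] for b in _RING_BONDS])
    bond_j = np.array([b[1] for b in _RING_BONDS])
    bond_l = np.array([b[2] for b in _RING_BONDS])
    ang_ijk = np.array([a[:3] for a in _RING_ANGLES])
    ang_t = np.array([a[3] for a in _RING_ANGLES])
    tor_q = np.array(_RING_TORSIONS)

    def residuals(x: np.ndarray) -> np.ndarray:
        pos = x.reshape(5, 3)
        bonds = np.linalg.norm(pos[bond_i] - pos[bond_j], axis=1)
        u = pos[ang_ijk[:, 0]] - pos[ang_ijk[:, 1]]
        v = pos[ang_ijk[:, 2]] - pos[ang_ijk[:, 1]]
        cosv = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        angles = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
        b1 = pos[tor_q[:, 1]] - pos[tor_q[:, 0]]
        b2 = pos[tor_q[:, 2]] - pos[tor_q[:, 1]]
        b3 = pos[tor_q[:, 3]] - pos[tor_q[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
        tors = np.degrees(
            np.arctan2(np.sum(np.cross(n1, n2) * b2n, axis=1), np.sum(n1 * n2, axis=1))
        )
        dtor = ((tors - targets + 180.0) % 360.0) - 180.0
        return np.concatenate(
            [(bonds - bond_l) * 100.0, (angles - ang_t) * 0.5, dtor * 3.0]
        )

    # planar pentagon footprint
    r0 = 1.23
    planar = np.array(
        [
            [r0 * math.cos(math.radians(90 + 72 * i)), r0 * math.sin(math.radians(90 + 72 * i)), 0.0]
            for i in range(5)
        ]
    )
    best = None
    amp_z = 0.4 * tau_m / 40.0
    # the out-of-plane mode phase tracks P + 90 (up to the normal-sign
    # ambiguity); try those two starts first, the coarse grid as fallback
    starts = [P + 90.0, P + 270.0] + list(range(0, 360, 36))
    for phase in starts:
        start = planar.copy()
        # m = 2 puckering mode of a five-ring as the out-of-plane guess
        start[:, 2] = amp_z * np.cos(np.radians(phase + 144.0 * np.arange(5)))
        sol = least_squares(residuals, start.ravel(), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        cost = float(sol.cost)
        pos = sol.x.reshape(5, 3)
        measured = [dihedral(*(pos[i] for i in q)) for q in _RING_TORSIONS]
        torsion_err = max(abs(m - t) for m, t in zip(measured, targets))
        if best is None or (torsion_err, cost) < best[0]:
            best = ((torsion_err, cost), pos)
        if torsion_err < 0.05:
            break
    (torsion_err, _), pos = best
    if torsion_err > 2.0:
        raise GeometryError(
            f"ring closure failed at P={P}, tau_m={tau_m} (torsion error {torsion_err:.2f} deg)"
        )
    pos = pos - pos.mean(axis=0)
    return tuple(tuple(p) for p in pos)


def beta_face_normal(positions: Mapping[str, np.ndarray]) -> np.ndarray:
    """Unit normal of the sugar ring pointing to the beta face.

    The beta face is the side of the furanose ring on which C5' and the
    nucleobase sit in natural beta-D-nucleosides; O2'/O3' point to the
    opposite (alpha) face.
    """
    ring = [np.asarray(positions[n], dtype=float) for n in _RING]
    cen = np.mean(ring, axis=0)
    n = np.zeros(3)
    for i in range(5):
        n += np.cross(ring[i] - cen, ring[(i + 1) % 5] - cen)
    # with ring order O4'-C1'-C2'-C3'-C4' the accumulated normal points
    # to the alpha face of a D-sugar; flip it
    n = -n
    return n / np.linalg.norm(n)


def _tetra_direction(center, nb1, nb2, face: np.ndarray, side: float) -> np.ndarray:
    """One of the two free tetrahedral directions at an sp3 centre.

    ``side`` picks the direction whose projection on ``face`` has the
    requested sign (+1: beta face, -1: alpha face).
    """
    u1 = nb1 - center
    u1 /= np.linalg.norm(u1)
    u2 = nb2 - center
    u2 /= np.linalg.norm(u2)
    b = -(u1 + u2)
    b /= np.linalg.norm(b)
    p = np.cross(u1, u2)
    p /= np.linalg.norm(p)
    half = math.radians(109.5 / 2.0)
    d1 = math.cos(half) * b + math.sin(half) * p
    d2 = math.cos(half) * b - math.sin(half) * p
    return d1 if np.dot(d1, face) * side > np.dot(d2, face) * side else d2


def ideal_sugar(
    P: float,
    tau_m: float,
    kind: str = "deoxyribose",
    chain_id: str = "X",
    seq_id: int = 1,
) -> Residue:
    """Idealized furanose sugar at a requested pucker.

    Returns a residue with the ring atoms plus C5', O5', O3' and (for
    ribose) O2'.  The measured pseudorotation phase of the result is
    within 2 deg of the request.
    """
    if not 10.0 < tau_m < 60.0:
        raise ValueError("tau_m must be in (10, 60) degrees")
    if kind not in ("ribose", "deoxyribose"):
        raise ValueError(f"unknown sugar kind {kind!r}")
    ring = {
        name: np.array(p) for name, p in zip(_RING, _ring_coordinates(P % 360.0, tau_m))
    }
    res = Residue("RIB" if kind == "ribose" else "DRB", chain_id, seq_id)
    for name, p in ring.items():
        res.add(Atom(name, name[0], p))
    face = beta_face_normal(ring)
    c5 = ring["C4'"] + 1.51 * _tetra_direction(ring["C4'"], ring["C3'"], ring["O4'"], face, +1)
    res.add(Atom("C5'", "C", c5))
    o3 = ring["C3'"] + 1.42 * _tetra_direction(ring["C3'"], ring["C2'"], ring["C4'"], face, -1)
    res.add(Atom("O3'", "O", o3))
    if kind == "ribose":
        o2 = ring["C2'"] + 1.41 * _tetra_direction(ring["C2'"], ring["C1'"], ring["C3'"], face, -1)
        res.add(Atom("O2'", "O", o2))
    o5 = nerf(ring["C3'"], ring["C4'"], c5, 1.44, 110.2, 54.0)
    res.add(Atom("O5'", "O", o5))
    return res


def glycosidic_direction(res: Residue) -> np.ndarray:
    """Unit vector from C1' toward the glycosidic nitrogen slot (beta face)."""
    ring = {n: res.atoms[n].position for n in _RING}
    face = beta_face_normal(ring)
    return _tetra_direction(ring["C1'"], ring["O4'"], ring["C2'"], face, +1)


def add_phosphate(res: Residue) -> None:
    """Place P/OP1/OP2 from the residue's own C4'-C5'-O5' frame (in situ)."""
    c4 = res.atoms["C4'"].position
    c5 = res.atoms["C5'"].position
    o5 = res.atoms["O5'"].position
    p = nerf(c4, c5, o5, 1.59, 120.9, 180.0)
    res.add(Atom("P", "P", p))
    res.add(Atom("OP1", "O", nerf(c5, o5, p, 1.49, 108.0, 115.0)))
    res.add(Atom("OP2", "O", nerf(c5, o5, p, 1.49, 108.0, -115.0)))


def ideal_nucleotide(
    nucleoside: str,
    P: float,
    tau_m: float,
    chi: float,
    chain_id: str = "X",
    seq_id: int = 1,
    with_phosphate: bool = True,
) -> Residue:
    """Complete idealized nucleotide at a requested pucker and chi."""
    from .build import attach_base_atoms  # deferred: build depends on synth

    kind = "ribose" if nucleoside in ("A", "U", "G", "C") else "deoxyribose"
    sugar = ideal_sugar(P, tau_m, kind, chain_id, seq_id)
    res = Residue(nucleoside, chain_id, seq_id)
    for atom in sugar.atoms.values():
        res.add(atom.copy())
    attach_base_atoms(res, nucleoside, chi)
    if with_phosphate:
        add_phosphate(res)
    return res


# ---------------------------------------------------------------------------
# Watson-Crick pair templates and duplex generation
# ---------------------------------------------------------------------------

_HBOND_TARGET = 2.90  # donor-acceptor heavy-atom distance in an ideal pair
_C1_C1_TARGET = 10.4


def _base_c1_proxy(coords: Dict[str, np.ndarray], nucleoside: str) -> np.ndarray:
    """Approximate C1' position implied by a base frame (along the
    external bisector of the glycosidic nitrogen)."""
    n = bases.glycosidic_atom(nucleoside)
    letter = bases.base_kind(nucleoside)
    nb = ("C4", "C8") if letter in ("A", "G") else ("C2", "C6")
    e = -sum(
        (coords[x] - coords[n]) / np.linalg.norm(coords[x] - coords[n]) for x in nb
    )
    e /= np.linalg.norm(e)
    return coords[n] + GLYCOSIDIC_BOND_LENGTH * e


@lru_cache(maxsize=8)
def _wc_pair_template(pu: str, py: str):
    """Planar Watson-Crick pair template (purine fixed at the origin).

    Returns ``(purine_coords, pyrimidine_coords)`` in the pair frame
    (z = 0 plane, midpoint of the two implied C1' atoms at the origin).
    The pyrimidine is placed by least squares so every matched
    donor/acceptor pair sits at 2.9 A and the implied C1'-C1' distance
    is 10.4 A.
    """
    pairs = bases.WATSON_CRICK_PAIRS[(bases.base_kind(pu), bases.base_kind(py))]
    cpu = bases.base_coordinates(pu)
    raw_py = bases.base_coordinates(py)
    hex_names = ("N1", "C2", "N3", "C4", "C5", "C6")
    cen_pu = np.mean([cpu[n] for n in hex_names], axis=0)
    u = cpu["N1"] - cen_pu
    u /= np.linalg.norm(u)
    ring_pu = [cpu[n] for n in bases.BASE_RING_ATOMS[bases.base_kind(pu)]]
    ring_py_names = bases.BASE_RING_ATOMS[bases.base_kind(py)]

    best = None
    # the pyrimidine enters the pair plane either as built or mirrored
    # in-plane (the two choices put its exocyclic O/N on opposite
    # lateral sides of the N1...N3 axis); pick the parity whose
    # edge-to-edge start matches the Watson-Crick partner atoms
    for flip in (np.diag([1.0, -1.0, 1.0]), np.eye(3)):
        cpy0 = {n: flip @ p for n, p in raw_py.items()}

        def place(params, base=cpy0):
            th, tx, ty = params
            rot = rotation_about_axis([0, 0, 1], math.degrees(th))
            return {n: rot @ p + np.array([tx, ty, 0.0]) for n, p in base.items()}

        def residuals(params, base=cpy0):
            cpy = place(params, base)
            out = [
                (np.linalg.norm(cpu[a] - cpy[b]) - _HBOND_TARGET) * 10.0
                for a, b in pairs
            ]
            if len(pairs) < 3:
                # two H-bonds leave the in-plane placement underdetermined;
                # fix the glycosidic opening with the C1'-C1' distance
                out.append(
                    np.linalg.norm(_base_c1_proxy(cpu, pu) - _base_c1_proxy(cpy, py))
                    - _C1_C1_TARGET
                )
            return np.array(out)

        # informed start: the N1(purine)...N3(pyrimidine) hydrogen bond
        # runs along the purine N1 radial direction, bases edge-to-edge
        cen_py = np.mean([cpy0[n] for n in hex_names], axis=0)
        v = cpy0["N3"] - cen_py
        v /= np.linalg.norm(v)
        th0 = math.atan2(-u[1], -u[0]) - math.atan2(v[1], v[0])
        rot0 = rotation_about_axis([0, 0, 1], math.degrees(th0))
        t0 = cpu["N1"] + _HBOND_TARGET * u - rot0 @ cpy0["N3"]
        start_cost = float(np.sum(residuals([th0, t0[0], t0[1]]) ** 2))
        sol = least_squares(residuals, [th0, t0[0], t0[1]], xtol=1e-14, ftol=1e-14)
        cpy = place(sol.x)
        # feasibility: no cross-base contact tighter than the matched
        # H-bond pairs themselves (guards against intercalated optima)
        matched = set(pairs)
        clearance = min(
            float(np.linalg.norm(cpu[a] - cpy[b]))
            for a in cpu
            for b in cpy
            if (a, b) not in matched
        )
        score = (clearance < 2.5, start_cost)
        if best is None or score < best[0]:
            best = (score, cpy)
    cpy = best[1]
    mid = 0.5 * (_base_c1_proxy(cpu, pu) + _base_c1_proxy(cpy, py))
    cpu = {n: p - mid for n, p in cpu.items()}
    cpy = {n: p - mid for n, p in cpy.items()}
    return cpu, cpy


def _pair_template_for(b1: str, b2: str):
    """Pair template oriented as (strand-1 base, strand-2 base)."""
    if bases.base_kind(b1) in ("A", "G"):
        cpu, cpy = _wc_pair_template(b1, b2)
        return cpu, cpy
    cpu, cpy = _wc_pair_template(b2, b1)
    return cpy, cpu


_DNA_COMPLEMENT = {"dA": "dT", "dT": "dA", "dG": "dC", "dC": "dG"}
_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Idealized helical parameters per duplex form: rise (A), twist (deg),
#: sugar phase P (deg), chi (deg).  B: 2'-endo sugars with -ac bases;
#: A: 3'-endo sugars with -ap bases.
HELIX_FORMS = {
    "B": {"rise": 3.38, "twist": 36.0, "P": 162.0, "chi": 250.0},
    "A": {"rise": 2.81, "twist": 32.7, "P": 18.0, "chi": 200.0},
}


def _attach_sugar_to_base(
    res: Residue, nucleoside: str, chi: float, P: float, tau_m: float
) -> None:
    """Build the sugar (and phosphate frame atoms) onto a placed base.

    The base atoms of ``res`` stay fixed; an ideal sugar is rigidly
    placed so that its C1' sits at the implied glycosidic position and
    the measured chi equals the request.
    """
    kind = "ribose" if nucleoside in ("A", "U", "G", "C") else "deoxyribose"
    coords = {n: res.atoms[n].position for n in res.atoms}
    c1_target = _base_c1_proxy(coords, nucleoside)
    n_atom = bases.glycosidic_atom(nucleoside)
    n_pos = coords[n_atom]

    sugar = ideal_sugar(P, tau_m, kind)
    d_g = glycosidic_direction(sugar)
    c1 = sugar.atoms["C1'"].position
    target_dir = n_pos - c1_target
    target_dir /= np.linalg.norm(target_dir)
    axis = np.cross(d_g, target_dir)
    if np.linalg.norm(axis) < 1e-12:
        rot = np.eye(3) if np.dot(d_g, target_dir) > 0 else rotation_about_axis(
            np.array([1.0, 0.0, 0.0]) if abs(d_g[0]) < 0.9 else np.array([0.0, 1.0, 0.0]),
            180.0,
        )
    else:
        ang = math.degrees(
            math.atan2(np.linalg.norm(axis), float(np.dot(d_g, target_dir)))
        )
        rot = rotation_about_axis(axis, ang)
    placed = {n: rot @ (a.position - c1) + c1_target for n, a in sugar.atoms.items()}

    # fix the remaining degree of freedom (rotation about the glycosidic
    # bond) so the measured chi matches; the dihedral responds exactly
    # linearly to this rotation, so one probe determines the sign
    partner = bases.chi_partner_atom(nucleoside)
    axis_dir = n_pos - c1_target

    def measure(sugar_pos) -> float:
        return dihedral(sugar_pos["O4'"], sugar_pos["C1'"], n_pos, coords[partner]) % 360.0

    def rotated(by_deg: float):
        r = rotation_about_axis(axis_dir, by_deg)
        return {n: r @ (p - c1_target) + c1_target for n, p in placed.items()}

    chi0 = measure(placed)
    probe = 10.0
    chi1 = measure(rotated(probe))
    gain = ((chi1 - chi0 + 180.0) % 360.0) - 180.0
    delta = ((chi % 360.0) - chi0 + 180.0) % 360.0 - 180.0
    placed = rotated(delta * probe / gain)

    for name, p in placed.items():
        res.add(Atom(name, name[0], p))
    add_phosphate(res)


def toy_duplex(sequence: str, form: str = "B", seed: int = 0) -> Structure:
    """Idealized Watson-Crick duplex from helical-wheel placement.

    ``sequence`` is the 5'->3' sequence of strand A in one-letter code
    (ACGT = DNA, ACGU = RNA, 4-20 nt); the complementary strand B is
    generated automatically.  Base pairs are planar with ideal H-bond
    geometry; consecutive pairs are related by the form's rise/twist.
    """
    if form not in HELIX_FORMS:
        raise ValueError(f"unknown duplex form {form!r}")
    if not 4 <= len(sequence) <= 20:
        raise ValueError("sequence must have 4-20 nucleotides")
    seq = sequence.upper()
    if set(seq) <= set("ACGT") and "T" in seq or (set(seq) <= set("ACG")):
        comp_map = _DNA_COMPLEMENT
        nucs = ["d" + c for c in seq]
    elif set(seq) <= set("ACGU"):
        comp_map = _RNA_COMPLEMENT
        nucs = list(seq)
    else:
        raise ValueError(f"sequence {sequence!r} is neither DNA nor RNA")
    params = HELIX_FORMS[form]
    tau = 40.0 if nucs[0] in _RNA_COMPLEMENT else 37.0
    n = len(nucs)
    structure = Structure(name=f"{form}-form duplex {sequence}")
    strand_b: List[Residue] = []
    for i, nuc in enumerate(nucs):
        comp = comp_map[nuc]
        t1, t2 = _pair_template_for(nuc, comp)
        rot = rotation_about_axis([0, 0, 1], i * params["twist"])
        shift = np.array([0.0, 0.0, i * params["rise"]])
        res1 = Residue(nuc, "A", i + 1)
        for name, p in t1.items():
            res1.add(Atom(name, name[0], rot @ p + shift))
        _attach_sugar_to_base(res1, nuc, params["chi"], params["P"], tau)
        structure.add(res1)
        res2 = Residue(comp, "B", n - i)
        for name, p in t2.items():
            res2.add(Atom(name, name[0], rot @ p + shift))
        _attach_sugar_to_base(res2, comp, params["chi"], params["P"], tau)
        strand_b.append(res2)
    for res in sorted(strand_b, key=lambda r: r.seq_id):
        structure.add(res)
    return structure


def stacked_dimer(nucleoside: str = "dA", rise: float = 3.4, twist: float = 36.0) -> Structure:
    """Two identical bases stacked about their ring-centroid axis.

    A minimal base-stacking fixture: the second copy is the first
    rotated by ``twist`` about the vertical axis through the ring
    centroid and shifted by ``rise``.
    """
    coords = bases.base_coordinates(nucleoside)
    ring = bases.BASE_RING_ATOMS[bases.base_kind(nucleoside)]
    cen = np.mean([coords[n] for n in ring], axis=0)
    st = Structure(name="stacked dimer")
    r1 = Residue(nucleoside, "A", 1)
    for name, p in coords.items():
        r1.add(Atom(name, name[0], p))
    st.add(r1)
    rot = rotation_about_axis([0, 0, 1], twist)
    r2 = Residue(nucleoside, "A", 2)
    for name, p in coords.items():
        r2.add(Atom(name, name[0], rot @ (p - cen) + cen + np.array([0, 0, rise])))
    st.add(r2)
    return st


def chi_population(
    library: RotamerLibrary,
    group: Tuple[str, Optional[str]],
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw a chi sample from the mixture defined by one library group."""
    if n < 1:
        raise ValueError("n must be >= 1")
    nuc, cls = group
    entries = library.group(nuc, cls)
    if not entries:
        raise ValueError(f"library has no group ({nuc}, {cls})")
    rng = np.random.default_rng(seed)
    probs = np.array([e.probability for e in entries])
    probs = probs / probs.sum()
    idx = rng.choice(len(entries), size=n, p=probs)
    means = np.array([e.chi for e in entries], dtype=float)
    sds = np.array([e.sd for e in entries], dtype=float)
    return (rng.normal(means[idx], sds[idx])) % 360.0


def example_library() -> RotamerLibrary:
    """A small synthetic pucker-dependent reference library.

    The entries emulate the field's known chi preferences — a dominant
    -ap (~200 deg) rotamer for 3'-endo-like sugars, a dominant -ac
    (~250 deg) rotamer for 2'-endo-like sugars, and a minor +sc
    (~65 deg) syn rotamer for purines only — with well-separated means
    so that mixture fitting on samples drawn from it is identifiable.
    This is a synthetic stand-in used by tests and demonstrations, not
    a statistically derived library.
    """
    entries: List[RotamerEntry] = []
    for nuc in NUCLEOSIDES_ORDER:
        purine = nuc in ("A", "G", "dA", "dG")
        if purine:
            entries.append(RotamerEntry(nuc, "ENDO3", 65, 10.0, 0.05))
            entries.append(RotamerEntry(nuc, "ENDO3", 200, 12.0, 0.75))
            entries.append(RotamerEntry(nuc, "ENDO3", 250, 12.0, 0.20))
            entries.append(RotamerEntry(nuc, "ENDO2", 65, 10.0, 0.10))
            entries.append(RotamerEntry(nuc, "ENDO2", 200, 12.0, 0.25))
            entries.append(RotamerEntry(nuc, "ENDO2", 250, 12.0, 0.65))
        else:
            entries.append(RotamerEntry(nuc, "ENDO3", 200, 12.0, 0.80))
            entries.append(RotamerEntry(nuc, "ENDO3", 250, 12.0, 0.20))
            entries.append(RotamerEntry(nuc, "ENDO2", 200, 12.0, 0.30))
            entries.append(RotamerEntry(nuc, "ENDO2", 250, 12.0, 0.70))
    lib = RotamerLibrary(entries=entries, flavor="pucker", provenance="synthetic example")
    lib.validate()
    return lib


NUCLEOSIDES_ORDER = ("A", "U", "G", "C", "dA", "dT", "dG", "dC")
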