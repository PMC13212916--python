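"""Idealized planar nucleobase geometries and polar-atom annotations.

Bases are constructed from regular-polygon ring geometry (hexagon side
1.37 A, fused pentagon side matched to the shared edge) with exocyclic
substituents placed radially at standard bond lengths.  The result is a
consistent idealized geometry: ring closure is exact, bond lengths are
within a few hundredths of an Angstrom of small-molecule values, and
Watson-Crick donor/acceptor positions are accurate enough for geometric
H-bond criteria.  Coordinates are planar (z = 0) in a local frame with
the glycosidic nitrogen (N1 pyrimidine / N9 purine) at the origin.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "base_kind",
    "base_coordinates",
    "glycosidic_atom",
    "chi_partner_atom",
    "BASE_RING_ATOMS",
    "BASE_DONORS",
    "BASE_ACCEPTORS",
    "WATSON_CRICK_PAIRS",
    "base_atom_names",
]

_HEX_SIDE = 1.37
_PENT_SIDE = 1.37
_C_O = 1.23
_C_N = 1.34
_C_C = 1.50


def base_kind(nucleoside: str) -> str:
    """Map a nucleoside code (A, dG, dT, ...) to its base letter."""
    letter = nucleoside[-1]
    return "T" if letter == "T" else letter


def glycosidic_atom(nucleoside: str) -> str:
    return "N9" if base_kind(nucleoside) in ("A", "G") else "N1"


def chi_partner_atom(nucleoside: str) -> str:
    """Fourth chi atom: C4 for purines, C2 for pyrimidines."""
    return "C4" if base_kind(nucleoside) in ("A", "G") else "C2"


#: Ring atoms per base letter (used for centroids/planes in stacking tests).
BASE_RING_ATOMS: Dict[str, Tuple[str, ...]] = {
    "A": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "G": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: H-bond donor heavy atoms with their antecedent for the donor-angle
#: check.  Exocyclic amines use their ring carbon; ring N-H donors use
#: the ring centroid (None), since the H points along the external
#: bisector of the ring bonds.
BASE_DONORS: Dict[str, Dict[str, Optional[str]]] = {
    "A": {"N6": "C6"},
    "G": {"N1": None, "N2": "C2"},
    "C": {"N4": "C4"},
    "U": {"N3": None},
    "T": {"N3": None},
}

#: H-bond acceptor heavy atoms.
BASE_ACCEPTORS: Dict[str, Tuple[str, ...]] = {
    "A": ("N1", "N3", "N7"),
    "G": ("O6", "N3", "N7"),
    "C": ("O2", "N3"),
    "U": ("O2", "O4"),
    "T": ("O2", "O4"),
}

#: Watson-Crick matched donor/acceptor atom pairs, (purine atom, pyrimidine atom).
WATSON_CRICK_PAIRS: Dict[Tuple[str, str], Tuple[Tuple[str, str], ...]] = {
    ("G", "C"): (("O6", "N4"), ("N1", "N3"), ("N2", "O2")),
    ("A", "T"): (("N6", "O4"), ("N1", "N3")),
    ("A", "U"): (("N6", "O4"), ("N1", "N3")),
}


def _hexagon(first_atom_names: List[str]) -> Dict[str, np.ndarray]:
    """Regular hexagon in the xy-plane, first atom at the origin."""
    r = _HEX_SIDE  # circumradius equals side length for a hexagon
    center = np.array([r, 0.0, 0.0])
    coords = {}
    for k, name in enumerate(first_atom_names):
        ang = math.radians(180.0 + 60.0 * k)
        coords[name] = center + r * np.array([math.cos(ang), math.sin(ang), 0.0])
    return coords


def _fuse_pentagon(
    coords: Dict[str, np.ndarray], edge: Tuple[str, str], new_names: List[str]
) -> None:
    """Fuse a regular pentagon onto an existing edge, away from the hexagon."""
    a = coords[edge[0]]
    b = coords[edge[1]]
    hex_center = np.mean([coords[n] for n in ("N1", "C2", "N3", "C4", "C5", "C6")], axis=0)
    m = 0.5 * (a + b)
    u = m - hex_center
    u = u / np.linalg.norm(u)
    s = float(np.linalg.norm(b - a))
    apothem = s / (2.0 * math.tan(math.radians(36.0)))
    circum = s / (2.0 * math.sin(math.radians(36.0)))
    pc = m + apothem * u
    th_a = math.atan2(a[1] - pc[1], a[0] - pc[0])
    # step direction around the pentagon: four steps from edge[0] reach edge[1]
    step = math.radians(72.0)
    end = pc + circum * np.array(
        [math.cos(th_a + 4 * step), math.sin(th_a + 4 * step), 0.0]
    )
    if np.linalg.norm(end - b) > 1e-6:
        step = -step
    for k, name in enumerate(new_names, start=1):
        th = th_a + k * step
        coords[name] = pc + circum * np.array([math.cos(th), math.sin(th), 0.0])


def _radial(coords: Dict[str, np.ndarray], ring: Tuple[str, ...], atom: str,
            bond: float) -> np.ndarray:
    """Place a substituent radially outward from the ring centroid."""
    center = np.mean([coords[n] for n in ring], axis=0)
    p = coords[atom]
    u = p - center
    u = u / np.linalg.norm(u)
    return p + bond * u


@lru_cache(maxsize=None)
def _build_base(letter: str) -> Dict[str, Tuple[float, float, float]]:
    hexn = ["N1", "C2", "N3", "C4", "C5", "C6"]
    coords = _hexagon(hexn)
    hex_ring = tuple(hexn)
    if letter in ("A", "G"):
        _fuse_pentagon(coords, ("C4", "C5"), ["N9", "C8", "N7"])
        pent_ring = ("C4", "C5", "N7", "C8", "N9")
        if letter == "A":
            coords["N6"] = _radial(coords, hex_ring, "C6", _C_N)
        else:
            coords["O6"] = _radial(coords, hex_ring, "C6", _C_O)
            coords["N2"] = _radial(coords, hex_ring, "C2", _C_N)
        origin = coords["N9"].copy()
    else:
        coords["O2"] = _radial(coords, hex_ring, "C2", _C_O)
        if letter == "C":
            coords["N4"] = _radial(coords, hex_ring, "C4", _C_N)
        else:
            coords["O4"] = _radial(coords, hex_ring, "C4", _C_O)
            if letter == "T":
                coords["C7"] = _radial(coords, hex_ring, "C5", _C_C)
        origin = coords["N1"].copy()
    return {n: tuple(p - origin) for n, p in coords.items()}


def base_coordinates(nucleoside: str) -> Dict[str, np.ndarray]:
    """Planar base coordinates in a local frame (glycosidic N at origin)."""
    letter = base_kind(nucleoside)
    if letter not in BASE_RING_ATOMS:
        raise ValueError(f"unknown nucleoside {nucleoside!r}")
    return {n: np.array(p) for n, p in _build_base(letter).items()}


def base_atom_names(nucleoside: str) -> Tuple[str, ...]:
    """Heavy-atom names of the idealized base of a nucleoside."""
    return tuple(_build_base(base_kind(nucleoside)).keys())


def base_polar_sites(res) -> Tuple[List[Tuple[np.ndarray, np.ndarray]], List[np.ndarray]]:
    """Donor (position, antecedent) pairs and acceptor positions of a
    residue's nucleobase.

    ``res`` is any residue-like object with an ``atoms`` mapping and a
    nucleoside ``name``.  Ring N-H donors use the ring centroid as
    antecedent.
    """
    letter = base_kind(res.name)
    ring = [res.atoms[n].position for n in BASE_RING_ATOMS[letter] if n in res.atoms]
    centroid = np.mean(ring, axis=0) if ring else None
    donors: List[Tuple[np.ndarray, np.ndarray]] = []
    for d, ante in BASE_DONORS[letter].items():
        if d not in res.atoms:
            continue
        if ante is None:
            if centroid is None:
                continue
            donors.append((res.atoms[d].position, centroid))
        elif ante in res.atoms:
            donors.append((res.atoms[d].position, res.atoms[ante].position))
    acceptors = [res.atoms[a].position for a in BASE_ACCEPTORS[letter] if a in res.atoms]
    return donors, acceptors
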