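"""Lightweight atomic-structure containers.

The containers are deliberately minimal: a :class:`Structure` is an
ordered collection of :class:`Residue` objects (nucleotides, amino
acids, or anything else), each holding :class:`Atom` records keyed by
atom name.  Parsing and serialisation of PDB/mmCIF is delegated to
gemmi in :mod:`nucpack.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "NUCLEOSIDES",
    "PURINES",
    "PYRIMIDINES",
    "RIBONUCLEOSIDES",
    "canonical_nucleoside",
    "residue_name_for",
]

#: Canonical nucleoside codes handled by the library.
NUCLEOSIDES = ("A", "U", "G", "C", "dA", "dT", "dG", "dC")
PURINES = frozenset({"A", "G", "dA", "dG"})
PYRIMIDINES = frozenset({"U", "C", "T", "dT", "dC"})
RIBONUCLEOSIDES = frozenset({"A", "U", "G", "C"})

_PDB_TO_CANONICAL = {
    "A": "A", "U": "U", "G": "G", "C": "C",
    "DA": "dA", "DT": "dT", "DG": "dG", "DC": "dC",
    "ADE": "A", "URA": "U", "GUA": "G", "CYT": "C", "THY": "dT",
}
_CANONICAL_TO_PDB = {
    "A": "A", "U": "U", "G": "G", "C": "C",
    "dA": "DA", "dT": "DT", "dG": "DG", "dC": "DC",
}


def canonical_nucleoside(resname: str) -> Optional[str]:
    """Map a PDB residue name to a canonical nucleoside code, else None."""
    return _PDB_TO_CANONICAL.get(resname.strip().upper())


def residue_name_for(nucleoside: str) -> str:
    """PDB residue name of a canonical nucleoside code."""
    return _CANONICAL_TO_PDB[nucleoside]


@dataclass
class Atom:
    """One atom: PDB-style name, element symbol, Cartesian position (A)."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be nonempty")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(), self.occupancy)


@dataclass
class Residue:
    """A residue: nucleotide, amino acid, or other component.

    ``name`` is the canonical nucleoside code (``A`` ... ``dC``) for
    nucleotides and the PDB residue name otherwise.
    """

    name: str
    chain_id: str
    seq_id: int
    atoms: Dict[str, Atom] = field(default_factory=dict)

    @property
    def is_nucleotide(self) -> bool:
        return self.name in NUCLEOSIDES

    @property
    def is_purine(self) -> bool:
        return self.name in PURINES

    @property
    def is_pyrimidine(self) -> bool:
        return self.name in PYRIMIDINES

    @property
    def is_ribose(self) -> bool:
        return self.name in RIBONUCLEOSIDES

    @property
    def key(self) -> Tuple[str, int]:
        return (self.chain_id, self.seq_id)

    def add(self, atom: Atom) -> None:
        self.atoms[atom.name] = atom

    def coords(self, names: Iterable[str]) -> np.ndarray:
        """Stacked positions of the named atoms (raises on absence)."""
        return np.array([self.atoms[n].position for n in names])

    def heavy_atoms(self) -> List[Atom]:
        return [a for a in self.atoms.values() if a.element.upper() != "H"]

    def copy(self) -> "Residue":
        r = Residue(self.name, self.chain_id, self.seq_id)
        r.atoms = {n: a.copy() for n, a in self.atoms.items()}
        return r

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Residue":
        """Return a rigidly transformed copy."""
        r = self.copy()
        for a in r.atoms.values():
            a.position = rotation @ a.position + translation
        return r


class Structure:
    """Ordered residue collection with (chain, seq_id) lookup."""

    def __init__(self, residues: Optional[Iterable[Residue]] = None, name: str = ""):
        self.name = name
        self._residues: List[Residue] = []
        self._index: Dict[Tuple[str, int], Residue] = {}
        for r in residues or ():
            self.add(r)

    def add(self, res: Residue) -> None:
        if res.key in self._index:
            raise ValueError(f"duplicate residue key {res.key}")
        self._residues.append(res)
        self._index[res.key] = res

    def __iter__(self) -> Iterator[Residue]:
        return iter(self._residues)

    def __len__(self) -> int:
        return len(self._residues)

    def get(self, chain_id: str, seq_id: int) -> Optional[Residue]:
        return self._index.get((chain_id, seq_id))

    def __contains__(self, key: Tuple[str, int]) -> bool:
        return key in self._index

    @property
    def residues(self) -> List[Residue]:
        return list(self._residues)

    def chains(self) -> Dict[str, List[Residue]]:
        out: Dict[str, List[Residue]] = {}
        for r in self._residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def nucleotides(self) -> List[Residue]:
        return [r for r in self._residues if r.is_nucleotide]

    def atoms(self) -> Iterator[Tuple[Residue, Atom]]:
        for r in self._residues:
            for a in r.atoms.values():
                yield r, a

    def copy(self) -> "Structure":
        return Structure((r.copy() for r in self._residues), name=self.name)

    def replace(self, res: Residue) -> None:
        """Replace the residue with the same (chain, seq_id) key."""
        if res.key not in self._index:
            raise KeyError(f"no residue {res.key} to replace")
        i = next(i for i, r in enumerate(self._residues) if r.key == res.key)
        self._residues[i] = res
        self._index[res.key] = res
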