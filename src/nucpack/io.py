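"""Structure I/O (PDB / mmCIF via gemmi) and coordinate-sphere extraction."""

from __future__ import annotations

import logging
import os
from typing import Dict, List, Optional

import gemmi
import numpy as np

from .structure import Atom, Residue, Structure, canonical_nucleoside, residue_name_for

logger = logging.getLogger(__name__)

__all__ = [
    "read_structure",
    "write_structure",
    "extract_sphere",
    "centers_from_phosphates",
]


def _format_from_path(path: str, fmt: Optional[str]) -> str:
    if fmt:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lower()
    if ext in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_structure(path: str, fmt: Optional[str] = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model is used.  When a residue carries alternate
    conformers, the highest-occupancy altloc of each atom is kept and a
    warning is logged; nucleotide residue names are canonicalised
    (``DA`` -> ``dA`` etc.), everything else keeps its PDB name.
    """
    fmt = _format_from_path(path, fmt)
    try:
        if fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(path).sole_block())
        else:
            st = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"failed to parse {path} as {fmt}: {exc}") from exc
    st.setup_entities()
    out = Structure(name=st.name or os.path.basename(path))
    model = st[0]
    for chain in model:
        for res in chain:
            canon = canonical_nucleoside(res.name)
            rname = canon if canon else res.name.strip()
            residue = Residue(rname, chain.name, res.seqid.num)
            best: Dict[str, gemmi.Atom] = {}
            had_altloc = False
            for atom in res:
                if atom.altloc not in ("", "\0", "A" * 0):
                    had_altloc = had_altloc or atom.altloc != ""
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if had_altloc:
                logger.warning(
                    "residue %s/%s %s: alternate conformers present, "
                    "keeping highest occupancy",
                    chain.name, res.seqid.num, res.name,
                )
            for name, atom in best.items():
                residue.add(
                    Atom(
                        name,
                        atom.element.name,
                        np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                    )
                )
            if residue.atoms:
                out.add(residue)
    return out


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.name or "nucpack"
    model = gemmi.Model("1")
    chains: Dict[str, gemmi.Chain] = {}
    for res in structure:
        if res.chain_id not in chains:
            chains[res.chain_id] = gemmi.Chain(res.chain_id)
        gres = gemmi.Residue()
        gres.name = residue_name_for(res.name) if res.is_nucleotide else res.name
        gres.seqid = gemmi.SeqId(res.seq_id, " ")
        for atom in res.atoms.values():
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.position)
            ga.occ = atom.occupancy
            gres.add_atom(ga)
        chains[res.chain_id].add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str, fmt: Optional[str] = None) -> None:
    """Write a :class:`Structure` as PDB or mmCIF (chosen by extension)."""
    fmt = _format_from_path(path, fmt)
    st = _to_gemmi(structure)
    if fmt == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)


def extract_sphere(structure: Structure, center, radius: float = 30.0) -> Structure:
    """Residue-level coordinate-sphere extraction.

    A residue is retained when any of its atoms lies within ``radius``
    of ``center``; whole residues are kept so torsion descriptors stay
    computable for every retained nucleotide.  No crystallographic
    symmetry expansion is performed — inputs are assumed pre-expanded.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    out = Structure(name=f"{structure.name}:sphere")
    for res in structure:
        pos = np.array([a.position for a in res.atoms.values()])
        if np.min(np.linalg.norm(pos - center, axis=1)) <= radius:
            out.add(res.copy())
    if len(out) == 0:
        logger.warning("sphere extraction at %s produced no residues", center)
    return out


def centers_from_phosphates(structure: Structure, every_nth: int = 5) -> List[np.ndarray]:
    """Sphere centres: every n-th phosphorus atom of the nucleotide part."""
    if every_nth < 1:
        raise ValueError("every_nth must be >= 1")
    phosphates = [
        res.atoms["P"].position
        for res in structure
        if res.is_nucleotide and "P" in res.atoms
    ]
    return [p.copy() for p in phosphates[::every_nth]]
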