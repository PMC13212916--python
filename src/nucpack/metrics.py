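"""Model-vs-reference comparison metrics.

Implements the indicators used to score rebuilt nucleic-acid models
against reference coordinates on a shared rigid backbone frame:

* pooled side-chain RMSD with the backbone atom sets excluded
  (nucleotides: P, OP1, OP2, O5', C5', C4', C3', O3'; amino acids:
  N, CA, C, O, CB) and no superposition;
* chi recovery rate (fraction of positions with |delta chi| < 15 deg)
  and mean absolute circular delta chi;
* interaction network fidelity (INF) over base-pair and base-stack
  edges, the geometric mean of precision and recall;
* the local distance difference test (lDDT) with the standard 15 A
  inclusion radius and 0.5/1/2/4 A thresholds; and
* the fraction of native protein-nucleotide interface contacts
  preserved (F_nat, 5 A heavy-atom cutoff).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import bases
from .geom import chi_angle, circular_difference
from .structure import Residue, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "NUCLEOTIDE_BACKBONE",
    "PROTEIN_BACKBONE",
    "sidechain_rmsd",
    "recovery_rate",
    "mean_delta_chi",
    "delta_chi_list",
    "inf_score",
    "detect_interactions",
    "lddt",
    "fnat",
    "ComparisonReport",
    "compare",
]

NUCLEOTIDE_BACKBONE = frozenset({"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"})
PROTEIN_BACKBONE = frozenset({"N", "CA", "C", "O", "CB"})

RECOVERY_CUTOFF = 15.0  # deg, strict: a 15.0 deg deviation is NOT a match


def _included_atoms(res: Residue) -> List[str]:
    excl = NUCLEOTIDE_BACKBONE if res.is_nucleotide else PROTEIN_BACKBONE
    return sorted(
        n for n, a in res.atoms.items() if n not in excl and a.element.upper() != "H"
    )


def sidechain_rmsd(model: Structure, reference: Structure) -> float:
    """Pooled all-residue RMSD over included (non-backbone) atoms.

    No superposition is applied — model and reference are assumed to
    share the fixed backbone frame.  Residues whose included atom sets
    differ (e.g. after identity redesign) are skipped with a log
    message and do not contribute.
    """
    sq_sum = 0.0
    n_atoms = 0
    for ref in reference:
        mod = model.get(ref.chain_id, ref.seq_id)
        if mod is None:
            continue
        names_ref = _included_atoms(ref)
        names_mod = _included_atoms(mod)
        if names_ref != names_mod or mod.name != ref.name:
            logger.info(
                "residue %s/%s: atom sets differ (identity change?); excluded from RMSD",
                ref.chain_id, ref.seq_id,
            )
            continue
        if not names_ref:
            continue
        d = mod.coords(names_ref) - ref.coords(names_ref)
        sq_sum += float(np.sum(d * d))
        n_atoms += len(names_ref)
    if n_atoms == 0:
        raise ValueError("no comparable atoms between model and reference")
    return math.sqrt(sq_sum / n_atoms)


def delta_chi_list(model: Structure, reference: Structure) -> List[float]:
    """Absolute circular chi differences for shared same-identity nucleotides."""
    out = []
    for ref in reference:
        if not ref.is_nucleotide:
            continue
        mod = model.get(ref.chain_id, ref.seq_id)
        if mod is None or not mod.is_nucleotide or mod.name != ref.name:
            continue
        out.append(circular_difference(chi_angle(mod), chi_angle(ref)))
    return out


def recovery_rate(delta_chis: Sequence[float]) -> float:
    """Percentage of |delta chi| strictly below 15 deg."""
    if len(delta_chis) == 0:
        raise ValueError("recovery rate of an empty comparison is undefined")
    d = np.abs(np.asarray(delta_chis, dtype=float))
    d = np.minimum(d % 360.0, 360.0 - d % 360.0)
    return 100.0 * float(np.count_nonzero(d < RECOVERY_CUTOFF)) / len(d)


def mean_delta_chi(delta_chis: Sequence[float]) -> float:
    """Mean absolute circular chi difference in degrees."""
    if len(delta_chis) == 0:
        raise ValueError("mean delta chi of an empty comparison is undefined")
    d = np.abs(np.asarray(delta_chis, dtype=float))
    d = np.minimum(d % 360.0, 360.0 - d % 360.0)
    return float(np.mean(d))


def inf_score(tp: int, fp: int, fn: int) -> float:
    """Interaction network fidelity: sqrt(precision * recall).

    Returns 0 with a warning when either denominator is empty.
    """
    if tp + fp == 0 or tp + fn == 0:
        logger.warning("INF undefined (tp+fp=%d, tp+fn=%d); scoring 0", tp + fp, tp + fn)
        return 0.0
    return math.sqrt((tp / (tp + fp)) * (tp / (tp + fn)))


# -- geometric base-interaction detection -----------------------------------

PAIR_HBOND_CUTOFF = 3.4      # A, donor-acceptor heavy-atom distance
PAIR_MIN_HBONDS = 2
PLANE_ANGLE_CUTOFF = 30.0    # deg
STACK_CENTROID_CUTOFF = 4.5  # A
STACK_OFFSET_CUTOFF = 2.5    # A

Edge = Tuple[Tuple[str, int], Tuple[str, int], str]


def _base_frame(res: Residue):
    ring = bases.BASE_RING_ATOMS[bases.base_kind(res.name)]
    if any(n not in res.atoms for n in ring):
        return None
    pts = res.coords(ring)
    cen = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - cen)
    return cen, vt[2]


def _polar_atoms(res: Residue):
    return bases.base_polar_sites(res)


def _count_hbonds(res1: Residue, res2: Residue) -> int:
    n = 0
    for a, b in ((res1, res2), (res2, res1)):
        donors, _ = _polar_atoms(a)
        _, acceptors = _polar_atoms(b)
        for dpos, ante in donors:
            for apos in acceptors:
                dist = float(np.linalg.norm(dpos - apos))
                if dist > PAIR_HBOND_CUTOFF or dist < 2.0:
                    continue
                u = ante - dpos
                v = apos - dpos
                ang = math.degrees(
                    math.acos(
                        np.clip(
                            np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)),
                            -1.0, 1.0,
                        )
                    )
                )
                if ang >= 120.0:
                    n += 1
    return n


def detect_interactions(structure: Structure) -> Set[Edge]:
    """Base-pair and base-stack edges by geometric criteria.

    A pair edge requires at least two donor-acceptor contacts within
    3.4 A with reasonable donor angles and base planes within 30 deg;
    a stack edge requires ring centroids within 4.5 A, planes within
    30 deg, and a centroid offset along the plane normal axis below
    2.5 A laterally.
    """
    nts = [r for r in structure if r.is_nucleotide or r.name in ("A", "U", "G", "C")]
    frames = {}
    for r in nts:
        f = _base_frame(r)
        if f is not None:
            frames[r.key] = f
    edges: Set[Edge] = set()
    for i, r1 in enumerate(nts):
        if r1.key not in frames:
            continue
        c1, n1 = frames[r1.key]
        for r2 in nts[i + 1:]:
            if r2.key not in frames:
                continue
            c2, n2 = frames[r2.key]
            sep = float(np.linalg.norm(c1 - c2))
            if sep > 15.0:
                continue
            plane_ang = math.degrees(math.acos(np.clip(abs(np.dot(n1, n2)), 0, 1)))
            if plane_ang > PLANE_ANGLE_CUTOFF:
                continue
            key = (min(r1.key, r2.key), max(r1.key, r2.key))
            # stacking: near-parallel planes, small lateral offset
            if sep < STACK_CENTROID_CUTOFF:
                rise = abs(float(np.dot(c2 - c1, n1)))
                lateral = math.sqrt(max(sep * sep - rise * rise, 0.0))
                if rise > 2.0 and lateral < STACK_OFFSET_CUTOFF:
                    edges.add((key[0], key[1], "stack"))
                    continue
            if _count_hbonds(r1, r2) >= PAIR_MIN_HBONDS:
                edges.add((key[0], key[1], "pair"))
    return edges


def interaction_counts(model: Structure, reference: Structure) -> Tuple[int, int, int]:
    """(TP, FP, FN) of model vs reference interaction edges."""
    em = detect_interactions(model)
    er = detect_interactions(reference)
    tp = len(em & er)
    return tp, len(em - er), len(er - em)


def lddt(
    model: Structure,
    reference: Structure,
    inclusion_radius: float = 15.0,
    thresholds: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
) -> Tuple[Dict[Tuple[str, int], float], float]:
    """Local distance difference test, per residue and averaged.

    For each residue, the reference inter-residue heavy-atom distances
    below the inclusion radius are compared with the model; the score
    is the fraction preserved within each threshold, averaged over
    thresholds, and the structure score is the mean over residues.
    Superposition-free by construction.
    """
    ref_atoms: List[Tuple[Tuple[str, int], str, np.ndarray]] = []
    for res in reference:
        for name in _all_heavy(res):
            ref_atoms.append((res.key, name, res.atoms[name].position))
    pos_ref = np.array([p for _, _, p in ref_atoms]) if ref_atoms else np.zeros((0, 3))

    model_pos = {}
    for res in model:
        for name in _all_heavy(res):
            model_pos[(res.key, name)] = res.atoms[name].position

    per_res_hits: Dict[Tuple[str, int], List[float]] = {}
    n = len(ref_atoms)
    thr = np.asarray(thresholds, dtype=float)
    for i in range(n):
        key_i, name_i, pi = ref_atoms[i]
        mi = model_pos.get((key_i, name_i))
        for j in range(i + 1, n):
            key_j, name_j, pj = ref_atoms[j]
            if key_j == key_i:
                continue
            d_ref = float(np.linalg.norm(pi - pj))
            if d_ref >= inclusion_radius:
                continue
            mj = model_pos.get((key_j, name_j))
            if mi is None or mj is None:
                frac = 0.0
            else:
                diff = abs(float(np.linalg.norm(mi - mj)) - d_ref)
                frac = float(np.mean(diff < thr))
            per_res_hits.setdefault(key_i, []).append(frac)
            per_res_hits.setdefault(key_j, []).append(frac)
    per_res = {k: float(np.mean(v)) for k, v in per_res_hits.items()}
    mean = float(np.mean(list(per_res.values()))) if per_res else 0.0
    return per_res, mean


def _all_heavy(res: Residue) -> List[str]:
    return sorted(n for n, a in res.atoms.items() if a.element.upper() != "H")


def _interface_contacts(structure: Structure, cutoff: float) -> Set[Tuple]:
    prot = [r for r in structure if not r.is_nucleotide]
    nucs = [r for r in structure if r.is_nucleotide]
    contacts = set()
    for p in prot:
        ppos = np.array([a.position for a in p.heavy_atoms()])
        if len(ppos) == 0:
            continue
        for q in nucs:
            qpos = np.array([a.position for a in q.heavy_atoms()])
            if len(qpos) == 0:
                continue
            d = np.linalg.norm(ppos[:, None, :] - qpos[None, :, :], axis=2)
            if np.min(d) < cutoff:
                contacts.add((p.key, q.key))
    return contacts


def fnat(model: Structure, reference: Structure, contact_cutoff: float = 5.0) -> float:
    """Fraction of native protein-nucleotide interface contacts preserved."""
    native = _interface_contacts(reference, contact_cutoff)
    if not native:
        raise ValueError("reference has no protein-nucleotide interface contacts")
    modeled = _interface_contacts(model, contact_cutoff)
    return len(native & modeled) / len(native)


@dataclass
class ComparisonReport:
    """Bundle of all comparison metrics for one model/reference pair."""

    overall_rmsd: float
    recovery_pct: float
    mean_delta_chi: float
    inf: float
    mean_lddt: float
    fnat: Optional[float]
    per_residue: Dict[Tuple[str, int], Dict[str, float]] = field(default_factory=dict)


def compare(
    model: Structure, reference: Structure, interface: bool = False
) -> ComparisonReport:
    """Compute the full metric suite for a model/reference pair."""
    deltas = delta_chi_list(model, reference)
    tp, fp, fn = interaction_counts(model, reference)
    per_res_lddt, mean_lddt = lddt(model, reference)
    per_residue: Dict[Tuple[str, int], Dict[str, float]] = {}
    for ref in reference:
        if ref.is_nucleotide and model.get(ref.chain_id, ref.seq_id) is not None:
            mod = model.get(ref.chain_id, ref.seq_id)
            row: Dict[str, float] = {}
            if mod.name == ref.name:
                row["delta_chi"] = circular_difference(chi_angle(mod), chi_angle(ref))
            if ref.key in per_res_lddt:
                row["lddt"] = per_res_lddt[ref.key]
            per_residue[ref.key] = row
    return ComparisonReport(
        overall_rmsd=sidechain_rmsd(model, reference),
        recovery_pct=recovery_rate(deltas) if deltas else float("nan"),
        mean_delta_chi=mean_delta_chi(deltas) if deltas else float("nan"),
        inf=inf_score(tp, fp, fn),
        mean_lddt=mean_lddt,
        fnat=fnat(model, reference) if interface else None,
        per_residue=per_residue,
    )
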