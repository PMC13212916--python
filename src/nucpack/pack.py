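"""Energy-driven candidate selection (side-chain packing) for nucleotides.

One candidate per designable position is selected so that the sum of
self and pairwise interaction energies approximates the global minimum
energy conformation (GMEC).  The search combines provably sound
dead-end elimination (Goldstein singles criterion) with either
exhaustive enumeration of the residual space (when small enough) or
Monte Carlo / simulated annealing.

The energy function is deliberately simple and pluggable: a capped
6-12 Lennard-Jones term over heavy atoms, a distance- and angle-gated
hydrogen-bond bonus between donor/acceptor heavy atoms, and a rotamer
prior proportional to -ln(library probability).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import bases
from .build import RotamerCandidate
from .structure import Residue, Structure

__all__ = [
    "EnergyModel",
    "EnergyTables",
    "PackPosition",
    "Solution",
    "compute_tables",
    "dee_goldstein",
    "mcsa",
    "exhaustive",
    "solve",
]

#: Per-element Lennard-Jones parameters: (r_min/2 in A, well depth kcal/mol).
LJ_PARAMS: Dict[str, Tuple[float, float]] = {
    "C": (1.70, 0.10),
    "N": (1.55, 0.16),
    "O": (1.52, 0.20),
    "P": (1.80, 0.20),
    "S": (1.80, 0.25),
    "H": (1.00, 0.02),
}

INTERACTION_CUTOFF = 8.0  # A, all-atom pair cutoff
HBOND_MIN = 2.6
HBOND_MAX = 3.4
HBOND_ANGLE_MIN = 120.0  # deg at the donor

#: Search-policy threshold: exhaustive enumeration below this many
#: residual combinations, Monte Carlo / simulated annealing above.
EXHAUSTIVE_LIMIT = 10**6


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the packing energy function."""

    clash_cap: float = 10.0     # kcal/mol ceiling per atom pair
    hbond_weight: float = 3.0   # kcal/mol bonus per hydrogen bond
    prior_weight: float = 0.5   # multiplier on -ln(library probability)
    cutoff: float = INTERACTION_CUTOFF

    def __post_init__(self) -> None:
        if self.clash_cap <= 0 or not math.isfinite(self.clash_cap):
            raise ValueError("clash_cap must be finite and positive")
        if self.hbond_weight < 0 or self.prior_weight < 0:
            raise ValueError("energy weights must be nonnegative")


@dataclass
class PackPosition:
    """A designable position with its candidate set."""

    key: Tuple[str, int]
    candidates: List[RotamerCandidate]
    designable: bool = False  # identity variable (vs orientation-only)

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError(f"position {self.key} has no candidates")


class EnergyTables:
    """Self and pairwise energies of all candidates, i < j."""

    def __init__(
        self,
        self_e: List[np.ndarray],
        pair_e: Dict[Tuple[int, int], np.ndarray],
    ):
        self.self_e = self_e
        self.pair_e = pair_e
        self.n_positions = len(self_e)

    def pair(self, i: int, j: int) -> Optional[np.ndarray]:
        """Pair table as an (n_i, n_j) array, or None when decoupled."""
        if i < j:
            return self.pair_e.get((i, j))
        t = self.pair_e.get((j, i))
        return None if t is None else t.T

    def energy(self, assignment: Sequence[int]) -> float:
        total = sum(float(self.self_e[i][a]) for i, a in enumerate(assignment))
        for (i, j), table in self.pair_e.items():
            total += float(table[assignment[i], assignment[j]])
        return total


@dataclass
class Solution:
    assignment: Tuple[int, ...]
    total_energy: float
    method: str  # EXHAUSTIVE, DEE_EXHAUSTIVE or DEE_MCSA


# ---------------------------------------------------------------------------
# energy evaluation
# ---------------------------------------------------------------------------


#: Contact-distance scale for polar (N/O) atom pairs: hydrogen-bonded
#: heavy atoms legitimately approach to ~2.7-3.0 A, inside the sum of
#: their van der Waals radii.
POLAR_PAIR_SCALE = 0.85


def _atom_table(atoms) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Positions, r_min/2, well depths and polar flags of an atom list."""
    pos = np.array([a.position for a in atoms]) if atoms else np.zeros((0, 3))
    params = [LJ_PARAMS.get(a.element.upper(), LJ_PARAMS["C"]) for a in atoms]
    radii = np.array([p[0] for p in params])
    eps = np.array([p[1] for p in params])
    polar = np.array([a.element.upper() in ("N", "O") for a in atoms], dtype=bool)
    return pos, radii, eps, polar


def _lj_energy(
    pos1, radii1, eps1, polar1, pos2, radii2, eps2, polar2, model: EnergyModel
) -> float:
    if len(pos1) == 0 or len(pos2) == 0:
        return 0.0
    d = np.linalg.norm(pos1[:, None, :] - pos2[None, :, :], axis=2)
    mask = d < model.cutoff
    if not np.any(mask):
        return 0.0
    rmin = radii1[:, None] + radii2[None, :]
    rmin = np.where(polar1[:, None] & polar2[None, :], rmin * POLAR_PAIR_SCALE, rmin)
    eps = np.sqrt(eps1[:, None] * eps2[None, :])
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 1e-6, rmin / np.maximum(d, 1e-6), 1e3)
        e = eps * (ratio**12 - 2.0 * ratio**6)
    e = np.minimum(e, model.clash_cap)
    return float(np.sum(e[mask]))


def _polar_sites(res: Residue):
    """(donor position, antecedent position) list and acceptor positions.

    Base donors/acceptors come from the nucleobase annotation tables;
    the ribose 2'-hydroxyl acts as both donor and acceptor.
    """
    donors: List[Tuple[np.ndarray, np.ndarray]] = []
    acceptors: List[np.ndarray] = []
    if res.is_nucleotide:
        donors, acceptors = bases.base_polar_sites(res)
        if "O2'" in res.atoms and "C2'" in res.atoms:
            donors.append((res.atoms["O2'"].position, res.atoms["C2'"].position))
            acceptors.append(res.atoms["O2'"].position)
    else:
        # generic polar heavy atoms of non-nucleotide residues
        for a in res.atoms.values():
            if a.element.upper() in ("N", "O"):
                acceptors.append(a.position)
    return donors, acceptors


def _hbond_energy(sites1, sites2, model: EnergyModel) -> float:
    total = 0.0
    for (donors_a, _), (_, acceptors_b) in ((sites1, sites2), (sites2, sites1)):
        for dpos, ante in donors_a:
            for apos in acceptors_b:
                dist = float(np.linalg.norm(dpos - apos))
                if not HBOND_MIN <= dist <= HBOND_MAX:
                    continue
                u = ante - dpos
                v = apos - dpos
                cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                if math.degrees(math.acos(np.clip(cosv, -1, 1))) >= HBOND_ANGLE_MIN:
                    total -= model.hbond_weight
    return total


def _candidate_energy_atoms(cand: RotamerCandidate):
    """Atoms a candidate contributes to interactions: the rebuilt
    (non-main-chain) atoms.  Main-chain atoms are shared with the fixed
    backbone frame and handled as environment."""
    return cand.sidechain_atoms()


def compute_tables(
    positions: Sequence[PackPosition],
    environment: Structure,
    model: EnergyModel = EnergyModel(),
) -> EnergyTables:
    """Self and pair energy tables for a packing problem.

    ``environment`` supplies the fixed context; residues whose key
    matches a designable position are excluded from it automatically
    (their rebuilt atoms are represented by the candidates).
    """
    pos_keys = {p.key for p in positions}
    env_res = [r for r in environment if r.key not in pos_keys]
    env_atoms = [a for r in env_res for a in r.heavy_atoms()]
    env_tab = _atom_table(env_atoms)
    env_sites_by_res = [_polar_sites(r) for r in env_res]

    cand_atoms = []
    cand_sites = []
    for p in positions:
        atoms_list = [_candidate_energy_atoms(c) for c in p.candidates]
        cand_atoms.append([_atom_table(a) for a in atoms_list])
        cand_sites.append([_polar_sites(c.residue) for c in p.candidates])

    self_e: List[np.ndarray] = []
    for pi, p in enumerate(positions):
        e = np.zeros(len(p.candidates))
        for ci, cand in enumerate(p.candidates):
            tab = cand_atoms[pi][ci]
            val = _lj_energy(*tab, *env_tab, model)
            for er, sites in zip(env_res, env_sites_by_res):
                if _near(tab[0], er):
                    val += _hbond_energy(cand_sites[pi][ci], sites, model)
            val += model.prior_weight * (-math.log(max(cand.library_probability, 1e-12)))
            e[ci] = val
        self_e.append(e)

    pair_e: Dict[Tuple[int, int], np.ndarray] = {}
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            table = np.zeros((len(positions[i].candidates), len(positions[j].candidates)))
            any_nonzero = False
            for a in range(table.shape[0]):
                for b in range(table.shape[1]):
                    val = _lj_energy(*cand_atoms[i][a], *cand_atoms[j][b], model)
                    val += _hbond_energy(cand_sites[i][a], cand_sites[j][b], model)
                    if val != 0.0:
                        any_nonzero = True
                    table[a, b] = val
            if any_nonzero:
                pair_e[(i, j)] = table
    return EnergyTables(self_e, pair_e)


def _near(pos1: np.ndarray, res: Residue, cutoff: float = INTERACTION_CUTOFF) -> bool:
    if len(pos1) == 0 or not res.atoms:
        return False
    rpos = np.array([a.position for a in res.atoms.values()])
    return bool(
        np.min(np.linalg.norm(pos1[:, None, :] - rpos[None, :, :], axis=2)) < cutoff
    )


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def dee_goldstein(
    tables: EnergyTables, alive: Optional[List[np.ndarray]] = None
) -> List[np.ndarray]:
    """Iterated Goldstein singles dead-end elimination.

    A candidate ``a`` at position ``i`` is eliminated when some
    competitor ``b`` satisfies
    ``E(i,a) - E(i,b) + sum_j min_c [E(ia,jc) - E(ib,jc)] > 0``;
    such a candidate cannot belong to any GMEC.  Returns boolean alive
    masks per position.
    """
    n = tables.n_positions
    if alive is None:
        alive = [np.ones(len(s), dtype=bool) for s in tables.self_e]
    changed = True
    while changed:
        changed = False
        for i in range(n):
            idx = np.flatnonzero(alive[i])
            if len(idx) <= 1:
                continue
            for a in idx:
                if not alive[i][a]:
                    continue
                for b in idx:
                    if a == b or not alive[i][b]:
                        continue
                    gap = tables.self_e[i][a] - tables.self_e[i][b]
                    for j in range(n):
                        if j == i:
                            continue
                        t = tables.pair(i, j)
                        if t is None:
                            continue
                        cols = np.flatnonzero(alive[j])
                        gap += np.min(t[a, cols] - t[b, cols])
                    if gap > 1e-12:
                        alive[i][a] = False
                        changed = True
                        break
            if not np.any(alive[i]):
                raise RuntimeError(f"DEE emptied position {i}: criterion bug")
    return alive


def exhaustive(
    tables: EnergyTables, alive: Optional[List[np.ndarray]] = None
) -> Tuple[Tuple[int, ...], float]:
    """Lexicographic exhaustive minimisation over the (pruned) space."""
    if alive is None:
        alive = [np.ones(len(s), dtype=bool) for s in tables.self_e]
    choices = [list(np.flatnonzero(m)) for m in alive]
    best = None
    best_e = math.inf
    for combo in itertools.product(*choices):
        e = tables.energy(combo)
        if e < best_e - 1e-12:
            best_e = e
            best = combo
    return tuple(best), best_e


def mcsa(
    tables: EnergyTables,
    schedule: Tuple[float, float, int] = (10.0, 0.05, 20000),
    seed: int = 0,
    restarts: int = 3,
    alive: Optional[List[np.ndarray]] = None,
) -> Solution:
    """Monte Carlo / simulated annealing with geometric cooling.

    Single-position moves under the Metropolis criterion; the best
    assignment ever seen is returned.  Deterministic for a fixed seed.
    """
    if alive is None:
        alive = [np.ones(len(s), dtype=bool) for s in tables.self_e]
    choices = [list(np.flatnonzero(m)) for m in alive]
    n = tables.n_positions
    t_start, t_end, steps = schedule
    cool = (t_end / t_start) ** (1.0 / max(steps - 1, 1))
    rng = np.random.default_rng(seed)
    best: Optional[Tuple[int, ...]] = None
    best_e = math.inf
    for _ in range(restarts):
        assign = [c[rng.integers(len(c))] for c in choices]
        e = tables.energy(assign)
        if e < best_e:
            best, best_e = tuple(assign), e
        temp = t_start
        for _ in range(steps):
            i = int(rng.integers(n))
            if len(choices[i]) == 1:
                temp *= cool
                continue
            new_c = choices[i][int(rng.integers(len(choices[i])))]
            if new_c == assign[i]:
                temp *= cool
                continue
            delta = tables.self_e[i][new_c] - tables.self_e[i][assign[i]]
            for j in range(n):
                if j == i:
                    continue
                t = tables.pair(i, j)
                if t is not None:
                    delta += t[new_c, assign[j]] - t[assign[i], assign[j]]
            if delta < 0 or rng.random() < math.exp(-delta / max(temp, 1e-9)):
                assign[i] = new_c
                e += delta
                if e < best_e - 1e-12:
                    best, best_e = tuple(assign), e
            temp *= cool
    # re-evaluate exactly to avoid drift from incremental updates
    return Solution(best, tables.energy(best), "DEE_MCSA")


def solve(
    structure: Structure,
    positions: Sequence[PackPosition],
    model: EnergyModel = EnergyModel(),
    seed: int = 0,
) -> Tuple[Solution, Structure]:
    """Select one candidate per position and splice the result.

    Pipeline: energy tables -> dead-end elimination -> exhaustive
    enumeration when the residual space is at most 10^6 combinations,
    Monte Carlo / simulated annealing otherwise.  Ties are broken
    lexicographically by (position, candidate) index, so the output is
    deterministic.
    """
    tables = compute_tables(positions, structure, model)
    alive = dee_goldstein(tables)
    space = 1
    for m in alive:
        space *= int(np.count_nonzero(m))
    if space <= EXHAUSTIVE_LIMIT:
        assignment, energy = exhaustive(tables, alive)
        solution = Solution(assignment, energy, "DEE_EXHAUSTIVE")
    else:
        solution = mcsa(tables, seed=seed, alive=alive)
    out = structure.copy()
    for p, ci in zip(positions, solution.assignment):
        chosen = p.candidates[ci].residue.copy()
        chosen.chain_id, chosen.seq_id = p.key
        if p.key in out._index:
            out.replace(chosen)
        else:
            out.add(chosen)
    return solution, out
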