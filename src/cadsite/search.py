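"""Combinatorial search for multi-residue Cd2+ sites.

Candidate coordination residues whose standard metal positions nearly
coincide (and whose placements do not collide) form the coordination pair
library - the compatibility graph.  Set reduction iteratively removes
candidates with fewer than three compatible partners, then a depth-first
clique enumeration yields every 4- or 5-residue combination with at least
two cysteine mutations whose averaged metal position keeps every member at
acceptable geometry or better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import GeometryParameterSet, evaluate_geometry
from .rotamers import SIDECHAIN_ELEMENTS, CoordinationResidue
from .scaffold import VDW_DEFAULT, VDW_RADII

log = logging.getLogger("cadsite")

DEFAULT_PAIR_DISTANCE = 1.6
SOLUTION_SIZES = (4, 5)
MIN_CYSTEINES = 2


@dataclass(frozen=True)
class CoordinationPair:
    """Two compatible candidates and their closest metal-position match."""

    a: int                 # library indices, a < b
    b: int
    pos_a: int             # metal-position indices within each entry
    pos_b: int
    distance: float


@dataclass
class MetalSiteSolution:
    member_indices: tuple[int, ...]
    members: tuple[CoordinationResidue, ...]
    chosen_positions: tuple[int, ...]
    cd_initial: np.ndarray
    cd_final: np.ndarray | None = None
    evaluations: tuple = ()
    score: float | None = None
    breakdown: list = field(default_factory=list)

    @property
    def n_cys(self) -> int:
        return sum(m.is_cys_mutation for m in self.members)

    def member_set_key(self):
        return tuple(sorted(m.sort_key() for m in self.members))

    def mutation_key(self):
        """(position, restype) identity used for reporting/recovery."""
        return tuple(
            sorted(
                (m.position, "bbO" if m.kind == "backbone_oxygen" else m.restype_new)
                for m in self.members
            )
        )


def _mutual_clash(
    a: CoordinationResidue, b: CoordinationResidue, tolerance: float
) -> bool:
    if not a.placed_atoms or not b.placed_atoms:
        return False
    for na, xa in a.placed_atoms.items():
        ra = VDW_RADII.get(SIDECHAIN_ELEMENTS.get(na, "C"), VDW_DEFAULT)
        for nb, xb in b.placed_atoms.items():
            rb = VDW_RADII.get(SIDECHAIN_ELEMENTS.get(nb, "C"), VDW_DEFAULT)
            if np.linalg.norm(xa - xb) < ra + rb - tolerance:
                return True
    return False


def build_pair_library(
    library: list[CoordinationResidue],
    d_max: float = DEFAULT_PAIR_DISTANCE,
    clash_tolerance: float = 0.5,
) -> list[CoordinationPair]:
    """All candidate pairs at distinct scaffold positions whose closest
    metal positions lie within d_max and whose side chains are mutually
    clash-free."""
    flat = []
    for i, entry in enumerate(library):
        for k, mp in enumerate(entry.metal_positions):
            flat.append((i, k, mp.xyz))
    if not flat:
        return []
    coords = np.asarray([f[2] for f in flat])
    tree = cKDTree(coords)
    best: dict[tuple[int, int], tuple[float, int, int]] = {}
    for ia, ib in tree.query_pairs(d_max):
        ea, ka, xa = flat[ia]
        eb, kb, xb = flat[ib]
        if ea == eb or library[ea].position == library[eb].position:
            continue
        if ea > eb:
            ea, eb, ka, kb, xa, xb = eb, ea, kb, ka, xb, xa
        d = float(np.linalg.norm(xa - xb))
        if d >= d_max:
            continue
        key = (ea, eb)
        if key not in best or d < best[key][0]:
            best[key] = (d, ka, kb)
    pairs = []
    for (ea, eb) in sorted(best):
        d, ka, kb = best[(ea, eb)]
        if _mutual_clash(library[ea], library[eb], clash_tolerance):
            continue
        pairs.append(CoordinationPair(ea, eb, ka, kb, d))
    return pairs


def reduce_library(
    library: list[CoordinationResidue], pairs: list[CoordinationPair]
) -> tuple[list[int], list[CoordinationPair]]:
    """Iterated degree pruning to a fixpoint.

    A candidate's co-coordination number is its count of compatible
    partners at distinct scaffold positions; anything below 3 can never sit
    in a 4-residue site and is removed, the pair library updated, until
    stable.  Returns (kept library indices, surviving pairs); the fixpoint
    is independent of removal order.
    """
    alive = set(range(len(library)))
    current = list(pairs)
    while True:
        partners: dict[int, set[int]] = {i: set() for i in alive}
        for p in current:
            if p.a in alive and p.b in alive:
                partners[p.a].add(library[p.b].position)
                partners[p.b].add(library[p.a].position)
        drop = {i for i in alive if len(partners[i]) < 3}
        if not drop:
            break
        alive -= drop
        current = [p for p in current if p.a in alive and p.b in alive]
    return sorted(alive), current


def average_metal_position(positions: np.ndarray | list) -> np.ndarray:
    """Unweighted arithmetic mean of the members' chosen metal positions."""
    return np.mean(np.asarray(positions, float), axis=0)


def choose_member_positions(
    members: list[CoordinationResidue],
) -> tuple[tuple[int, ...], np.ndarray]:
    """Pick one metal position per member so all crowd one centroid.

    Deterministic fixed point: start from each member's first-listed
    position, then repeatedly re-choose the position nearest the running
    centroid (ties to the lower index) until stable.
    """
    chosen = [0] * len(members)
    for _ in range(10):
        centroid = average_metal_position(
            [m.metal_positions[c].xyz for m, c in zip(members, chosen)]
        )
        new = []
        for m in members:
            dists = [np.linalg.norm(mp.xyz - centroid) for mp in m.metal_positions]
            new.append(int(np.argmin(dists)))
        if new == chosen:
            break
        chosen = new
    centroid = average_metal_position(
        [m.metal_positions[c].xyz for m, c in zip(members, chosen)]
    )
    return tuple(chosen), centroid


def default_geometry_check(
    members: list[CoordinationResidue],
    cd: np.ndarray,
    params: GeometryParameterSet,
) -> bool:
    """Every member must evaluate at least 'acceptable' at the metal point."""
    return all(
        evaluate_geometry(m.modes, cd, params).verdict != "fail" for m in members
    )


def enumerate_solutions(
    library: list[CoordinationResidue],
    pairs: list[CoordinationPair],
    params: GeometryParameterSet | None = None,
    sizes=SOLUTION_SIZES,
    min_cys: int = MIN_CYSTEINES,
    geometry_check=None,
) -> list[MetalSiteSolution]:
    """Depth-first enumeration of coordination-site solutions.

    A solution is a clique of 4 or 5 candidates in the pair graph at
    distinct scaffold positions with >= min_cys cysteine mutations whose
    averaged metal position passes the geometry check for every member.
    Output is deterministic: members in canonical library order, duplicate
    member sets emitted once.
    """
    if geometry_check is None:
        if params is None:
            raise ValueError("need params or an explicit geometry_check")
        geometry_check = lambda members, cd: default_geometry_check(  # noqa: E731
            members, cd, params
        )

    n = len(library)
    order = sorted(range(n), key=lambda i: library[i].sort_key())
    rank = {idx: r for r, idx in enumerate(order)}
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for p in pairs:
        adj[p.a].add(p.b)
        adj[p.b].add(p.a)

    max_size = max(sizes)
    solutions: list[MetalSiteSolution] = []
    seen: set = set()

    def extend(clique: list[int], candidates: list[int], cys_count: int):
        size = len(clique)
        if size in sizes and cys_count >= min_cys:
            members = [library[i] for i in clique]
            chosen, cd_initial = choose_member_positions(members)
            if geometry_check(members, cd_initial):
                sol = MetalSiteSolution(
                    tuple(clique), tuple(members), chosen, cd_initial
                )
                key = sol.member_set_key()
                if key not in seen:
                    seen.add(key)
                    solutions.append(sol)
        if size == max_size:
            return
        # prune: even taking every remaining candidate cannot reach min_cys
        remaining_cys = sum(library[c].is_cys_mutation for c in candidates)
        if cys_count + remaining_cys < min_cys:
            return
        used_positions = {library[i].position for i in clique}
        for idx, c in enumerate(candidates):
            if library[c].position in used_positions:
                continue
            nxt = [
                d
                for d in candidates[idx + 1 :]
                if d in adj[c] and library[d].position != library[c].position
            ]
            extend(
                clique + [c], nxt, cys_count + int(library[c].is_cys_mutation)
            )

    roots = sorted(range(n), key=lambda i: rank[i])
    for r_i, i in enumerate(roots):
        cands = sorted((j for j in adj[i] if rank[j] > rank[i]), key=lambda j: rank[j])
        extend([i], cands, int(library[i].is_cys_mutation))

    solutions.sort(key=lambda s: s.member_set_key())
    return solutions
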