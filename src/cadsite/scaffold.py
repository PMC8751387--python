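"""Scaffold handling: structure input, domain assignment, interface detection,
mutability masking.

The design strategy places a Cd2+ site at the interface between the two
domains of a periplasmic binding protein, so that metal binding biases the
open/closed equilibrium.  This module turns a PDB file into the package's
in-memory scaffold, labels each residue with its domain, finds the
inter-domain interface (Calpha within a cutoff of the opposite domain) and
derives the set of positions that may be mutated to coordination residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

log = logging.getLogger("cadsite")

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: heavy-atom van der Waals radii (Angstrom) used by every clash rule
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
VDW_DEFAULT = 1.70

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class ScaffoldError(Exception):
    """Fatal problem with the input structure or the domain definition."""


@dataclass
class Residue:
    chain: str
    number: int
    name: str
    atoms: dict[str, np.ndarray]
    elements: dict[str, str]

    @property
    def backbone_complete(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def __getitem__(self, atom: str) -> np.ndarray:
        return self.atoms[atom]


@dataclass
class DomainDefinition:
    """Inclusive residue-number intervals for the two domains."""

    domain_i_ranges: list[tuple[int, int]]
    domain_ii_ranges: list[tuple[int, int]]

    def domain_of(self, number: int) -> str | None:
        in_i = any(lo <= number <= hi for lo, hi in self.domain_i_ranges)
        in_ii = any(lo <= number <= hi for lo, hi in self.domain_ii_ranges)
        if in_i and in_ii:
            raise ScaffoldError(f"residue {number} claimed by both domains")
        if in_i:
            return "I"
        if in_ii:
            return "II"
        return None


#: the ribose-binding-protein scaffold split used throughout the study
RBP_DOMAINS = DomainDefinition(
    domain_i_ranges=[(1, 103), (236, 263)],
    domain_ii_ranges=[(104, 235), (264, 271)],
)


@dataclass
class MutabilityMask:
    """Positions that must never be mutated: prolines and the hinge, whose
    conformation carries the open/closed motion."""

    excluded_restypes: frozenset[str] = frozenset({"PRO"})
    excluded_ranges: tuple[tuple[int, int], ...] = ((102, 104), (234, 236), (263, 265))

    def excludes(self, residue: Residue) -> bool:
        if residue.name in self.excluded_restypes:
            return True
        return any(lo <= residue.number <= hi for lo, hi in self.excluded_ranges)


RBP_MASK = MutabilityMask()


@dataclass
class Scaffold:
    residues: list[Residue]
    domain_assignment: dict[int, str] = field(default_factory=dict)
    incomplete: set[int] = field(default_factory=set)
    _index: dict[int, Residue] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {r.number: r for r in self.residues}
        if len(self._index) != len(self.residues):
            raise ScaffoldError("duplicate residue numbers in chain")
        self.incomplete = {r.number for r in self.residues if not r.backbone_complete}

    def residue(self, number: int) -> Residue:
        return self._index[number]

    def __contains__(self, number: int) -> bool:
        return number in self._index

    def numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    # ---- flat heavy-atom arrays for neighbour searches -------------------
    def atom_table(self):
        """(coords (N,3), residue numbers (N,), atom names, is_backbone flags)."""
        coords, nums, names, bb = [], [], [], []
        for r in self.residues:
            for name, xyz in r.atoms.items():
                coords.append(xyz)
                nums.append(r.number)
                names.append(name)
                bb.append(name in BACKBONE_ATOMS)
        return (
            np.asarray(coords, float),
            np.asarray(nums, int),
            names,
            np.asarray(bb, bool),
        )

    def vdw_radii_array(self) -> np.ndarray:
        radii = []
        for r in self.residues:
            for name in r.atoms:
                radii.append(VDW_RADII.get(r.elements[name], VDW_DEFAULT))
        return np.asarray(radii, float)

    def kdtree(self) -> cKDTree:
        coords, _, _, _ = self.atom_table()
        return cKDTree(coords)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_structure(path, model_index: int = 0, chain: str = "A") -> Scaffold:
    """Read one protein chain from a PDB file into a Scaffold.

    Waters, heteroatoms and existing ligands are dropped; alternate
    conformations are resolved to the highest-occupancy conformer; residues
    missing any backbone atom are kept but flagged incomplete (they are
    excluded from mutation and coordination downstream).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()  # keeps highest-occupancy altloc
    st.remove_hydrogens()
    if len(st) == 0:
        raise ScaffoldError(f"no models in {path}")
    model = st[min(model_index, len(st) - 1)]
    chains = [ch.name for ch in model]
    if chain not in chains:
        raise ScaffoldError(f"chain {chain!r} not found (have {chains})")

    residues: list[Residue] = []
    for res in model[chain]:
        if res.name not in AMINO_ACIDS:
            continue  # waters, ribose, ions, modified residues
        if res.seqid.icode.strip():
            raise ScaffoldError(
                f"insertion code on residue {res.seqid.num}{res.seqid.icode}: "
                "plain author numbering is required"
            )
        atoms, elements = {}, {}
        for at in res:
            if at.element.name == "H":
                continue
            if at.name in atoms:
                continue
            atoms[at.name] = np.array([at.pos.x, at.pos.y, at.pos.z], float)
            elements[at.name] = at.element.name or at.name[0]
        residues.append(Residue(chain, res.seqid.num, res.name, atoms, elements))

    if not residues:
        raise ScaffoldError(f"chain {chain!r} has no amino-acid residues")
    sc = Scaffold(residues)
    for n in sorted(sc.incomplete):
        log.warning("residue %d lacks a backbone atom; excluded from design", n)
    coords, *_ = sc.atom_table()
    if not np.isfinite(coords).all():
        raise ScaffoldError("non-finite coordinates in input")
    return sc


def assign_domains(scaffold: Scaffold, definition: DomainDefinition) -> Scaffold:
    """Populate the residue -> {I, II} map; unassigned residues are fatal."""
    assignment = {}
    for res in scaffold.residues:
        dom = definition.domain_of(res.number)
        if dom is None:
            raise ScaffoldError(f"residue {res.number} belongs to neither domain")
        assignment[res.number] = dom
    scaffold.domain_assignment = assignment
    return scaffold


def find_interface(scaffold: Scaffold, cutoff: float = 12.0) -> set[int]:
    """Residues whose Calpha lies within `cutoff` of any Calpha of the
    opposite domain."""
    if not scaffold.domain_assignment:
        raise ScaffoldError("domains not assigned")
    nums, cas, doms = [], [], []
    for res in scaffold.residues:
        if "CA" not in res.atoms:
            raise ScaffoldError(f"residue {res.number} has no CA")
        nums.append(res.number)
        cas.append(res.atoms["CA"])
        doms.append(scaffold.domain_assignment[res.number])
    cas = np.asarray(cas, float)
    doms = np.asarray(doms)
    out: set[int] = set()
    for dom_a, dom_b in (("I", "II"), ("II", "I")):
        a = np.where(doms == dom_a)[0]
        b = np.where(doms == dom_b)[0]
        if len(a) == 0 or len(b) == 0:
            continue
        tree = cKDTree(cas[b])
        dists, _ = tree.query(cas[a], k=1)
        for idx, d in zip(a, dists):
            if d <= cutoff:
                out.add(nums[idx])
    return out


def apply_mutability(
    scaffold: Scaffold, mask: MutabilityMask, interface: set[int]
) -> set[int]:
    """Mutable set = interfacial residues minus masked ones minus residues
    with incomplete backbones."""
    out = set()
    for n in interface:
        res = scaffold.residue(n)
        if mask.excludes(res) or n in scaffold.incomplete:
            continue
        out.add(n)
    return out
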