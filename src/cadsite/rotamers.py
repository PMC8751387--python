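"""Rotamer-based candidate placement.

Loads a backbone-dependent (Dunbrack-style) rotamer library, perturbs the
local backbone with the backrub move, rebuilds candidate coordination side
chains (Cys, His, Asp, Glu) from ideal internal coordinates and rotamer chi
angles, screens them for steric clashes, and assembles the coordination
residue library - every clash-free placement annotated with its candidate
Cd2+ positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._geom import dihedral_deg, nerf, rotation_about_axis
from .geometry import (
    GeometryParameterSet,
    MetalPosition,
    modes_for,
    generate_metal_positions,
)
from .scaffold import BACKBONE_ATOMS, VDW_DEFAULT, VDW_RADII, Scaffold

log = logging.getLogger("cadsite")

COORDINATION_TYPES = ("CYS", "HIS", "ASP", "GLU")
N_CHI = {"CYS": 1, "HIS": 2, "ASP": 2, "GLU": 3}

DEFAULT_BACKRUB_ANGLES = (-6.0, 0.0, 6.0)


class RotamerLibraryError(Exception):
    pass


@dataclass(frozen=True)
class Rotamer:
    restype: str
    phi_bin: int
    psi_bin: int
    chi: tuple[float, ...]
    probability: float


class RotamerLibrary:
    """Lookup by residue type and 10-degree-binned (phi, psi)."""

    BIN = 10

    def __init__(self, entries: dict[tuple[str, int, int], list[Rotamer]]):
        self._entries = entries

    @staticmethod
    def bin_angle(angle: float) -> int:
        b = int(round(angle / RotamerLibrary.BIN)) * RotamerLibrary.BIN
        if b == 180:
            b = -180
        return b

    def query(self, restype: str, phi: float, psi: float) -> list[Rotamer]:
        key = (restype, self.bin_angle(phi), self.bin_angle(psi))
        return list(self._entries.get(key, ()))

    def __len__(self) -> int:
        return sum(len(v) for v in self._entries.values())


def load_rotamer_library(path) -> RotamerLibrary:
    """Parse a Dunbrack bbdep-style whitespace table.

    Columns: restype phi psi count r1 r2 r3 r4 probability chi1..chi4
    [sig1..sig4]; '#' lines are comments.  Rotamers are stored sorted by
    descending probability; only the four coordination types are kept.
    """
    entries: dict[tuple[str, int, int], list[Rotamer]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                restype = parts[0].upper()
                phi, psi = float(parts[1]), float(parts[2])
                prob = float(parts[8])
                chis = tuple(float(x) for x in parts[9:13])
            except (IndexError, ValueError) as exc:
                raise RotamerLibraryError(f"{path}:{lineno}: malformed row") from exc
            if restype not in COORDINATION_TYPES:
                continue
            if not 0.0 < prob <= 1.0:
                raise RotamerLibraryError(
                    f"{path}:{lineno}: probability {prob} outside (0, 1]"
                )
            key = (
                restype,
                RotamerLibrary.bin_angle(phi),
                RotamerLibrary.bin_angle(psi),
            )
            rot = Rotamer(restype, key[1], key[2], chis[: N_CHI[restype]], prob)
            entries.setdefault(key, []).append(rot)
    for rots in entries.values():
        rots.sort(key=lambda r: (-r.probability, r.chi))
    return RotamerLibrary(entries)


# ---------------------------------------------------------------------------
# backrub
# ---------------------------------------------------------------------------

def backrub_variants(
    scaffold: Scaffold, position: int, angles=DEFAULT_BACKRUB_ANGLES
):
    """Local backbone variants of residue `position`.

    For each angle theta the segment between the flanking Calphas -
    C and O of residue i-1, all atoms of residue i, N of residue i+1 -
    is rotated rigidly by theta about the Ca(i-1)-Ca(i+1) axis; the pivots
    themselves never move.  Returns [(theta, {(resnum, atom): xyz})];
    theta = 0 always yields an empty override map.  Terminal residues with
    no flanking Calpha yield only the theta = 0 variant.
    """
    prev_n, next_n = position - 1, position + 1
    have_pivots = (
        prev_n in scaffold
        and next_n in scaffold
        and "CA" in scaffold.residue(prev_n).atoms
        and "CA" in scaffold.residue(next_n).atoms
    )
    if not have_pivots:
        log.debug("position %d lacks flanking CA; backrub limited to 0", position)
        return [(0.0, {})]

    ca_prev = scaffold.residue(prev_n)["CA"]
    ca_next = scaffold.residue(next_n)["CA"]
    moving: list[tuple[int, str]] = []
    for name in ("C", "O"):
        if name in scaffold.residue(prev_n).atoms:
            moving.append((prev_n, name))
    for name in scaffold.residue(position).atoms:
        moving.append((position, name))
    if "N" in scaffold.residue(next_n).atoms:
        moving.append((next_n, "N"))

    out = []
    for theta in angles:
        if theta == 0.0:
            out.append((0.0, {}))
            continue
        rot = rotation_about_axis(ca_prev, ca_next - ca_prev, theta)
        overrides = {
            (num, name): rot(scaffold.residue(num)[name]) for num, name in moving
        }
        out.append((theta, overrides))
    return out


def backbone_dihedrals(scaffold: Scaffold, position: int) -> tuple[float, float] | None:
    """(phi, psi) of a residue from the unperturbed backbone, or None at
    chain termini."""
    prev_n, next_n = position - 1, position + 1
    res = scaffold.residue(position)
    if prev_n not in scaffold or next_n not in scaffold:
        return None
    prev, nxt = scaffold.residue(prev_n), scaffold.residue(next_n)
    needed = ("C" in prev.atoms, res.backbone_complete, "N" in nxt.atoms)
    if not all(needed):
        return None
    phi = dihedral_deg(prev["C"], res["N"], res["CA"], res["C"])
    psi = dihedral_deg(res["N"], res["CA"], res["C"], nxt["N"])
    return phi, psi


# ---------------------------------------------------------------------------
# side-chain construction (ideal internal coordinates + rotamer chi)
# ---------------------------------------------------------------------------

# atom: (ref1, ref2, ref3, bond, angle, torsion); torsion is either a fixed
# number, 'chiN', or ('chiN', offset).  CB is common to all four types.
_CB = ("CB", ("C", "N", "CA", 1.530, 110.5, 122.6))

SIDECHAIN_TOPOLOGY: dict[str, list[tuple[str, tuple]]] = {
    "CYS": [
        _CB,
        ("SG", ("N", "CA", "CB", 1.810, 114.0, "chi1")),
    ],
    "HIS": [
        _CB,
        ("CG", ("N", "CA", "CB", 1.500, 113.8, "chi1")),
        ("ND1", ("CA", "CB", "CG", 1.380, 122.7, "chi2")),
        ("CD2", ("CA", "CB", "CG", 1.360, 129.8, ("chi2", 180.0))),
        ("CE1", ("CB", "CG", "ND1", 1.320, 109.2, 180.0)),
        ("NE2", ("CB", "CG", "CD2", 1.370, 107.2, 180.0)),
    ],
    "ASP": [
        _CB,
        ("CG", ("N", "CA", "CB", 1.516, 112.6, "chi1")),
        ("OD1", ("CA", "CB", "CG", 1.249, 118.4, "chi2")),
        ("OD2", ("CA", "CB", "CG", 1.249, 118.4, ("chi2", 180.0))),
    ],
    "GLU": [
        _CB,
        ("CG", ("N", "CA", "CB", 1.520, 114.1, "chi1")),
        ("CD", ("CA", "CB", "CG", 1.516, 112.6, "chi2")),
        ("OE1", ("CB", "CG", "CD", 1.249, 118.4, "chi3")),
        ("OE2", ("CB", "CG", "CD", 1.249, 118.4, ("chi3", 180.0))),
    ],
}

SIDECHAIN_ELEMENTS = {
    "CB": "C", "SG": "S", "CG": "C", "CD": "C", "ND1": "N", "CD2": "C",
    "CE1": "C", "NE2": "N", "OD1": "O", "OD2": "O", "OE1": "O", "OE2": "O",
}


def build_sidechain_atoms(
    backbone: dict[str, np.ndarray], restype: str, chi: tuple[float, ...]
) -> dict[str, np.ndarray]:
    """Heavy-atom side chain from ideal internal coordinates and chi angles,
    anchored on an N-CA-C backbone given as a name -> coordinate dict."""
    if restype not in SIDECHAIN_TOPOLOGY:
        raise ValueError(f"{restype} is not a coordination residue type")
    if len(chi) != N_CHI[restype]:
        raise ValueError(
            f"{restype} needs {N_CHI[restype]} chi angles, got {len(chi)}"
        )
    placed: dict[str, np.ndarray] = {}

    def ref(name: str) -> np.ndarray:
        return placed[name] if name in placed else backbone[name]

    chimap = {f"chi{i + 1}": v for i, v in enumerate(chi)}
    for atom, (r1, r2, r3, bond, ang, tor) in SIDECHAIN_TOPOLOGY[restype]:
        if isinstance(tor, str):
            torsion = chimap[tor]
        elif isinstance(tor, tuple):
            torsion = chimap[tor[0]] + tor[1]
        else:
            torsion = tor
        placed[atom] = nerf(ref(r1), ref(r2), ref(r3), bond, ang, torsion)
    return placed


def assemble_side_chain(
    scaffold: Scaffold,
    position: int,
    restype_new: str,
    chi: tuple[float, ...],
    backbone_override: dict | None = None,
) -> dict[str, np.ndarray]:
    """Rebuild the heavy-atom side chain of `restype_new` at a position.

    Anchored on the residue's (possibly backrub-perturbed) N-CA-C backbone;
    deterministic for fixed inputs.  Returns atom name -> coordinates for
    the new side chain only.
    """
    backbone_override = backbone_override or {}
    res = scaffold.residue(position)
    backbone = {
        name: backbone_override.get((position, name), res[name])
        for name in ("N", "CA", "C")
    }
    return build_sidechain_atoms(backbone, restype_new, chi)


# ---------------------------------------------------------------------------
# clash screening
# ---------------------------------------------------------------------------

class ClashContext:
    """Prebuilt scaffold atom arrays + KD-tree for repeated clash queries."""

    def __init__(self, scaffold: Scaffold, tolerance: float = 0.5):
        self.scaffold = scaffold
        self.tolerance = tolerance
        self.coords, self.resnums, self.names, self.is_backbone = scaffold.atom_table()
        self.radii = scaffold.vdw_radii_array()
        self.tree = cKDTree(self.coords)
        self.max_query = float(self.radii.max()) + max(VDW_RADII.values())

    def clashes(self, placed: dict[str, np.ndarray], position: int) -> bool:
        """True if any placed atom overlaps a scaffold heavy atom.

        The candidate's own residue is excluded entirely (its native side
        chain is conceptually stripped by the mutation) as are the backbone
        atoms of the two flanking residues bonded to the anchor.
        """
        for name, xyz in placed.items():
            r_new = VDW_RADII.get(SIDECHAIN_ELEMENTS.get(name, "C"), VDW_DEFAULT)
            idx = self.tree.query_ball_point(xyz, r_new + self.max_query)
            for i in idx:
                num = self.resnums[i]
                if num == position:
                    continue
                if num in (position - 1, position + 1) and self.is_backbone[i]:
                    continue
                limit = r_new + self.radii[i] - self.tolerance
                if np.linalg.norm(xyz - self.coords[i]) < limit:
                    return True
        return False

    def metal_clear(self, xyz: np.ndarray, position: int, floor: float) -> bool:
        """True if a metal position keeps >= floor from every protein heavy
        atom outside its own residue."""
        for i in self.tree.query_ball_point(xyz, floor):
            if self.resnums[i] != position:
                return False
        return True


def clash_check(
    placed: dict[str, np.ndarray],
    scaffold: Scaffold,
    position: int,
    tolerance: float = 0.5,
    context: ClashContext | None = None,
) -> bool:
    """Pass/fail steric screen; True means clash-free."""
    ctx = context if context is not None else ClashContext(scaffold, tolerance)
    return not ctx.clashes(placed, position)


# ---------------------------------------------------------------------------
# coordination residue library
# ---------------------------------------------------------------------------

@dataclass
class CoordinationResidue:
    position: int
    kind: str                       # 'sidechain_mutation' | 'backbone_oxygen'
    restype_new: str
    rotamer: Rotamer | None
    rotamer_index: int
    backrub_angle: float
    placed_atoms: dict[str, np.ndarray]
    modes: list = field(default_factory=list)
    metal_positions: list[MetalPosition] = field(default_factory=list)

    @property
    def probability(self) -> float:
        return self.rotamer.probability if self.rotamer else 1.0

    @property
    def is_cys_mutation(self) -> bool:
        return self.kind == "sidechain_mutation" and self.restype_new == "CYS"

    @property
    def score_type(self) -> str:
        return self.modes[0].score_type if self.modes else "backbone_o"

    def sort_key(self):
        return (
            self.position,
            self.kind,
            self.restype_new,
            self.rotamer_index,
            self.backrub_angle,
        )

    def label(self) -> str:
        if self.kind == "backbone_oxygen":
            return f"{self.position}:bbO"
        return (
            f"{self.position}:{self.restype_new}"
            f"/r{self.rotamer_index}/b{self.backrub_angle:+.0f}"
        )


def build_coordination_library(
    scaffold: Scaffold,
    mutable: set[int],
    interface: set[int],
    rotlib: RotamerLibrary,
    params: GeometryParameterSet,
    p_min: float = 0.01,
    clash_tolerance: float = 0.5,
    backrub_angles=DEFAULT_BACKRUB_ANGLES,
) -> list[CoordinationResidue]:
    """Enumerate every viable coordination candidate.

    mutable position x coordination type x rotamer (p >= p_min) x backrub
    angle, keeping clash-free placements with at least one surviving metal
    position; plus one backbone-carbonyl candidate per interfacial residue
    with a complete backbone (masked residues included - contributing a
    backbone oxygen requires no mutation).
    """
    ctx = ClashContext(scaffold, clash_tolerance)
    floor = params.metal_clash_floor
    library: list[CoordinationResidue] = []
    rejections = {"no_rotamers": 0, "clash": 0, "no_metal_position": 0}

    def surviving_positions(modes, position):
        kept = []
        for mp in generate_metal_positions(modes, params):
            if ctx.metal_clear(mp.xyz, position, floor):
                kept.append(mp)
        return kept

    for position in sorted(mutable):
        if scaffold.residue(position).number in scaffold.incomplete:
            continue
        dihedrals = backbone_dihedrals(scaffold, position)
        variants = backrub_variants(scaffold, position, backrub_angles)
        for restype in COORDINATION_TYPES:
            if dihedrals is None:
                rotamers: list[Rotamer] = []
            else:
                rotamers = [
                    r
                    for r in rotlib.query(restype, *dihedrals)
                    if r.probability >= p_min
                ]
            if not rotamers:
                rejections["no_rotamers"] += 1
                continue
            for ridx, rot in enumerate(rotamers):
                for theta, override in variants:
                    placed = assemble_side_chain(
                        scaffold, position, restype, rot.chi, override
                    )
                    if ctx.clashes(placed, position):
                        rejections["clash"] += 1
                        continue
                    res = scaffold.residue(position)
                    atoms = {
                        n: override.get((position, n), res[n])
                        for n in BACKBONE_ATOMS
                    }
                    atoms.update(placed)
                    modes = modes_for("sidechain_mutation", restype, atoms)
                    positions = surviving_positions(modes, position)
                    if not positions:
                        rejections["no_metal_position"] += 1
                        continue
                    library.append(
                        CoordinationResidue(
                            position, "sidechain_mutation", restype,
                            rot, ridx, theta, placed, modes, positions,
                        )
                    )

    for position in sorted(interface):
        res = scaffold.residue(position)
        if not res.backbone_complete:
            continue
        atoms = {n: res[n] for n in BACKBONE_ATOMS}
        modes = modes_for("backbone_oxygen", res.name, atoms)
        positions = surviving_positions(modes, position)
        if not positions:
            rejections["no_metal_position"] += 1
            continue
        library.append(
            CoordinationResidue(
                position, "backbone_oxygen", res.name, None, 0, 0.0, {}, modes,
                positions,
            )
        )

    library.sort(key=CoordinationResidue.sort_key)
    if not library:
        raise RuntimeError(
            f"coordination residue library is empty; rejections: {rejections}"
        )
    log.info(
        "coordination library: %d entries (rejections %s)", len(library), rejections
    )
    return library
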