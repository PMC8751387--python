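"""Synthetic test fixtures: a desk-scale scaffold with a geometrically
planted Cd2+ coordination site.

The generator works backwards from a chosen metal point.  For each planted
member it builds a template residue with ideal backbone geometry, rebuilds
the target side chain from chosen rotamer chi angles, forward-generates the
member's standard metal positions, and then rigidly re-poses the whole
residue so that one of those positions lands exactly on the metal point
with the residue body along an assigned outward direction.  Because every
pipeline step is rigid-motion invariant, re-running the design on the
resulting scaffold reproduces the planted site with perfect geometry at
zero noise.

Decoy residues are posed on a surrounding shell, side chains pointing
outward, so their candidate metal positions can never crowd a common
centre.  The matching mini rotamer library (planted chi values plus decoy
rotamers, emitted over a small phi/psi-bin neighbourhood) and the geometry
parameter file are written alongside the scaffold, so the whole pipeline is
testable with no downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from ._geom import nerf, unit
from .geometry import (
    GeometryParameterSet,
    default_parameter_text,
    generate_metal_positions,
    modes_for,
)
from .rotamers import RotamerLibrary, build_sidechain_atoms
from .scaffold import DomainDefinition, MutabilityMask

PLANTED_MEMBER_TYPES = ("CYS", "HIS", "ASP", "GLU", "BBO")

#: outward member directions: tetrahedral for four, trigonal-bipyramidal for five
_TETRA = [
    np.array([1.0, 1.0, 1.0]) / np.sqrt(3),
    np.array([1.0, -1.0, -1.0]) / np.sqrt(3),
    np.array([-1.0, 1.0, -1.0]) / np.sqrt(3),
    np.array([-1.0, -1.0, 1.0]) / np.sqrt(3),
]
_TRIG_BIPY = [
    np.array([0.0, 0.0, 1.0]),
    np.array([0.0, 0.0, -1.0]),
    np.array([1.0, 0.0, 0.0]),
    np.array([-0.5, np.sqrt(3) / 2, 0.0]),
    np.array([-0.5, -np.sqrt(3) / 2, 0.0]),
]

#: decoy shell directions: the twelve cube-edge midpoints
_EDGE_DIRECTIONS = [
    unit(np.array(v, float))
    for v in [
        (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
        (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
        (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
    ]
]

DECOY_SHELL_RADIUS = 9.0

#: planted rotamer chi angles (and the index of the metal position the
#: member donates through, within the generation order of its modes)
_PLANTED_CHI = {
    "CYS": (-65.0,),
    "HIS": (-60.0, 90.0),
    "ASP": (-70.0, 20.0),
    "GLU": (-60.0, 180.0, -40.0),
}
_DECOY_CHI = {
    "CYS": (55.0,),
    "GLU": (60.0, -175.0, 45.0),
}
_PLANTED_PROB = 0.6
_PLANTED_ALT_PROB = 0.3
_DECOY_PROB = 0.5


class FixtureError(Exception):
    pass


@dataclass
class FixtureSpec:
    planted: tuple[str, ...] = ("CYS", "CYS", "GLU", "BBO")
    noise_sigma: float = 0.0
    n_decoys: int = 12
    seed: int = 0
    metal: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def validate(self):
        k = len(self.planted)
        if k != 0 and not 4 <= k <= 5:
            raise FixtureError(f"planted site must have 4-5 members, got {k}")
        for t in self.planted:
            if t not in PLANTED_MEMBER_TYPES:
                raise FixtureError(f"unknown planted member type {t!r}")
        if not 0 <= self.n_decoys <= len(_EDGE_DIRECTIONS):
            raise FixtureError(
                f"n_decoys must be in [0, {len(_EDGE_DIRECTIONS)}]"
            )
        if self.noise_sigma < 0:
            raise FixtureError("noise sigma must be non-negative")


@dataclass
class FixtureBundle:
    scaffold_path: Path
    rotlib_path: Path
    params_path: Path
    domain_definition: DomainDefinition
    mask: MutabilityMask
    chain: str
    planted_key: tuple          # ground truth, MetalSiteSolution.mutation_key form
    planted_positions: tuple[int, ...]
    metal: np.ndarray
    n_residues: int = 0
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _template_backbone() -> dict[str, np.ndarray]:
    n = np.array([-0.525, 1.363, 0.0])
    ca = np.zeros(3)
    c = np.array([1.526, 0.0, 0.0])
    o = nerf(n, ca, c, 1.231, 120.5, -45.0)
    return {"N": n, "CA": ca, "C": c, "O": o}


def _with_cb(atoms: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = dict(atoms)
    out["CB"] = nerf(atoms["C"], atoms["N"], atoms["CA"], 1.530, 110.5, 122.6)
    return out


def _align_rotation(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector v_from onto v_to."""
    from scipy.spatial.transform import Rotation

    a, b = unit(v_from), unit(v_to)
    cross = np.cross(a, b)
    dot = float(np.dot(a, b))
    if np.linalg.norm(cross) < 1e-12:
        if dot > 0:
            return np.eye(3)
        # pick any perpendicular axis for a 180 degree flip
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = unit(np.cross(a, perp))
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = unit(cross)
    ang = np.arccos(np.clip(dot, -1.0, 1.0))
    return Rotation.from_rotvec(ang * axis).as_matrix()


def _pose_planted_member(
    member_type: str,
    direction: np.ndarray,
    metal: np.ndarray,
    params: GeometryParameterSet,
    occupied: list[np.ndarray],
) -> tuple[dict[str, np.ndarray], tuple[float, ...] | None]:
    """Backbone atoms (world frame) of one planted member, plus the chi
    angles the mini library must offer (None for a backbone-oxygen member).

    The residue is free to spin about its metal->body axis; that roll is
    chosen deterministically to maximize clearance from the members already
    placed (`occupied`: their world-frame atom coordinates)."""
    from scipy.spatial.transform import Rotation

    bb = _template_backbone()
    if member_type == "BBO":
        atoms = dict(bb)
        modes = modes_for("backbone_oxygen", "ALA", atoms)
        chi = None
    else:
        chi = _PLANTED_CHI[member_type]
        atoms = dict(bb)
        atoms.update(build_sidechain_atoms(bb, member_type, chi))
        modes = modes_for("sidechain_mutation", member_type, atoms)
    positions = generate_metal_positions(modes, params)
    if not positions:
        raise FixtureError(f"no metal positions for planted {member_type}")
    # donate through the last generated position: for carboxylates that is
    # the bidentate site, for Cys the trans torsion, for backbone O the
    # second lone pair - any fixed deterministic choice works
    mp = positions[-1]
    anchor = mp.xyz
    body = unit(atoms["CA"] - anchor)
    align = _align_rotation(body, direction)
    full = _with_cb(bb)
    full.update(atoms)

    def posed(roll_deg: float) -> dict[str, np.ndarray]:
        spin = Rotation.from_rotvec(np.radians(roll_deg) * direction).as_matrix()
        return {
            name: spin @ (align @ (xyz - anchor)) + metal
            for name, xyz in full.items()
        }

    best_roll, best_clearance = 0.0, -1.0
    for roll in range(0, 360, 15):
        world = posed(float(roll))
        if occupied:
            clearance = min(
                float(np.linalg.norm(x - o))
                for x in world.values()
                for o in occupied
            )
        else:
            clearance = 0.0
        if clearance > best_clearance:
            best_roll, best_clearance = float(roll), clearance
    world = posed(best_roll)
    occupied.extend(world.values())
    placed_bb = {name: world[name] for name in ("N", "CA", "C", "O", "CB")}
    return placed_bb, chi


def _pose_decoy(direction: np.ndarray) -> dict[str, np.ndarray]:
    bb = _with_cb(_template_backbone())
    rot = _align_rotation(bb["CB"] - bb["CA"], direction)
    ca = DECOY_SHELL_RADIUS * direction
    return {name: rot @ (xyz - bb["CA"]) + ca for name, xyz in bb.items()}


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def _write_pdb(residues: list[tuple[int, str, dict[str, np.ndarray]]], path: Path):
    st = gemmi.Structure()
    st.name = "cadsite synthetic fixture"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    for number, name, atoms in residues:
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(number, " ")
        for an in ("N", "CA", "C", "O", "CB"):
            if an not in atoms:
                continue
            at = gemmi.Atom()
            at.name = an
            at.element = gemmi.Element(elements[an])
            at.pos = gemmi.Position(*atoms[an])
            at.occ = 1.0
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())


def _rotlib_rows(restype: str, phi: float, psi: float, prob: float, chi, spread: int):
    """Rows for one rotamer over a (2*spread+1)^2 phi/psi-bin neighbourhood,
    absorbing noise-induced dihedral shifts."""
    rows = []
    chi4 = list(chi) + [0.0] * (4 - len(chi))
    pb = RotamerLibrary.bin_angle(phi)
    sb = RotamerLibrary.bin_angle(psi)
    for dp in range(-spread, spread + 1):
        for ds in range(-spread, spread + 1):
            p = RotamerLibrary.bin_angle(pb + 10 * dp)
            s = RotamerLibrary.bin_angle(sb + 10 * ds)
            chis = " ".join(f"{c:8.1f}" for c in chi4)
            rows.append(
                f"{restype} {p:5d} {s:5d}  999  1 1 1 1  {prob:.4f} {chis}"
                f"  {'  8.0' * 4}"
            )
    return rows


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_fixture(spec: FixtureSpec, out_dir) -> FixtureBundle:
    """Write scaffold PDB, mini rotamer library and parameter file; return
    the bundle with the planted ground truth."""
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = GeometryParameterSet.default()
    metal = np.asarray(spec.metal, float)

    k = len(spec.planted)
    member_dirs = _TRIG_BIPY if k == 5 else _TETRA
    n = k + spec.n_decoys
    if n < 8:
        raise FixtureError("fixture needs at least 8 residues total")

    # planted members sit at evenly spaced interior sequence slots
    if k:
        planted_slots = [2 + round(i * (n - 3) / (k - 1)) for i in range(k)]
    else:
        planted_slots = []
    if len(set(planted_slots)) != k:
        raise FixtureError("too few decoys to separate planted members")

    member_bb: dict[int, tuple[str, dict, tuple | None]] = {}
    occupied: list[np.ndarray] = []
    for i, (mtype, slot) in enumerate(zip(spec.planted, planted_slots)):
        bb, chi = _pose_planted_member(mtype, member_dirs[i], metal, params, occupied)
        member_bb[slot] = (mtype, bb, chi)

    half = n // 2
    dom = DomainDefinition([(1, half)], [(half + 1, n)])

    # assign decoy directions: each decoy leans toward a planted direction
    # of the opposite domain so the whole shell stays interfacial
    decoy_slots = [s for s in range(1, n + 1) if s not in member_bb]
    opposite_dirs = {
        "I": [member_dirs[i] for i, s in enumerate(planted_slots) if s > half],
        "II": [member_dirs[i] for i, s in enumerate(planted_slots) if s <= half],
    }
    available = list(range(len(_EDGE_DIRECTIONS)))
    decoy_dir: dict[int, np.ndarray] = {}
    for s in decoy_slots:
        domain = "I" if s <= half else "II"
        targets = opposite_dirs[domain] or member_dirs
        best_i = max(
            available,
            key=lambda i: max(float(np.dot(_EDGE_DIRECTIONS[i], t)) for t in targets),
        )
        available.remove(best_i)
        decoy_dir[s] = _EDGE_DIRECTIONS[best_i]

    residues = []
    for s in range(1, n + 1):
        if s in member_bb:
            _, bb, _ = member_bb[s]
            residues.append((s, "ALA", dict(bb)))
        else:
            residues.append((s, "ALA", _pose_decoy(decoy_dir[s])))

    # noise: each residue's backbone is displaced rigidly by sigma times a
    # standard-normal 3-vector; the field is drawn once per seed and scaled
    # by sigma, so a given seed degrades monotonically as sigma grows
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        field = rng.standard_normal((len(residues), 3))
        for (_, _, atoms), shift in zip(residues, field):
            for name in atoms:
                atoms[name] = atoms[name] + spec.noise_sigma * shift

    scaffold_path = out / "scaffold.pdb"
    _write_pdb(residues, scaffold_path)

    # ---- mini rotamer library -------------------------------------------
    # rows are emitted for the noise-free dihedrals: recompute them from an
    # unjittered rebuild so the library does not chase the noise
    clean = {}
    for s in range(1, n + 1):
        if s in member_bb:
            clean[s] = member_bb[s][1]
        else:
            clean[s] = _pose_decoy(decoy_dir[s])
    def clean_phi_psi(slot: int):
        if not (1 < slot < n):
            return None
        from ._geom import dihedral_deg
        return (
            dihedral_deg(clean[slot - 1]["C"], clean[slot]["N"], clean[slot]["CA"], clean[slot]["C"]),
            dihedral_deg(clean[slot]["N"], clean[slot]["CA"], clean[slot]["C"], clean[slot + 1]["N"]),
        )

    spread = 2
    rows: dict[str, None] = {}  # insertion-ordered de-duplication
    for s, (mtype, _, chi) in sorted(member_bb.items()):
        if chi is None:
            continue
        pp = clean_phi_psi(s)
        if pp is None:
            raise FixtureError(f"planted member at terminal slot {s}")
        for row in _rotlib_rows(mtype, *pp, _PLANTED_PROB, chi, spread):
            rows[row] = None
        alt = tuple(c + 115.0 for c in chi)
        for row in _rotlib_rows(mtype, *pp, _PLANTED_ALT_PROB, alt, spread):
            rows[row] = None
    for s in decoy_slots:
        pp = clean_phi_psi(s)
        if pp is None:
            continue
        for rt, chi in _DECOY_CHI.items():
            for row in _rotlib_rows(rt, *pp, _DECOY_PROB, chi, spread):
                rows[row] = None

    rotlib_path = out / "rotamers.txt"
    rotlib_path.write_text(
        "# synthetic backbone-dependent mini rotamer library\n"
        + "\n".join(rows)
        + "\n"
    )

    params_path = out / "cd_geometry.ini"
    params_path.write_text(default_parameter_text())

    planted_key = tuple(
        sorted(
            (slot, "bbO" if mtype == "BBO" else mtype)
            for slot, (mtype, _, _) in member_bb.items()
        )
    )
    return FixtureBundle(
        scaffold_path=scaffold_path,
        rotlib_path=rotlib_path,
        params_path=params_path,
        domain_definition=dom,
        mask=MutabilityMask(excluded_ranges=()),
        chain="A",
        planted_key=planted_key,
        planted_positions=tuple(sorted(member_bb)),
        metal=metal,
        n_residues=n,
    )
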