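"""Cd2+ coordination geometry: standard metal-position generation and the
two-level (perfect / acceptable) geometric evaluation.

Every coordinating group defines a local frame (three reference atoms); an
ideal metal position is the NeRF placement at the configured bond length,
bond angle and dihedral(s) in that frame.  Evaluation measures the same
parameters for an arbitrary metal position and classifies each one as
perfect, acceptable or fail by membership in two nested windows.  All ideal
values, window half-widths, per-type discrete scores and type weights live
in a plain-text parameter file, never in code.

Coordination chemistry covered:

* Cys SG         - thiolate; a configurable fan of dihedral directions about
                   the CB-SG bond (the Cd-S torsion is soft).
* His ND1 / NE2  - imidazole nitrogens; one in-plane position each, along
                   the exterior lone-pair bisector.
* Asp/Glu        - carboxylate; one bidentate position on the in-plane O-C-O
                   bisector axis plus three monodentate sp2 lone-pair
                   positions (anti of each oxygen and one syn representative
                   - the two syn lobes flank the same inter-oxygen face).
* backbone O     - carbonyl; the two in-plane sp2 lone pairs.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from ._geom import angle_deg, circular_diff_deg, dihedral_deg, nerf, unit

__all__ = [
    "GeometryParameterSet",
    "GeometryEvaluation",
    "CoordinationMode",
    "MetalPosition",
    "modes_for",
    "generate_metal_positions",
    "evaluate_geometry",
    "default_parameter_text",
]

VERDICT_ORDER = {"fail": 0, "acceptable": 1, "perfect": 2}


class ParameterError(Exception):
    """Malformed or inconsistent geometry parameter file."""


@dataclass(frozen=True)
class Window:
    """Ideal value with nested perfect/acceptable half-widths (closed)."""

    ideal: float
    perfect: float
    acceptable: float

    def classify(self, deviation: float) -> str:
        if deviation <= self.perfect:
            return "perfect"
        if deviation <= self.acceptable:
            return "acceptable"
        return "fail"


@dataclass
class GeometryParameterSet:
    windows: dict[str, dict[str, Window]]        # mode key -> param name -> window
    gen_dihedrals: dict[str, tuple[float, ...]]  # mode key (+variant) -> torsions
    weights: dict[str, float]                    # score type -> w of the quality term
    scores: dict[str, tuple[float, float]]       # score type -> (perfect, acceptable)
    metal_clash_floor: float = 2.0

    def window(self, mode_key: str, param: str) -> Window:
        return self.windows[mode_key][param]

    @classmethod
    def from_text(cls, text: str) -> "GeometryParameterSet":
        cp = configparser.ConfigParser()
        cp.read_file(io.StringIO(text))
        windows: dict[str, dict[str, Window]] = {}
        gen: dict[str, tuple[float, ...]] = {}
        for section in cp.sections():
            if section in ("weights", "scores", "limits"):
                continue
            windows[section] = {}
            for key, raw in cp.items(section):
                vals = [float(x) for x in raw.split()]
                if key.startswith("gen_dihedrals"):
                    variant = key.removeprefix("gen_dihedrals").lstrip("_")
                    gen[f"{section}:{variant}" if variant else section] = tuple(vals)
                    continue
                if len(vals) != 3:
                    raise ParameterError(
                        f"[{section}] {key}: expected 'ideal perfect acceptable'"
                    )
                w = Window(*vals)
                if w.perfect < 0 or w.acceptable < w.perfect:
                    raise ParameterError(
                        f"[{section}] {key}: perfect window must nest in acceptable"
                    )
                if key.startswith("bond") and not (1.5 < w.ideal < 3.5):
                    raise ParameterError(
                        f"[{section}] {key}: bond length {w.ideal} outside (1.5, 3.5)"
                    )
                windows[section][key] = w
        weights = {k: float(v) for k, v in cp.items("weights")}
        scores = {}
        for k, v in cp.items("scores"):
            hi, lo = (float(x) for x in v.split())
            if not hi > lo:
                raise ParameterError(
                    f"[scores] {k}: perfect score must exceed acceptable score"
                )
            scores[k] = (hi, lo)
        floor = 2.0
        if cp.has_section("limits"):
            floor = cp.getfloat("limits", "metal_clash_floor", fallback=2.0)
        return cls(windows, gen, weights, scores, floor)

    @classmethod
    def from_file(cls, path) -> "GeometryParameterSet":
        with open(path) as fh:
            return cls.from_text(fh.read())

    @classmethod
    def default(cls) -> "GeometryParameterSet":
        return cls.from_text(default_parameter_text())


def default_parameter_text() -> str:
    return (
        resources.files("cadsite")
        .joinpath("params/cd_geometry.ini")
        .read_text()
    )


# ---------------------------------------------------------------------------
# coordination modes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoordinationMode:
    """One way a placed residue can donate to the metal.

    `frame` holds the reference coordinates the parameters are measured in:
    for single-atom modes (x, y, z) with z the donor atom; for the bidentate
    carboxylate (ante, c, o1, o2).
    """

    key: str                 # parameter-file section
    score_type: str          # weight / discrete-score bucket
    donor_atoms: tuple[str, ...]
    frame: tuple[np.ndarray, ...]
    variant: str = ""        # 'o1' / 'o2' for carboxylate oxygens


@dataclass(frozen=True)
class MetalPosition:
    xyz: np.ndarray
    mode: CoordinationMode


def modes_for(kind: str, restype: str, atoms: dict[str, np.ndarray]) -> list[CoordinationMode]:
    """Coordination modes available to a placed residue.

    `kind` is 'sidechain_mutation' or 'backbone_oxygen'; `atoms` maps atom
    names (backbone plus rebuilt side chain) to coordinates.
    """
    if kind == "backbone_oxygen":
        return [
            CoordinationMode(
                "backbone_o", "backbone_o", ("O",),
                (atoms["CA"], atoms["C"], atoms["O"]),
            )
        ]
    if restype == "CYS":
        return [
            CoordinationMode(
                "cys_sg", "cys", ("SG",), (atoms["CA"], atoms["CB"], atoms["SG"])
            )
        ]
    if restype == "HIS":
        return [
            CoordinationMode(
                "his_nd1", "his", ("ND1",), (atoms["CB"], atoms["CG"], atoms["ND1"])
            ),
            CoordinationMode(
                "his_ne2", "his", ("NE2",), (atoms["CG"], atoms["CD2"], atoms["NE2"])
            ),
        ]
    if restype in ("ASP", "GLU"):
        if restype == "ASP":
            ante, c, o1, o2 = atoms["CB"], atoms["CG"], atoms["OD1"], atoms["OD2"]
            o1n, o2n = "OD1", "OD2"
        else:
            ante, c, o1, o2 = atoms["CG"], atoms["CD"], atoms["OE1"], atoms["OE2"]
            o1n, o2n = "OE1", "OE2"
        return [
            CoordinationMode("carboxylate_mono", "asp_glu", (o1n,), (ante, c, o1), "o1"),
            CoordinationMode("carboxylate_mono", "asp_glu", (o2n,), (ante, c, o2), "o2"),
            CoordinationMode("carboxylate_bi", "asp_glu", (o1n, o2n), (ante, c, o1, o2)),
        ]
    raise ValueError(f"{restype} is not a coordination residue type")


def generate_metal_positions(
    modes: list[CoordinationMode], params: GeometryParameterSet
) -> list[MetalPosition]:
    """Ideal Cd2+ positions for each mode, before any protein-clash filtering."""
    out: list[MetalPosition] = []
    for mode in modes:
        if mode.key == "carboxylate_bi":
            _, c, o1, o2 = mode.frame
            d_bid = params.window(mode.key, "bond").ideal
            mid = 0.5 * (o1 + o2)
            half = 0.5 * float(np.linalg.norm(o1 - o2))
            if d_bid <= half:
                continue
            axis = unit(mid - c)
            # keep the axis in the carboxylate plane and orthogonal to O1-O2
            oo = unit(o2 - o1)
            axis = unit(axis - np.dot(axis, oo) * oo)
            pos = mid + np.sqrt(d_bid**2 - half**2) * axis
            out.append(MetalPosition(pos, mode))
            continue
        bond = params.window(mode.key, "bond").ideal
        ang = params.window(mode.key, "angle").ideal
        gen_key = f"{mode.key}:{mode.variant}" if mode.variant else mode.key
        torsions = params.gen_dihedrals.get(gen_key, params.gen_dihedrals.get(mode.key, ()))
        x, y, z = mode.frame
        for tor in torsions:
            out.append(MetalPosition(nerf(x, y, z, bond, ang, tor), mode))
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ParamRecord:
    name: str
    measured: float
    deviation: float
    level: str


@dataclass
class GeometryEvaluation:
    mode: CoordinationMode
    records: list[ParamRecord] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        levels = [VERDICT_ORDER[r.level] for r in self.records]
        return {0: "fail", 1: "acceptable", 2: "perfect"}[min(levels)]

    def normalized_strain(self) -> float:
        return sum(r.deviation for r in self.records)


def _evaluate_mode(
    mode: CoordinationMode, cd: np.ndarray, params: GeometryParameterSet
) -> GeometryEvaluation:
    ev = GeometryEvaluation(mode)
    wins = params.windows[mode.key]
    if mode.key == "carboxylate_bi":
        _, c, o1, o2 = mode.frame
        w = wins["bond"]
        for label, o in (("bond_o1", o1), ("bond_o2", o2)):
            d = float(np.linalg.norm(cd - o))
            ev.records.append(ParamRecord(label, d, abs(d - w.ideal), w.classify(abs(d - w.ideal))))
        wp = wins["plane_dist"]
        normal = unit(np.cross(o1 - c, o2 - c))
        dist = abs(float(np.dot(cd - c, normal)))
        ev.records.append(ParamRecord("plane_dist", dist, dist, wp.classify(dist)))
        return ev

    x, y, z = mode.frame
    w = wins["bond"]
    d = float(np.linalg.norm(cd - z))
    ev.records.append(ParamRecord("bond", d, abs(d - w.ideal), w.classify(abs(d - w.ideal))))
    if "angle" in wins:
        w = wins["angle"]
        a = angle_deg(y, z, cd)
        ev.records.append(ParamRecord("angle", a, abs(a - w.ideal), w.classify(abs(a - w.ideal))))
    tor = dihedral_deg(x, y, z, cd)
    if "dihedral" in wins:
        w = wins["dihedral"]
        dev = circular_diff_deg(tor, w.ideal)
        ev.records.append(ParamRecord("dihedral", tor, dev, w.classify(dev)))
    if "planarity" in wins:
        w = wins["planarity"]
        dev = min(circular_diff_deg(tor, 0.0), circular_diff_deg(tor, 180.0))
        ev.records.append(ParamRecord("planarity", tor, dev, w.classify(dev)))
    return ev


def evaluate_geometry(
    modes: list[CoordinationMode] | CoordinationMode,
    cd_position: np.ndarray,
    params: GeometryParameterSet,
) -> GeometryEvaluation:
    """Evaluate a metal position against a residue's coordination modes.

    With several modes available (His tautomer nitrogens, carboxylate
    denticities) the best-scoring mode judges the residue: verdicts are
    compared first, then total normalized strain.
    """
    if isinstance(modes, CoordinationMode):
        modes = [modes]
    cd = np.asarray(cd_position, float)
    best: GeometryEvaluation | None = None
    for mode in modes:
        ev = _evaluate_mode(mode, cd, params)
        if best is None:
            best = ev
            continue
        vb, ve = VERDICT_ORDER[best.verdict], VERDICT_ORDER[ev.verdict]
        if ve > vb or (ve == vb and ev.normalized_strain() < best.normalized_strain()):
            best = ev
    assert best is not None
    return best
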