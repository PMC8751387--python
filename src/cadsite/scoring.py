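"""Scoring, metal-position fine-tuning, ranking and model output.

Each solution is scored additively over its members:

    Score = sum_i ( Quality_i + CoordinationScore_i )

where the quality of member i combines its rotamer probability p_i, its
backrub angle theta_i and a coordination-type weight w_i:

    Quality_i = 0.9 * log(p_i) - 2 * |theta_i| / 6.0 + w_i

(natural logarithm by default) and CoordinationScore_i is a discrete
per-type value depending on whether the member's geometry at the metal
point is perfect or merely acceptable.  The metal coordinate is then
fine-tuned over a 0.8 x 0.8 x 0.8 A lattice with 0.1 A spacing centred on
the averaged initial position, maximizing the total score while keeping
every member at least acceptable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .geometry import GeometryParameterSet, evaluate_geometry
from .rotamers import CoordinationResidue
from .scaffold import Scaffold
from .search import MetalSiteSolution

log = logging.getLogger("cadsite")

LATTICE_EXTENT = 0.4   # half-extent per axis, Angstrom
LATTICE_STEP = 0.1


@dataclass
class MemberScore:
    member: CoordinationResidue
    verdict: str
    quality: float
    coordination: float

    @property
    def total(self) -> float:
        return self.quality + self.coordination


def quality_score(
    p: float, theta: float, w: float, log_base: str | float = "e"
) -> float:
    """Quality term of one coordination residue.

    p: rotamer probability in (0, 1] (backbone-oxygen members use 1);
    theta: backrub angle in degrees; w: coordination-type weight.
    """
    if p <= 0:
        raise ValueError(f"rotamer probability must be positive, got {p}")
    if log_base in ("e", math.e):
        lg = math.log(p)
    elif log_base in ("10", 10, 10.0):
        lg = math.log10(p)
    else:
        lg = math.log(p, float(log_base))
    return 0.9 * lg - 2.0 * abs(theta) / 6.0 + w


def coordination_score(
    verdict: str, score_type: str, params: GeometryParameterSet
) -> float:
    """Discrete per-type score for a perfect or acceptable member."""
    if verdict == "fail":
        raise ValueError("cannot score a failing coordination residue")
    hi, lo = params.scores[score_type]
    return hi if verdict == "perfect" else lo


def score_members(
    members, cd: np.ndarray, params: GeometryParameterSet, log_base="e"
) -> list[MemberScore] | None:
    """Per-member scores at a metal point, or None if any member fails."""
    out = []
    for m in members:
        ev = evaluate_geometry(m.modes, cd, params)
        if ev.verdict == "fail":
            return None
        st = ev.mode.score_type
        q = quality_score(m.probability, m.backrub_angle, params.weights[st], log_base)
        out.append(MemberScore(m, ev.verdict, q, coordination_score(ev.verdict, st, params)))
    return out


def total_score(member_scores: list[MemberScore]) -> float:
    return sum(ms.total for ms in member_scores)


def fine_tune_position(
    solution: MetalSiteSolution,
    params: GeometryParameterSet,
    extent: float = LATTICE_EXTENT,
    step: float = LATTICE_STEP,
    log_base="e",
) -> MetalSiteSolution:
    """Move the metal to the best point of the lattice around cd_initial.

    Scans every point of the (2*extent/step + 1)^3 grid; points where any
    member drops below acceptable are excluded; ties break by distance to
    cd_initial, then by lexicographic grid order.  cd_initial itself is
    always a valid candidate, so the score never decreases.
    """
    n = int(round(extent / step))
    offsets = np.arange(-n, n + 1) * step
    best = None  # (score, -distance not needed; see comparisons)
    for dx in offsets:
        for dy in offsets:
            for dz in offsets:
                cd = solution.cd_initial + np.array([dx, dy, dz])
                scores = score_members(solution.members, cd, params, log_base)
                if scores is None:
                    continue
                s = total_score(scores)
                d = float(np.linalg.norm(cd - solution.cd_initial))
                if (
                    best is None
                    or s > best[0] + 1e-12
                    or (abs(s - best[0]) <= 1e-12 and d < best[1] - 1e-12)
                ):
                    best = (s, d, cd, scores)
    assert best is not None, "cd_initial must satisfy the acceptable contract"
    solution.cd_final = best[2]
    solution.score = best[0]
    solution.breakdown = best[3]
    solution.evaluations = tuple(
        evaluate_geometry(m.modes, best[2], params) for m in solution.members
    )
    return solution


# ---------------------------------------------------------------------------
# ranking and reporting
# ---------------------------------------------------------------------------

def mutation_notation(scaffold: Scaffold, member: CoordinationResidue) -> str:
    """'X<pos>Y' notation for a mutation, e.g. D165E; backbone-oxygen
    members are reported as e.g. 'T134(O)'."""
    native = scaffold.residue(member.position).name
    one = _THREE_TO_ONE.get(native, "X")
    if member.kind == "backbone_oxygen":
        return f"{one}{member.position}(O)"
    new = _THREE_TO_ONE.get(member.restype_new, "X")
    return f"{one}{member.position}{new}"


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

REPORT_COLUMNS = (
    "rank", "score", "n_members", "mutations", "donor_atoms",
    "member_scores", "cd_x", "cd_y", "cd_z",
)


def rank_solutions(solutions: list[MetalSiteSolution]) -> list[MetalSiteSolution]:
    """Descending total score; ties by fewer members then canonical member
    order.  Duplicate member sets are already unique by construction."""
    return sorted(
        solutions,
        key=lambda s: (-s.score, len(s.members), s.member_set_key()),
    )


def rank_and_report(
    scaffold: Scaffold, solutions: list[MetalSiteSolution]
) -> tuple[list[MetalSiteSolution], str]:
    """Rank fine-tuned solutions and render the TSV design report."""
    ranked = rank_solutions(solutions)
    lines = ["\t".join(REPORT_COLUMNS)]
    for rank, sol in enumerate(ranked, 1):
        muts = " ".join(
            mutation_notation(scaffold, m)
            for m in sorted(sol.members, key=lambda m: m.position)
        )
        donors = " ".join(
            f"{m.position}:{'+'.join(ev.mode.donor_atoms)}"
            for m, ev in zip(sol.members, sol.evaluations)
        )
        per_member = " ".join(
            f"{ms.quality:.3f}+{ms.coordination:.1f}" for ms in sol.breakdown
        )
        x, y, z = sol.cd_final
        lines.append(
            "\t".join(
                [
                    str(rank),
                    f"{sol.score:.3f}",
                    str(len(sol.members)),
                    muts,
                    donors,
                    per_member,
                    f"{x:.3f}", f"{y:.3f}", f"{z:.3f}",
                ]
            )
        )
    return ranked, "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# mutant model output
# ---------------------------------------------------------------------------

def write_mutant_model(scaffold: Scaffold, solution: MetalSiteSolution, path) -> None:
    """Write the designed mutant as a PDB file.

    Mutated positions carry the rebuilt side chain (and their original
    backbone); every other residue is copied unchanged; the Cd2+ ion is
    appended as a single HETATM with element CD at cd_final.
    """
    import gemmi

    from .scaffold import BACKBONE_ATOMS
    from .rotamers import SIDECHAIN_ELEMENTS

    by_position = {
        m.position: m for m in solution.members if m.kind == "sidechain_mutation"
    }
    st = gemmi.Structure()
    st.name = "cadsite design"
    model = gemmi.Model("1")
    chain = gemmi.Chain(scaffold.residues[0].chain or "A")
    for res in scaffold.residues:
        out = gemmi.Residue()
        member = by_position.get(res.number)
        out.name = member.restype_new if member else res.name
        out.seqid = gemmi.SeqId(res.number, " ")
        if member:
            atoms = {n: res[n] for n in BACKBONE_ATOMS if n in res.atoms}
            atoms.update(member.placed_atoms)
            elements = {
                n: (res.elements.get(n) or SIDECHAIN_ELEMENTS.get(n, "C"))
                if n in res.atoms
                else SIDECHAIN_ELEMENTS.get(n, "C")
                for n in atoms
            }
        else:
            atoms = res.atoms
            elements = res.elements
        for name, xyz in atoms.items():
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(elements.get(name, "C"))
            at.pos = gemmi.Position(*xyz)
            at.occ = 1.0
            out.add_atom(at)
        chain.add_residue(out)

    ion = gemmi.Residue()
    ion.name = "CD"
    ion.seqid = gemmi.SeqId(max(scaffold.numbers()) + 1, " ")
    ion.het_flag = "H"
    at = gemmi.Atom()
    at.name = "CD"
    at.element = gemmi.Element("Cd")
    at.pos = gemmi.Position(*solution.cd_final)
    at.occ = 1.0
    ion.add_atom(at)
    chain.add_residue(ion)

    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)
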