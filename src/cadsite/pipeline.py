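"""End-to-end design pipeline: scaffold -> candidates -> pairs -> sites ->
scores -> report.

The pipeline itself consumes no randomness; identical configuration and
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .geometry import GeometryParameterSet
from .rotamers import (
    DEFAULT_BACKRUB_ANGLES,
    build_coordination_library,
    load_rotamer_library,
)
from .scaffold import (
    DomainDefinition,
    MutabilityMask,
    apply_mutability,
    assign_domains,
    find_interface,
    read_structure,
    RBP_DOMAINS,
    RBP_MASK,
)
from .scoring import fine_tune_position, rank_and_report, write_mutant_model
from .search import (
    DEFAULT_PAIR_DISTANCE,
    MIN_CYSTEINES,
    SOLUTION_SIZES,
    build_pair_library,
    enumerate_solutions,
    reduce_library,
)

log = logging.getLogger("cadsite")


@dataclass
class PipelineConfig:
    pdb: str = ""
    chain: str = "A"
    model_index: int = 0
    rotlib: str = ""
    params: str = ""                       # empty -> packaged defaults
    domain_i_ranges: list = field(default_factory=lambda: list(RBP_DOMAINS.domain_i_ranges))
    domain_ii_ranges: list = field(default_factory=lambda: list(RBP_DOMAINS.domain_ii_ranges))
    mask_ranges: list = field(default_factory=lambda: list(RBP_MASK.excluded_ranges))
    mask_restypes: list = field(default_factory=lambda: sorted(RBP_MASK.excluded_restypes))
    interface_cutoff: float = 12.0
    p_min: float = 0.01
    clash_tolerance: float = 0.5
    backrub_angles: tuple = DEFAULT_BACKRUB_ANGLES
    pair_distance_max: float = DEFAULT_PAIR_DISTANCE
    solution_sizes: tuple = SOLUTION_SIZES
    min_cysteines: int = MIN_CYSTEINES
    log_base: str = "e"
    lattice_extent: float = 0.4
    lattice_step: float = 0.1
    max_reported_designs: int = 50
    out_dir: str = ""
    dump_intermediates: bool = False

    def domain_definition(self) -> DomainDefinition:
        return DomainDefinition(
            [tuple(r) for r in self.domain_i_ranges],
            [tuple(r) for r in self.domain_ii_ranges],
        )

    def mutability_mask(self) -> MutabilityMask:
        return MutabilityMask(
            frozenset(self.mask_restypes),
            tuple(tuple(r) for r in self.mask_ranges),
        )


@dataclass
class RunResult:
    designs: list                      # ranked MetalSiteSolutions
    report: str
    counts: dict[str, int]
    scaffold: object


def run_design(config: PipelineConfig) -> RunResult:
    """Execute the full design pipeline and (optionally) write outputs."""
    scaffold = read_structure(config.pdb, config.model_index, config.chain)
    assign_domains(scaffold, config.domain_definition())
    interface = find_interface(scaffold, config.interface_cutoff)
    mutable = apply_mutability(scaffold, config.mutability_mask(), interface)

    params = (
        GeometryParameterSet.from_file(config.params)
        if config.params
        else GeometryParameterSet.default()
    )
    rotlib = load_rotamer_library(config.rotlib)

    counts = {
        "residues": len(scaffold.residues),
        "interfacial": len(interface),
        "mutable": len(mutable),
    }

    library = build_coordination_library(
        scaffold, mutable, interface, rotlib, params,
        p_min=config.p_min,
        clash_tolerance=config.clash_tolerance,
        backrub_angles=tuple(config.backrub_angles),
    )
    counts["library"] = len(library)

    pairs = build_pair_library(
        library, config.pair_distance_max, config.clash_tolerance
    )
    counts["pairs"] = len(pairs)

    solutions = []
    if pairs:
        kept, reduced_pairs = reduce_library(library, pairs)
        counts["library_reduced"] = len(kept)
        counts["pairs_reduced"] = len(reduced_pairs)
        if kept:
            keep_map = {old: new for new, old in enumerate(kept)}
            sub_library = [library[i] for i in kept]
            sub_pairs = [
                type(p)(keep_map[p.a], keep_map[p.b], p.pos_a, p.pos_b, p.distance)
                for p in reduced_pairs
            ]
            solutions = enumerate_solutions(
                sub_library,
                sub_pairs,
                params,
                sizes=tuple(config.solution_sizes),
                min_cys=config.min_cysteines,
            )
    else:
        counts["library_reduced"] = 0
        counts["pairs_reduced"] = 0
    counts["solutions"] = len(solutions)

    for sol in solutions:
        fine_tune_position(
            sol, params, config.lattice_extent, config.lattice_step, config.log_base
        )
    ranked, report = rank_and_report(scaffold, solutions)
    ranked = ranked[: config.max_reported_designs]

    log.info("pipeline counts: %s", counts)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "designs.tsv").write_text(report)
        (out / "config.json").write_text(
            json.dumps(asdict(config), indent=2, default=list) + "\n"
        )
        (out / "counts.json").write_text(json.dumps(counts, indent=2) + "\n")
        models = out / "models"
        models.mkdir(exist_ok=True)
        for i, sol in enumerate(ranked, 1):
            write_mutant_model(scaffold, sol, models / f"design_{i:03d}.pdb")
        if config.dump_intermediates:
            _dump_intermediates(out, library, pairs)

    return RunResult(ranked, report, counts, scaffold)


def _dump_intermediates(out: Path, library, pairs) -> None:
    lines = ["index\tposition\tkind\trestype\trotamer\tbackrub\tn_metal_positions"]
    for i, e in enumerate(library):
        lines.append(
            f"{i}\t{e.position}\t{e.kind}\t{e.restype_new}\t{e.rotamer_index}"
            f"\t{e.backrub_angle:+.0f}\t{len(e.metal_positions)}"
        )
    (out / "coordination_library.tsv").write_text("\n".join(lines) + "\n")
    lines = ["a\tb\tdistance"]
    for p in pairs:
        lines.append(f"{p.a}\t{p.b}\t{p.distance:.3f}")
    (out / "pair_library.tsv").write_text("\n".join(lines) + "\n")
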