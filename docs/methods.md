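# Methods

## The design model

`cadsite` treats metal-site design as pure geometric constraint
satisfaction: no energy function, no electrostatics, no solvation. A
candidate coordination residue is any clash-free placement of a Cys, His,
Asp or Glu side chain (rebuilt from ideal internal coordinates and
rotamer chi means) at a mutable interfacial position, or the backbone
carbonyl oxygen of any interfacial residue. Each candidate carries one or
more *standard metal positions* — the points where a Cd²⁺ ion would sit
if the coordination geometry were ideal — and a multi-residue site is a
set of candidates whose standard positions nearly coincide.

Assumptions this model makes:

* the scaffold backbone is rigid apart from the local ±6° backrub move;
* coordination is adequately described by first-shell distance/angle/
  dihedral windows calibrated on high-resolution Cd²⁺ protein structures;
* side-chain viability is a hard-sphere overlap test, not a packing
  energy;
* members of a site interact with the ion independently (the score is
  additive over members).

## Coordination geometry

Each coordinating group defines a local frame of three reference atoms;
ideal metal positions are NeRF placements at the configured bond length,
bond angle and torsion(s) in that frame, and evaluation measures the same
internal coordinates for an arbitrary metal point. Torsions follow the
IUPAC sign convention; angular deviations are measured on the circle.

Defaults shipped in `params/cd_geometry.ini` (ideal / perfect ± /
acceptable ±):

| mode | bond (Å) | angle (°) | torsion |
|---|---|---|---|
| Cys SG | 2.52 / 0.10 / 0.30 | CB–SG–Cd 109.5 / 10 / 25 | free; generated at −60, 60, 180 |
| His ND1 | 2.30 / 0.10 / 0.30 | CG–ND1–Cd 125.4 / 10 / 25 | 0 (in-plane exterior bisector) / 15 / 40 |
| His NE2 | 2.30 / 0.10 / 0.30 | CD2–NE2–Cd 125.9 / 10 / 25 | 180 / 15 / 40 |
| carboxylate mono | 2.28 / 0.10 / 0.30 | C–O–Cd 120 / 12 / 27 | planarity 0 / 15 / 40 |
| carboxylate bi | 2.50 / 0.12 / 0.32 per O | — | out-of-plane distance 0 / 0.30 / 0.80 Å |
| backbone O | 2.35 / 0.10 / 0.30 | C–O–Cd 120 / 12 / 27 | planarity 0 / 15 / 40 |

Ideal values follow mean first-shell geometry of Cd²⁺ sites in
high-resolution crystal structures of cadmium-binding proteins; the
window half-widths are chosen so that the perfect window captures
near-ideal sites and the acceptable window tolerates roughly one PDB
coordinate-error's worth of strain at the donor atom. Both levels are
closed intervals and the loader rejects any file where the perfect window
is not nested in the acceptable one, or where a perfect score does not
exceed the acceptable score.

A carboxylate emits one bidentate position (on the in-plane O–C–O
bisector axis, equidistant from both oxygens) and three monodentate
sp² lone-pair positions: the anti lobe of each oxygen plus a single syn
representative, because the two syn lobes flank the same inter-oxygen
face of the group. The generation direction lists are parameter-file keys
(`gen_dihedrals*`), so other conventions — a different Cys torsion fan, a
fourth monodentate lobe — are reachable by configuration. A His placement
offers both tautomer nitrogens as alternative donors of the same
placement; evaluation judges a metal point by the best-fitting mode
(verdict first, then total deviation).

Generated positions closer than 2.0 Å (`metal_clash_floor`) to any
protein heavy atom outside their own residue are discarded — the residue
clash screen filters side chains, this floor keeps the ion itself out of
the protein.

## Candidate placement

* Rotamers come from a Dunbrack-style whitespace table binned on 10°
  (φ, ψ); only rotamers with probability ≥ `p_min` (default 0.01) are
  used; chi means only, no sub-rotamer spread. (φ, ψ) are measured on the
  unperturbed backbone.
* The backrub move rotates the segment between the flanking Cα pivots
  (C, O of i−1; all of i; N of i+1) rigidly about the Cα(i−1)–Cα(i+1)
  axis by θ₁,₃ ∈ {−6°, 0°, +6°}; pivots are bit-identical to the input.
  Terminal residues get only θ = 0. Backbone-oxygen candidates are taken
  from the native (θ = 0) backbone only.
* Clash rule: heavy-atom van der Waals radii C 1.70, N 1.55, O 1.52,
  S 1.80 Å with a 0.5 Å overlap tolerance; the candidate's own residue
  and the backbones of its two sequence neighbours are exempt (the native
  side chain at the position is conceptually stripped by the mutation).

## Search

Pairing uses the best match over the two candidates' position lists;
the default threshold is 1.6 Å (configurable; 1.8 Å is a documented
alternative convention). Set reduction removes candidates with fewer
than three compatible partners at distinct scaffold positions, iterated
to a fixpoint (the fixpoint is order-independent; every member of a
4-clique survives, so no solution is lost). Enumeration is an exact
depth-first clique search over the canonically sorted reduced library,
pruned on cysteine feasibility; a solution needs 4 or 5 members at
distinct positions, ≥ 2 Cys mutations, and all members at least
*acceptable* at the averaged metal point.

Within a solution, each member contributes one chosen position. The
choice is a small deterministic fixed point: start from first-listed
positions, re-choose each member's position nearest the running centroid
(ties to the lower index) until stable. This makes the chosen set — and
hence cd_initial — independent of the order in which the DFS assembled
the clique, which the permutation-invariance property requires.

## Scoring and fine-tuning

Quality uses the natural logarithm (configurable to base 10); backbone-
oxygen members score with p = 1, θ = 0, so their quality equals the 3.0
weight — the strong preference for coordination that requires no
mutation at all. Discrete coordination scores default to 2.0 (perfect) /
1.0 (acceptable) for every type.

Fine-tuning scans the full (2·0.4/0.1 + 1)³ = 729-point lattice centred
on cd_initial, skipping points where any member drops below acceptable;
ties in score break by distance to cd_initial, then by lexicographic grid
order, making the result unique and reproducible. Because the quality
terms do not depend on the metal point, fine-tuning can only change the
discrete perfect/acceptable levels; the landscape therefore has plateaus,
and the tie-break settles on the plateau point nearest the start. Only
the ion moves; member placements and chosen positions are frozen.

Ranking is descending total score, then fewer members, then canonical
member order; duplicate member sets are emitted once. Reports are TSV
with coordinates to 3 decimals; mutant models are standard PDB with the
designed side chains and a single Cd HETATM.

## The synthetic fixture

The generator works backwards from a chosen metal point: each planted
member is a template residue (ideal backbone, side chain rebuilt from the
chi values the mini rotamer library will offer) that is rigidly re-posed
so one of its forward-generated standard metal positions lands exactly on
the metal point, with the residue body along an assigned outward
direction (tetrahedral for 4 members, trigonal-bipyramidal for 5). The
free roll about that axis is chosen deterministically to maximize
clearance between members. Because every pipeline stage is rigid-motion
invariant, re-running the design recovers the planted site with perfect
geometry at zero noise — up to the 10⁻³ Å coordinate precision of the
PDB format the scaffold is written in.

Twelve decoy residues sit on a 9 Å shell of well-separated directions,
side chains pointing outward, each leaning toward a planted direction of
the opposite sequence domain so the whole shell stays interfacial. Their
rotamer rows (and the planted ones) are emitted over a ±2-bin (φ, ψ)
neighbourhood so that noise-shifted backbones still find their rotamers.

Backbone noise displaces each residue rigidly by σ times a standard-
normal 3-vector; the field is drawn once per seed and scaled by σ, so a
given seed degrades monotonically with σ. A rigid per-residue
displacement was chosen over independent per-atom jitter because the
latter shears the local N–Cα–C frame and the error is then amplified by
the side-chain lever arm, collapsing recovery in a cliff rather than the
graded decay that makes the noise sweep informative. Typical recovery of
the planted site as the top-ranked design over 20 seeds: 100 % at σ = 0,
∼75–90 % at 0.2 Å, ∼10–20 % at 0.5 Å, 0 % at 1.0 Å.

What the fixture does *not* emulate: real packing density (decoys are
sparse and the site is fully solvent-open), native side chains beyond
Cβ, sequence-local steric context, correlated backbone motion, and real
rotamer statistics (the mini library contains exactly the rotamers the
construction needs plus decoys). Passing the planted-recovery tests
therefore demonstrates the correctness of the geometric search, not
design performance on crowded native interfaces.

## Numerical choices and degenerate inputs

* Windows are closed: a deviation exactly at a threshold passes.
* Dihedral deviations use the circular metric; "planarity" is the
  distance of a torsion to the nearer of {0°, 180°}.
* Alternate conformations resolve to the highest-occupancy conformer;
  residues missing a backbone atom are excluded from candidacy with a
  logged warning; insertion codes are rejected.
* An empty coordination library or an all-removed reduction is a fatal,
  diagnosed error; an empty solution list is a valid outcome.
* The pipeline consumes no randomness; byte-identical outputs for
  identical inputs are a tested contract.

## Known limitations

* Mutual clashes are screened pairwise at pair-library time; three side
  chains may still collide softly inside a 4–5-residue solution.
* Fine-tuning does not re-select member coordination positions while the
  ion moves.
* No metal–ligand energetics, polarization, protonation or selectivity
  modelling (e.g. against Zn²⁺); affinity is outside the model.
* Single-chain, two-domain scaffolds only.
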