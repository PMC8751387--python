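# cadsite

Geometric design of Cd²⁺ binding sites at protein domain–domain interfaces.

Periplasmic binding proteins such as the *E. coli* ribose-binding protein
(RBP) are two-domain receptors whose hinge-bending open→closed motion is
the input signal of bacterial chemotaxis. Placing a metal-binding site in
the cleft between the two domains couples metal binding to that motion and
turns the receptor into a biosensor for the metal. `cadsite` implements
the computational half of that engineering problem: given a scaffold
structure, a backbone-dependent rotamer library and a set of Cd²⁺
coordination-geometry parameters, it enumerates candidate coordination
residues at the inter-domain interface, searches for 4–5-residue
combinations that can chelate a single Cd²⁺ ion, and ranks the designs.

## Method

1. **Scaffold preparation** — the structure is split into two domains by
   residue ranges; a residue is *interfacial* when its Cα lies within
   12 Å of any Cα of the opposite domain. Prolines and hinge residues are
   never mutated.
2. **Coordination residue library** — every mutable interfacial position
   is computationally mutated to Cys, His, Asp and Glu using rotamers from
   a Dunbrack-style backbone-dependent library, under three backrub
   backbone variants (θ₁,₃ ∈ {−6°, 0°, +6°}). Clash-free placements are
   kept; backbone carbonyl oxygens of interfacial residues enter the
   library as coordination candidates without mutation.
3. **Standard metal positions** — for every coordinating atom, ideal Cd²⁺
   positions are generated from tabulated coordination geometry
   (Cd–S(Cys), Cd–N(His), carboxylate monodentate and bidentate, backbone
   C=O; for a carboxylate, one bidentate and three monodentate positions).
4. **Pair library and set reduction** — two candidates whose metal
   positions fall within 1.6 Å of each other and whose side chains do not
   collide form a coordination pair; candidates with fewer than three
   compatible partners are iteratively removed.
5. **Site enumeration** — a depth-first search lists every 4–5-residue
   clique in the pair graph with at least two cysteines whose averaged
   metal position keeps all members at *acceptable* geometry.
6. **Scoring and fine-tuning** — each solution is scored

   Score = Σᵢ (Qualityᵢ + CoordinationScoreᵢ),
   Qualityᵢ = 0.9·ln(pᵢ) − 2·|θ₁,₃|/6 + wᵢ

   with rotamer probability *p*, backrub angle θ₁,₃ and type weight *w*
   (Cys 0.8, His 1.0, Asp/Glu 0.8, backbone O 3.0). CoordinationScore is a
   discrete per-type value, higher when all geometry parameters meet the
   *perfect* thresholds and lower when they are merely *acceptable*. The
   Cd²⁺ position is then fine-tuned over a 0.8 × 0.8 × 0.8 Å lattice with
   0.1 Å spacing, maximizing the total score.

All ideal bond lengths, angle/dihedral targets, perfect/acceptable windows
and discrete scores live in a plain-text parameter file
(`src/cadsite/params/cd_geometry.ini`), not in code.

## Worked example

The package ships a synthetic-fixture generator that plants a
geometrically exact 2×Cys + Glu + backbone-O site among twelve decoy
residues on a two-segment mini-scaffold, together with the matching mini
rotamer library — so the whole pipeline runs with no downloads:

```sh
cadsite fixture --out fx --seed 1
cadsite design --pdb fx/scaffold.pdb --rotlib fx/rotamers.txt \
               --params fx/cd_geometry.ini --out run \
               --domain-i 1-8 --domain-ii 9-16
```

which prints stage counts and writes `run/designs.tsv`:

```
rank  score   n_members  mutations            donor_atoms                 cd_x    cd_y    cd_z
1     12.021  4          A2C A6C A11E A15(O)  2:SG 6:SG 11:OE1+OE2 15:O   -0.000  0.000  -0.000
2     9.021   4          A2C A6C A11E A15(O)  2:SG 6:SG 11:OE1+OE2 15:O   -0.009  0.000  -0.066
...
```

The top design is exactly the planted site: mutations A2C, A6C, A11E plus
the backbone oxygen of residue 15, chelating Cd²⁺ at the planted origin.
Its score decomposes per member as quality + coordination score:
0.340 + 2.0 for each Cys (0.9·ln 0.6 + 0.8, perfect geometry), 0.340 + 2.0
for the bidentate Glu, and 3.000 + 2.0 for the backbone oxygen — total
12.021. Lower-ranked rows are the same site built from backrub-perturbed
variants (each ±6° backrub costs 2 score units) or through monodentate
rather than bidentate Glu coordination. A mutant model with the placed
side chains and the Cd²⁺ HETATM is written per design
(`run/models/design_001.pdb`), and `cadsite score --pdb` re-evaluates it.

To run on a real scaffold, point `--pdb` at a two-domain structure (e.g.
the closed ribose-binding protein, PDB 2DRI, with its standard domain
split `--domain-i 1-103,236-263 --domain-ii 104-235,264-271` and hinge
mask 102-104,234-236,263-265) and `--rotlib` at a Dunbrack bbdep-format
rotamer file.

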