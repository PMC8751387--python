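# Default Cd2+ coordination geometry parameters.
#
# Ideal values follow mean first-shell geometry of Cd2+ sites in
# high-resolution protein crystal structures (Cd-S(thiolate) ~2.52 A,
# Cd-N(imidazole) ~2.30 A, Cd-O(carboxylate) ~2.28 A monodentate /
# ~2.50 A bidentate, Cd-O(carbonyl) ~2.35 A).  Each geometric parameter
# line reads: ideal  perfect-half-width  acceptable-half-width
# (windows are closed; the perfect window nests inside the acceptable one).
#
# gen_dihedrals lists the torsions (degrees, frame x-y-z-Cd) at which
# candidate metal positions are generated for the mode.

[weights]
cys = 0.8
his = 1.0
asp_glu = 0.8
backbone_o = 3.0

[scores]
# per coordination type: perfect acceptable
cys = 2.0 1.0
his = 2.0 1.0
asp_glu = 2.0 1.0
backbone_o = 2.0 1.0

[cys_sg]
# frame CA-CB-SG; the Cd-S torsion is soft, so no dihedral window
bond = 2.52 0.10 0.30
angle = 109.5 10 25
gen_dihedrals = -60 60 180

[his_nd1]
# frame CB-CG-ND1; exterior lone-pair bisector lies at torsion 0
bond = 2.30 0.10 0.30
angle = 125.4 10 25
dihedral = 0 15 40
gen_dihedrals = 0

[his_ne2]
# frame CG-CD2-NE2; exterior lone-pair bisector lies at torsion 180
bond = 2.30 0.10 0.30
angle = 125.9 10 25
dihedral = 180 15 40
gen_dihedrals = 180

[carboxylate_mono]
# frame (CB-CG-ODx for Asp, CG-CD-OEx for Glu); torsion 0 = anti lobe,
# 180 = syn lobe; O2 emits only its anti lobe (one syn representative)
bond = 2.28 0.10 0.30
angle = 120.0 12 27
planarity = 0 15 40
gen_dihedrals_o1 = 0 180
gen_dihedrals_o2 = 0

[carboxylate_bi]
# symmetric chelation on the in-plane O-C-O bisector axis
bond = 2.50 0.12 0.32
plane_dist = 0 0.30 0.80

[backbone_o]
# frame CA-C-O; two in-plane sp2 lone pairs
bond = 2.35 0.10 0.30
angle = 120.0 12 27
planarity = 0 15 40
gen_dihedrals = 0 180

[limits]
# generated metal positions closer than this to any protein heavy atom
# outside their own residue are discarded
metal_clash_floor = 2.0
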