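"""Rotamer library parsing, backrub, side-chain assembly, clash screening,
library construction."""

import numpy as np
import pytest

from cadsite import (
    assemble_side_chain,
    backrub_variants,
    build_coordination_library,
    clash_check,
    find_interface,
    load_rotamer_library,
)
from cadsite._geom import angle_deg, dihedral_deg, unit
from cadsite.geometry import generate_metal_positions, modes_for
from cadsite.rotamers import (
    ClashContext,
    RotamerLibraryError,
    backbone_dihedrals,
)
from cadsite.scaffold import VDW_RADII



class TestLibraryParsing:
    def test_fixture_library_sorted_descending(self, bundle):
        lib = load_rotamer_library(bundle.rotlib_path)
        assert len(lib) > 0
        seen_bins = 0
        for (rt, pb, sb), rots in lib._entries.items():
            seen_bins += 1
            probs = [r.probability for r in rots]
            assert probs == sorted(probs, reverse=True)
            for r in rots:
                assert 0 < r.probability <= 1
                assert len(r.chi) == {"CYS": 1, "HIS": 2, "ASP": 2, "GLU": 3}[rt]
        assert seen_bins > 10

    def test_noncoordination_type_query_empty(self, bundle):
        lib = load_rotamer_library(bundle.rotlib_path)
        assert lib.query("GLY", -60, -40) == []

    def test_uncovered_bin_query_empty(self, bundle):
        lib = load_rotamer_library(bundle.rotlib_path)
        # scan for a bin guaranteed absent
        present = {k[1:] for k in lib._entries if k[0] == "CYS"}
        for phi in range(-180, 180, 10):
            if (phi, phi) not in present:
                assert lib.query("CYS", phi, phi) == []
                return
        pytest.skip("library covers every diagonal bin")

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("CYS -60 -40 10 1 1 1 1 not_a_number 180 0 0 0\n")
        with pytest.raises(RotamerLibraryError, match=":1"):
            load_rotamer_library(p)

    def test_probability_outside_unit_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("CYS -60 -40 10 1 1 1 1 1.2 180 0 0 0\n")
        with pytest.raises(RotamerLibraryError, match="probability"):
            load_rotamer_library(p)


class TestBackrub:
    def test_zero_angle_identity(self, scaffold):
        variants = dict(backrub_variants(scaffold, 5))
        assert variants[0.0] == {}

    def test_inverse_rotations_recover_input(self, scaffold):
        res = scaffold.residue(5)
        (_, fwd), = [v for v in backrub_variants(scaffold, 5, angles=(6.0,))]
        # apply -6 to the +6 result by rotating the overridden coords back
        from cadsite._geom import rotation_about_axis

        ca_prev = scaffold.residue(4)["CA"]
        ca_next = scaffold.residue(6)["CA"]
        back = rotation_about_axis(ca_prev, ca_next - ca_prev, -6.0)
        for (num, name), xyz in fwd.items():
            orig = scaffold.residue(num)[name]
            assert np.linalg.norm(back(xyz) - orig) < 1e-9

    def test_pivots_fixed_and_analytic_displacement(self, scaffold):
        pos = 5
        ca_prev = scaffold.residue(pos - 1)["CA"]
        ca_next = scaffold.residue(pos + 1)["CA"]
        axis = unit(ca_next - ca_prev)
        for theta, overrides in backrub_variants(scaffold, pos, angles=(-6.0, 6.0)):
            assert (pos - 1, "CA") not in overrides
            assert (pos + 1, "CA") not in overrides
            ca = scaffold.residue(pos)["CA"]
            moved = overrides[(pos, "CA")]
            v = ca - ca_prev
            r_perp = np.linalg.norm(v - np.dot(v, axis) * axis)
            expected = 2.0 * r_perp * abs(np.sin(np.radians(theta) / 2.0))
            assert np.linalg.norm(moved - ca) == pytest.approx(expected, abs=1e-9)

    def test_terminal_residue_only_zero(self, scaffold):
        variants = backrub_variants(scaffold, 1)
        assert variants == [(0.0, {})]


def nerf_oracle(a, b, c, bond, angle, torsion):
    """Independent internal-to-Cartesian placement built on scipy rotations."""
    from scipy.spatial.transform import Rotation

    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    bc = unit(c - b)
    d0 = c + bond * bc  # extended position
    n = unit(np.cross(b - a, c - b))
    # bend by (180 - angle) about the plane normal, then twist about b->c;
    # the twist sense follows the dihedral sign convention (a positive
    # torsion appears clockwise looking from b towards c)
    bend = Rotation.from_rotvec(np.radians(180.0 - angle) * n)
    twist = Rotation.from_rotvec(-np.radians(torsion) * bc)
    d = c + twist.apply(bend.apply(d0 - c))
    # self-check: the oracle must satisfy the measured definitions
    assert abs(angle_deg(b, c, d) - angle) < 1e-6
    assert min(abs(dihedral_deg(a, b, c, d) - torsion),
               360 - abs(dihedral_deg(a, b, c, d) - torsion)) < 1e-6
    return d


class TestSideChainAssembly:
    def test_cys_sg_matches_independent_construction(self, scaffold):
        placed = assemble_side_chain(scaffold, 5, "CYS", (180.0,))
        res = scaffold.residue(5)
        cb = nerf_oracle(res["C"], res["N"], res["CA"], 1.530, 110.5, 122.6)
        sg = nerf_oracle(res["N"], res["CA"], cb, 1.810, 114.0, 180.0)
        assert np.linalg.norm(placed["CB"] - cb) < 1e-6
        assert np.linalg.norm(placed["SG"] - sg) < 1e-6

    def test_chi_angles_round_trip(self, scaffold):
        res = scaffold.residue(5)
        for restype, chi in [
            ("CYS", (-65.0,)),
            ("HIS", (-60.0, 90.0)),
            ("ASP", (-70.0, 20.0)),
            ("GLU", (-60.0, 180.0, -40.0)),
        ]:
            placed = assemble_side_chain(scaffold, 5, restype, chi)
            chain = {"CYS": ["SG"], "HIS": ["CG", "ND1"], "ASP": ["CG", "OD1"],
                     "GLU": ["CG", "CD", "OE1"]}[restype]
            atoms = [res["N"], res["CA"], placed["CB"]] + [placed[a] for a in chain]
            for i, expected in enumerate(chi):
                measured = dihedral_deg(*atoms[i : i + 4])
                assert measured == pytest.approx(expected, abs=1e-6)

    def test_non_coordination_type_rejected(self, scaffold):
        with pytest.raises(ValueError, match="ALA"):
            assemble_side_chain(scaffold, 5, "ALA", ())

    def test_deterministic(self, scaffold):
        a = assemble_side_chain(scaffold, 5, "GLU", (-60.0, 180.0, -40.0))
        b = assemble_side_chain(scaffold, 5, "GLU", (-60.0, 180.0, -40.0))
        for name in a:
            assert np.array_equal(a[name], b[name])

    def test_l_chirality(self, scaffold):
        res = scaffold.residue(5)
        placed = assemble_side_chain(scaffold, 5, "CYS", (180.0,))
        improper = dihedral_deg(res["C"], res["N"], res["CA"], placed["CB"])
        assert improper == pytest.approx(122.6, abs=1e-6)


class TestClashCheck:
    def test_open_solvent_passes(self, scaffold):
        probe = {"SG": np.array([40.0, 40.0, 40.0])}
        assert clash_check(probe, scaffold, 5)

    def test_hard_overlap_fails(self, scaffold):
        target = scaffold.residue(10)["CA"]
        probe = {"SG": target + np.array([1.0, 0.0, 0.0])}
        assert not clash_check(probe, scaffold, 5)

    def test_threshold_flip_at_analytic_distance(self):
        # isolated target: residue 2's CA approached from +x, its other
        # backbone atoms tucked on the -x side
        from cadsite.scaffold import Residue, Scaffold

        def res(num, ca):
            ca = np.asarray(ca, float)
            atoms = {"N": ca + (-1.4, 0.3, 0), "CA": ca, "C": ca + (-1.2, -0.9, 0),
                     "O": ca + (-2.2, -1.2, 0.5)}
            return Residue("A", num, "ALA", atoms, {k: k[0] for k in atoms})

        sc = Scaffold([res(1, (-30, 0, 0)), res(2, (0, 0, 0))])
        ctx = ClashContext(sc, tolerance=0.5)
        threshold = VDW_RADII["S"] + VDW_RADII["C"] - 0.5
        flips = []
        for d in np.arange(1.0, 6.0, 0.02):
            probe = {"SG": np.array([d, 0.0, 0.0])}
            flips.append((d, ctx.clashes(probe, 5)))
        transitions = [
            (d1, d2) for (d1, c1), (d2, c2) in zip(flips, flips[1:]) if c1 != c2
        ]
        assert len(transitions) == 1
        d1, d2 = transitions[0]
        assert d1 <= threshold <= d2 + 1e-9


class TestLibraryBuild:
    def test_size_matches_exhaustive_enumeration(self, bundle, scaffold, params):
        from cadsite import apply_mutability
        rotlib = load_rotamer_library(bundle.rotlib_path)
        interface = find_interface(scaffold)
        mutable = apply_mutability(scaffold, bundle.mask, interface)
        lib = build_coordination_library(
            scaffold, mutable, interface, rotlib, params
        )

        # independent exhaustive enumeration of viable candidates
        ctx = ClashContext(scaffold, 0.5)
        count = 0
        for pos in sorted(mutable):
            dihedrals = backbone_dihedrals(scaffold, pos)
            if dihedrals is None:
                continue
            for rt in ("CYS", "HIS", "ASP", "GLU"):
                for rot in rotlib.query(rt, *dihedrals):
                    if rot.probability < 0.01:
                        continue
                    for theta, override in backrub_variants(scaffold, pos):
                        placed = assemble_side_chain(scaffold, pos, rt, rot.chi, override)
                        if ctx.clashes(placed, pos):
                            continue
                        res = scaffold.residue(pos)
                        atoms = {
                            n: override.get((pos, n), res[n])
                            for n in ("N", "CA", "C", "O")
                        }
                        atoms.update(placed)
                        mps = generate_metal_positions(
                            modes_for("sidechain_mutation", rt, atoms), params
                        )
                        if any(
                            ctx.metal_clear(mp.xyz, pos, params.metal_clash_floor)
                            for mp in mps
                        ):
                            count += 1
        n_bbo = sum(1 for e in lib if e.kind == "backbone_oxygen")
        assert len(lib) - n_bbo == count
        assert n_bbo <= len(interface)

    def test_entries_clash_free_and_sorted(self, bundle, scaffold, params):
        rotlib = load_rotamer_library(bundle.rotlib_path)
        interface = find_interface(scaffold)
        from cadsite import apply_mutability
        mutable = apply_mutability(scaffold, bundle.mask, interface)
        lib = build_coordination_library(scaffold, mutable, interface, rotlib, params)
        keys = [e.sort_key() for e in lib]
        assert keys == sorted(keys)
        ctx = ClashContext(scaffold, 0.5)
        for e in lib:
            if e.kind == "sidechain_mutation":
                assert not ctx.clashes(e.placed_atoms, e.position)
            assert e.metal_positions

    def test_all_masked_leaves_backbone_oxygens(self, bundle, scaffold, params):
        rotlib = load_rotamer_library(bundle.rotlib_path)
        interface = find_interface(scaffold)
        lib = build_coordination_library(scaffold, set(), interface, rotlib, params)
        assert lib and all(e.kind == "backbone_oxygen" for e in lib)
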