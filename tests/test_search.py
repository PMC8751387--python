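"""Pair library, set reduction and clique enumeration against brute-force
oracles."""

from itertools import combinations

import numpy as np
import pytest

from cadsite import (
    average_metal_position,
    build_pair_library,
    enumerate_solutions,
    reduce_library,
)
from cadsite.search import choose_member_positions

from conftest import make_entry


def random_library(rng, n_entries, n_clusters=3, spread=0.8):
    """Entries whose metal positions scatter around a few cluster centres,
    so cliques of co-coordinating candidates actually occur."""
    centers = rng.uniform(-4, 4, (n_clusters, 3))
    entries = []
    for i in range(n_entries):
        c = centers[rng.integers(n_clusters)]
        n_pos = rng.integers(1, 4)
        xyzs = c + rng.normal(0, spread, (n_pos, 3))
        restype = rng.choice(["CYS", "HIS", "ASP", "GLU"])
        kind = "sidechain_mutation"
        if rng.random() < 0.15:
            restype, kind = "ALA", "backbone_oxygen"
        entries.append(make_entry(i + 1, xyzs, restype, kind))
    return entries


def bruteforce_pairs(entries, d_max):
    out = set()
    for i, j in combinations(range(len(entries)), 2):
        if entries[i].position == entries[j].position:
            continue
        d = min(
            np.linalg.norm(a.xyz - b.xyz)
            for a in entries[i].metal_positions
            for b in entries[j].metal_positions
        )
        if d < d_max:
            out.add((i, j))
    return out


def bruteforce_reduce(entries, pair_keys):
    alive = set(range(len(entries)))
    while True:
        deg = {
            i: len(
                {
                    entries[j].position
                    for (a, b) in pair_keys
                    for j in ((b,) if a == i else (a,) if b == i else ())
                    if a in alive and b in alive
                }
            )
            for i in alive
        }
        drop = {i for i in alive if deg[i] < 3}
        if not drop:
            return alive
        alive -= drop
        pair_keys = {(a, b) for (a, b) in pair_keys if a in alive and b in alive}


def bruteforce_solutions(entries, pair_keys, sizes, min_cys, geometry_check):
    adjacency = set(pair_keys)
    found = set()
    for size in sizes:
        for combo in combinations(range(len(entries)), size):
            if len({entries[i].position for i in combo}) != size:
                continue
            if any(
                tuple(sorted(p)) not in adjacency for p in combinations(combo, 2)
            ):
                continue
            if sum(entries[i].is_cys_mutation for i in combo) < min_cys:
                continue
            members = [entries[i] for i in combo]
            _, cd = choose_member_positions(members)
            if geometry_check(members, cd):
                found.add(combo)
    return found


def centroid_within(radius):
    def check(members, cd):
        return all(
            min(np.linalg.norm(mp.xyz - cd) for mp in m.metal_positions) < radius
            for m in members
        )
    return check


class TestPairLibrary:
    def test_close_pair_emitted(self):
        a = make_entry(1, [(0, 0, 0)])
        b = make_entry(2, [(1.0, 0, 0)])
        pairs = build_pair_library([a, b], 1.6)
        assert len(pairs) == 1
        assert pairs[0].distance == pytest.approx(1.0)

    def test_threshold_respected_and_fig_value_reachable(self):
        a = make_entry(1, [(0, 0, 0)])
        b = make_entry(2, [(1.7, 0, 0)])
        assert build_pair_library([a, b], 1.6) == []
        assert len(build_pair_library([a, b], 1.8)) == 1

    def test_same_position_never_paired(self):
        a = make_entry(1, [(0, 0, 0)])
        b = make_entry(1, [(0.5, 0, 0)], restype="HIS")
        assert build_pair_library([a, b], 1.6) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        entries = random_library(rng, 20)
        pairs = build_pair_library(entries, 1.6)
        got = {(p.a, p.b) for p in pairs}
        assert got == bruteforce_pairs(entries, 1.6)
        for p in pairs:
            d = np.linalg.norm(
                entries[p.a].metal_positions[p.pos_a].xyz
                - entries[p.b].metal_positions[p.pos_b].xyz
            )
            assert d == pytest.approx(p.distance)
            assert p.distance < 1.6


class TestReduction:
    def test_chain_graph_fully_removed(self):
        entries = [make_entry(i + 1, [(float(i), 0, 0)]) for i in range(4)]
        chain = [
            type("P", (), {"a": i, "b": i + 1})() for i in range(3)
        ]
        from cadsite.search import CoordinationPair

        chain = [CoordinationPair(i, i + 1, 0, 0, 0.5) for i in range(3)]
        kept, rp = reduce_library(entries, chain)
        assert kept == [] and rp == []

    def test_k5_untouched(self):
        from cadsite.search import CoordinationPair

        entries = [make_entry(i + 1, [(0, 0, 0)]) for i in range(5)]
        pairs = [
            CoordinationPair(i, j, 0, 0, 0.1) for i, j in combinations(range(5), 2)
        ]
        kept, rp = reduce_library(entries, pairs)
        assert kept == list(range(5))
        assert len(rp) == 10

    @pytest.mark.parametrize("seed", range(20))
    def test_fixpoint_matches_naive_pruning(self, seed):
        from cadsite.search import CoordinationPair

        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 16))
        entries = [make_entry(i + 1, [(0, 0, 0)]) for i in range(n)]
        keys = {
            (i, j)
            for i, j in combinations(range(n), 2)
            if rng.random() < 0.3
        }
        pairs = [CoordinationPair(i, j, 0, 0, 0.1) for i, j in sorted(keys)]
        kept, _ = reduce_library(entries, pairs)
        assert set(kept) == bruteforce_reduce(entries, keys)


class TestEnumeration:
    def geometry_all(self, members, cd):
        return True

    def test_single_cys_no_solutions(self):
        rng = np.random.default_rng(0)
        entries = [make_entry(1, [(0, 0, 0)], "CYS")] + [
            make_entry(i + 2, [rng.normal(0, 0.2, 3)], "HIS") for i in range(6)
        ]
        pairs = build_pair_library(entries, 1.6)
        sols = enumerate_solutions(
            entries, pairs, geometry_check=self.geometry_all
        )
        assert sols == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(200 + seed)
        entries = random_library(rng, int(rng.integers(8, 16)))
        pairs = build_pair_library(entries, 1.6)
        check = centroid_within(2.5)
        got = {
            s.member_indices
            for s in enumerate_solutions(entries, pairs, geometry_check=check)
        }
        expected = bruteforce_solutions(
            entries, {(p.a, p.b) for p in pairs}, (4, 5), 2, check
        )
        assert got == expected

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        entries = random_library(rng, 14)
        pairs = build_pair_library(entries, 1.6)
        check = centroid_within(2.5)
        base = {
            tuple(sorted(e.position for e in s.members))
            for s in enumerate_solutions(entries, pairs, geometry_check=check)
        }
        perm = list(rng.permutation(len(entries)))
        shuffled = [entries[i] for i in perm]
        pairs2 = build_pair_library(shuffled, 1.6)
        got = {
            tuple(sorted(e.position for e in s.members))
            for s in enumerate_solutions(shuffled, pairs2, geometry_check=check)
        }
        assert got == base

    def test_solution_invariants(self, run_result):
        for sol in run_result.designs:
            assert len(sol.members) in (4, 5)
            assert sol.n_cys >= 2
            positions = [m.position for m in sol.members]
            assert len(set(positions)) == len(positions)
            assert all(ev.verdict != "fail" for ev in sol.evaluations)


class TestAveragePosition:
    def test_mean_of_identical(self):
        p = np.array([1.0, 2.0, 3.0])
        assert np.allclose(average_metal_position([p] * 4), p)

    def test_square_center(self):
        pts = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]
        assert np.allclose(average_metal_position(pts), (0.5, 0.5, 0))

    def test_matches_numpy_mean_random(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 3))
        assert np.allclose(average_metal_position(pts), pts.sum(axis=0) / 5)
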