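"""DCJ distance vs exhaustive search, subcircles, junction anatomy."""

import numpy as np
import pytest

from mitocompare.errors import ContractViolation
from mitocompare.genome import CircularSequence, Interval
from mitocompare.rearrangement import (
    BlockPermutation,
    blocks_to_permutation,
    brute_force_distance,
    characterize_junction,
    dcj_distance,
    dcj_distance_between,
    enumerate_subcircles,
    inversion_only_distance,
)
from mitocompare.repeats import RepeatPair
from mitocompare.simulate import SimulationConfig, simulate_pair
from mitocompare.synteny import detect_blocks


def random_perm(rng, n):
    order = rng.permutation(np.arange(1, n + 1)) * rng.choice([1, -1], size=n)
    return BlockPermutation(tuple(int(x) for x in order))


class TestPermutationNormalization:
    def test_rotation_and_reflection_equivalence(self):
        p = BlockPermutation((2, -3, 1, 4))
        rotated = BlockPermutation((1, 4, 2, -3))
        reflected = BlockPermutation(tuple(-x for x in reversed((2, -3, 1, 4))))
        assert p == rotated == reflected

    def test_invalid_rejected(self):
        with pytest.raises(Exception):
            BlockPermutation((1, 1, 2))

    def test_n_inverted(self):
        assert BlockPermutation((1, -2, 3, -4, 5, -6, 7, 8, 10, 9, 11)).n_inverted == 3


class TestDcjDistance:
    def test_identity_zero(self):
        assert dcj_distance(BlockPermutation((1, 2, 3))).distance == 0

    def test_single_inversion_one(self):
        p = BlockPermutation((1, -2, 3))
        assert dcj_distance(p).distance == 1
        assert brute_force_distance(p) == 1

    def test_transposition_costs_two(self):
        p = BlockPermutation((1, 3, 2, 4))
        assert dcj_distance(p).distance == 2
        assert brute_force_distance(p) == 2

    def test_matches_oracle_randomly(self, rng):
        for n in (4, 5, 6):
            for _ in range(60):
                p = random_perm(rng, n)
                assert dcj_distance(p).distance == brute_force_distance(p)

    def test_invariant_under_representation(self, rng):
        for _ in range(20):
            p = random_perm(rng, 6)
            order = p.signs_and_order
            rot = BlockPermutation(order[2:] + order[:2])
            refl = BlockPermutation(tuple(-x for x in reversed(order)))
            assert dcj_distance(p).distance == dcj_distance(rot).distance
            assert dcj_distance(p).distance == dcj_distance(refl).distance

    def test_triangle_inequality(self, rng):
        for _ in range(30):
            a, b, c = (random_perm(rng, 5) for _ in range(3))
            assert dcj_distance_between(a, c) <= (
                dcj_distance_between(a, b) + dcj_distance_between(b, c)
            )

    def test_brute_force_refuses_large_n(self):
        with pytest.raises(ContractViolation):
            brute_force_distance(BlockPermutation(tuple(range(1, 10))), max_n=8)


class TestInversionOnly:
    def test_small_cases(self):
        assert inversion_only_distance(BlockPermutation((1, 2, 3))) == 0
        assert inversion_only_distance(BlockPermutation((1, -2, 3))) == 1

    def test_never_below_dcj(self, rng):
        for _ in range(10):
            p = random_perm(rng, 5)
            assert inversion_only_distance(p, max_depth=8) >= dcj_distance(p).distance


class TestParameterRecovery:
    def test_simulated_inversions_recovered(self):
        """k planted non-adjacent inversions are recovered as distance k."""
        from mitocompare.simulate import random_nonoverlapping_inversions

        hits = trials = 0
        for k in (2, 4):
            for seed in range(5):
                events = random_nonoverlapping_inversions(10, k, seed=seed * 7 + k)
                cfg = SimulationConfig(
                    seed=seed * 7 + k, ancestor_length_bp=50_000, n_blocks=10, events=events
                )
                t = simulate_pair(cfg)
                blocks = detect_blocks(t.ref, t.derived)
                d = dcj_distance(blocks_to_permutation(blocks)).distance
                trials += 1
                hits += d == k
        assert hits == trials


class TestSubcircles:
    def test_toy_case(self):
        rp = RepeatPair(Interval(1000, 1100), Interval(6000, 6100), 100, "direct", 1.0)
        c1, c2 = enumerate_subcircles(10_000, rp)
        assert {c1.length_bp, c2.length_bp} == {5000}

    def test_conservation_random_placements(self, rng):
        L = 223_412
        for _ in range(100):
            a, b = sorted(rng.integers(0, L, size=2).tolist())
            if a == b:
                continue
            rp = RepeatPair(Interval(a, a + 1), Interval(b, b + 1), 1, "direct", 1.0)
            c1, c2 = enumerate_subcircles(L, rp)
            assert c1.length_bp + c2.length_bp == L

    def test_inverted_pair_rejected(self):
        rp = RepeatPair(Interval(0, 100), Interval(5000, 5100), 100, "inverted", 1.0)
        with pytest.raises(ContractViolation, match="inversion isomer"):
            enumerate_subcircles(10_000, rp)


class TestJunctions:
    def test_clean_inversion_no_loss(self):
        cfg = SimulationConfig(
            seed=31, ancestor_length_bp=20_000, n_blocks=4,
            events=[{"type": "inversion", "start": 1, "end": 1}],
            ref_specific_lengths=[150] * 4,
        )
        t = simulate_pair(cfg)
        blocks = detect_blocks(t.ref, t.derived)
        inv = next(b for b in blocks if b.strand == "-")
        j = characterize_junction(t.ref, t.derived, blocks, (inv.block_id, "end"))
        assert j.lost_bp == 0 and j.inserted_bp == 0

    def test_deletion_and_anonymous_insertion(self):
        """A junction where 253 bp of the reference was lost and 44 bp of
        novel sequence inserted is quantified exactly."""
        rng = np.random.default_rng(32)
        bases = np.array(list("ACGT"))
        left = "".join(bases[rng.integers(4, size=6000)])
        lost = "".join(bases[rng.integers(4, size=253)])
        right = "".join(bases[rng.integers(4, size=6000)])
        novel = "".join(bases[rng.integers(4, size=44)])
        ref = CircularSequence("r", left + lost + right)
        qry = CircularSequence("q", left + novel + right)
        # circularity joins the outer contexts, so the genomes differ by a
        # single origin-wrapping block whose one junction is the indel site
        blocks = detect_blocks(ref, qry)
        assert len(blocks) == 1
        j = characterize_junction(ref, qry, blocks, (blocks[0].block_id, "end"))
        assert j.kind == "collinear"
        assert j.lost_bp == 253
        assert j.inserted_bp == 44
        assert j.inserted_anonymous

    def test_probe_split_prefix_suffix(self):
        """A 798 bp segment surviving as 78 bp + 467 bp flanks (253 bp lost)
        is parsed from a probe alignment as prefix 78 / suffix 467."""
        rng = np.random.default_rng(33)
        bases = np.array(list("ACGT"))

        def rand(n):
            return "".join(bases[rng.integers(4, size=n)])

        p78, m253, s467 = rand(78), rand(253), rand(467)
        refA, refB, z1, z2 = rand(5000), rand(5000), rand(4000), rand(4000)
        # reference carries the intact segment between two other contexts
        ref = CircularSequence("r", refA + p78 + m253 + s467 + refB)
        # query: the segment's flanks survive at a junction between z-contexts
        qry = CircularSequence("q", z1 + refA + p78 + s467 + refB + z2)
        blocks = detect_blocks(ref, qry)
        blk = max(blocks, key=lambda b: b.length_bp)
        probe_start = len(z1) + len(refA)
        probe = Interval(probe_start, probe_start + 78 + 467)
        j = characterize_junction(ref, qry, blocks, (blk.block_id, "end"), probe=probe)
        assert j.kind == "probe"
        assert j.shared_prefix_bp == 78
        assert j.shared_suffix_bp == 467
        assert j.lost_bp == 253
        assert j.inserted_bp == 0
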