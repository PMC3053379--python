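"""Repeat finder: planted recovery, brute-force oracle agreement, coverage."""

import numpy as np
import pytest

from conftest import random_sequence
from mitocompare.genome import CircularSequence, Interval, reverse_complement
from mitocompare.repeats import (
    RepeatPair,
    find_dispersed_repeats,
    find_large_repeats,
    guaranteed_seed,
    repeat_coverage,
    repeats_at_breakpoints,
)
from mitocompare.simulate import PlantedRepeat, SimulationConfig, simulate_ancestor, simulate_pair
from repeat_oracle import brute_force_repeats


def _covers(pair: RepeatPair, start: int, length: int, L: int) -> bool:
    for iv in (pair.interval_a, pair.interval_b):
        s = iv.start
        span = (iv.end - iv.start) % L or L
        for d in (-L, 0, L):
            if s + d <= start and start + length <= s + d + span:
                return True
    return False


class TestGuaranteedSeed:
    def test_default_dispersed_bound(self):
        # 30 bp at 90%: 3 mismatches -> ceil(27/4) = 7
        assert guaranteed_seed(30, 500, 0.90) == 7

    def test_exact_threshold(self):
        assert guaranteed_seed(30, 500, 1.0) == 30


class TestPlantedRecovery:
    def test_exact_direct_pair(self):
        cfg = SimulationConfig(
            seed=3, ancestor_length_bp=10_000, n_blocks=1,
            planted_repeats=[PlantedRepeat(100, "direct", 1.0, positions=(200, 600))],
        )
        s = simulate_ancestor(cfg)
        pairs = find_dispersed_repeats(s)
        hits = [p for p in pairs if _covers(p, 200, 100, 10_000) and p.orientation == "direct"]
        assert hits and hits[0].identity == 1.0

    def test_inverted_pair(self):
        cfg = SimulationConfig(
            seed=4, ancestor_length_bp=8_000, n_blocks=1,
            planted_repeats=[PlantedRepeat(146, "inverted", 1.0, positions=(2000, 4000))],
        )
        s = simulate_ancestor(cfg)
        pairs = find_dispersed_repeats(s)
        assert any(p.orientation == "inverted" and _covers(p, 2000, 146, 8000) for p in pairs)

    def test_degraded_pair_at_threshold(self):
        cfg = SimulationConfig(
            seed=5, ancestor_length_bp=8_000, n_blocks=1,
            planted_repeats=[PlantedRepeat(60, "direct", 0.9, positions=(1000, 5000))],
        )
        s = simulate_ancestor(cfg)
        pairs = find_dispersed_repeats(s)
        assert any(_covers(p, 1000, 60, 8000) and p.identity >= 0.9 for p in pairs)

    def test_wrap_origin_pair(self):
        base = random_sequence(6, 5000)
        unit = random_sequence(7, 120).residues
        res = list(base.residues)
        # one copy straddling the origin
        res[4940:5000] = unit[:60]
        res[0:60] = unit[60:]
        res[2000:2120] = unit
        s = CircularSequence("x", "".join(res))
        pairs = find_dispersed_repeats(s)
        assert any(p.length_bp >= 120 and p.orientation == "direct" for p in pairs)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        cfg = SimulationConfig(
            seed=seed, ancestor_length_bp=4000, n_blocks=1,
            planted_repeats=[
                PlantedRepeat(80, "direct", 0.92, positions=(200, 900)),
                PlantedRepeat(146, "inverted", 1.0, positions=(1500, 2500)),
                PlantedRepeat(35, "direct", 0.9, positions=(3300, 3700)),
            ],
        )
        s = simulate_ancestor(cfg)
        detected = {p.key() for p in find_dispersed_repeats(s)}
        assert detected == brute_force_repeats(s)


class TestLargeRepeats:
    def test_planted_2427_direct(self):
        cfg = SimulationConfig(
            seed=8, ancestor_length_bp=50_000, n_blocks=1,
            planted_repeats=[PlantedRepeat(2427, "direct", 1.0, positions=(5000, 30_000))],
        )
        s = simulate_ancestor(cfg)
        pairs = find_large_repeats(s)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.orientation == "direct" and abs(p.length_bp - 2427) <= 6

    def test_no_large_repeat_empty(self):
        assert find_large_repeats(random_sequence(9, 20_000)) == []


class TestCoverage:
    def test_single_pair_arithmetic(self):
        g = random_sequence(10, 10_000)
        pair = RepeatPair(Interval(100, 200), Interval(700, 800), 100, "direct", 1.0)
        assert repeat_coverage(g, [pair]) == pytest.approx(0.02)

    def test_union_semantics_shared_copy(self):
        g = random_sequence(11, 10_000)
        pairs = [
            RepeatPair(Interval(100, 200), Interval(700, 800), 100, "direct", 1.0),
            RepeatPair(Interval(100, 200), Interval(3000, 3100), 100, "direct", 1.0),
        ]
        assert repeat_coverage(g, pairs) == pytest.approx(0.03)

    def test_monotone_in_thresholds(self):
        cfg = SimulationConfig(
            seed=12, ancestor_length_bp=10_000, n_blocks=1,
            planted_repeats=[
                PlantedRepeat(80, "direct", 0.92, positions=(200, 900)),
                PlantedRepeat(300, "direct", 0.95, positions=(4000, 6000)),
            ],
        )
        s = simulate_ancestor(cfg)
        cov_strict = repeat_coverage(s, find_dispersed_repeats(s, min_identity=0.97))
        cov_loose = repeat_coverage(s, find_dispersed_repeats(s, min_identity=0.90))
        cov_short = repeat_coverage(s, find_dispersed_repeats(s, max_len=100))
        cov_long = repeat_coverage(s, find_dispersed_repeats(s, max_len=500))
        assert cov_loose >= cov_strict
        assert cov_long >= cov_short


class TestRevcompSymmetry:
    def test_pairs_mirrored(self):
        cfg = SimulationConfig(
            seed=13, ancestor_length_bp=6000, n_blocks=1,
            planted_repeats=[
                PlantedRepeat(90, "direct", 1.0, positions=(500, 2000)),
                PlantedRepeat(120, "inverted", 1.0, positions=(3000, 4500)),
            ],
        )
        s = simulate_ancestor(cfg)
        L = s.length_bp
        fwd = {p.key() for p in find_dispersed_repeats(s)}
        rev = set()
        for p in find_dispersed_repeats(reverse_complement(s)):
            # mirror coordinates back to the forward strand
            starts = sorted(
                (L - iv.start - p.length_bp) % L
                for iv in (p.interval_a, p.interval_b)
            )
            rev.add((p.orientation, starts[0], starts[1], p.length_bp))
        assert fwd == rev


class TestBreakpointAnnotation:
    def test_inversion_candidate_flag(self):
        """An inverted repeat pair planted at both flanks of an inverted
        block is flagged as the candidate mediator of the inversion."""
        cfg = SimulationConfig(
            seed=14, ancestor_length_bp=24_000, n_blocks=4,
            events=[{"type": "inversion", "start": 2, "end": 2}],
            planted_repeats=[PlantedRepeat(146, "inverted", 1.0, flank_block=3)],
            qry_specific_lengths=[150] * 4,
            ref_specific_lengths=[150] * 4,
        )
        t = simulate_pair(cfg)
        from mitocompare.synteny import detect_blocks

        blocks = detect_blocks(t.ref, t.derived)
        pairs = find_dispersed_repeats(t.ref)
        anns = repeats_at_breakpoints(blocks, pairs, t.ref.length_bp)
        inverted_block_ids = {b.block_id for b in blocks if b.strand == "-"}
        flagged = {a.block_id for a in anns if a.pattern == "inversion-candidate"}
        assert flagged & inverted_block_ids

    def test_no_repeats_no_annotation(self):
        t = simulate_pair(SimulationConfig(seed=15, ancestor_length_bp=12_000, n_blocks=2))
        from mitocompare.synteny import detect_blocks

        blocks = detect_blocks(t.ref, t.derived)
        assert repeats_at_breakpoints(blocks, [], t.ref.length_bp) == []
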