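"""Synthetic-data generator: determinism, replay, ground-truth consistency."""

import numpy as np
import pytest

from mitocompare.errors import ConfigurationError, ValidationError
from mitocompare.simulate import (
    PlantedRepeat,
    SimulationConfig,
    apply_snps,
    random_nonoverlapping_inversions,
    simulate_ancestor,
    simulate_pair,
    simulate_qpcr,
)
from mitocompare.assay import copy_ratio
from mitocompare.variation import classify_snp


class TestAncestor:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=1, ancestor_length_bp=1000, n_blocks=2)
        assert simulate_ancestor(cfg).residues == simulate_ancestor(cfg).residues

    def test_different_seeds_differ(self):
        a = simulate_ancestor(SimulationConfig(seed=1, ancestor_length_bp=1000, n_blocks=2))
        b = simulate_ancestor(SimulationConfig(seed=2, ancestor_length_bp=1000, n_blocks=2))
        assert a.residues != b.residues

    def test_planted_repeat_engraved(self):
        cfg = SimulationConfig(
            seed=3, ancestor_length_bp=2000, n_blocks=1,
            planted_repeats=[PlantedRepeat(100, "direct", 1.0, positions=(200, 900))],
        )
        s = simulate_ancestor(cfg)
        assert s.residues[200:300] == s.residues[900:1000]

    def test_oversize_repeat_rejected(self):
        cfg = SimulationConfig(
            seed=1, ancestor_length_bp=100, n_blocks=1,
            planted_repeats=[PlantedRepeat(500, "direct", positions=(0, 50))],
        )
        with pytest.raises(ConfigurationError):
            simulate_ancestor(cfg)

    def test_overlapping_repeats_rejected(self):
        cfg = SimulationConfig(
            seed=1, ancestor_length_bp=2000, n_blocks=1,
            planted_repeats=[
                PlantedRepeat(100, "direct", positions=(200, 900)),
                PlantedRepeat(100, "direct", positions=(250, 1500)),
            ],
        )
        with pytest.raises(ConfigurationError):
            simulate_ancestor(cfg)


class TestDerivation:
    def test_zero_events_identity(self):
        cfg = SimulationConfig(seed=2, ancestor_length_bp=6000, n_blocks=3)
        t = simulate_pair(cfg)
        assert t.derived.equals_rotation(t.ancestor)
        assert t.expected_permutation() == [1]

    def test_single_middle_inversion_block_map(self):
        cfg = SimulationConfig(
            seed=2, ancestor_length_bp=9000, n_blocks=3,
            events=[{"type": "inversion", "start": 1, "end": 1}],
            qry_specific_lengths=[150, 150, 150],
            ref_specific_lengths=[150, 150, 150],
        )
        t = simulate_pair(cfg)
        assert [(p.block_id, p.sign) for p in t.block_map] == [(1, 1), (2, -1), (3, 1)]
        assert t.expected_permutation() == [1, -2, 3]

    def test_replay_reproduces_derived_exactly(self):
        cfg = SimulationConfig(
            seed=7, ancestor_length_bp=20000, n_blocks=5,
            events=[
                {"type": "inversion", "start": 1, "end": 2},
                {"type": "transposition", "start": 0, "end": 0, "insert_after": 3},
            ],
            n_snps=25, qry_specific_lengths=[300, 300],
            qry_indels=[{"block": 4, "delta": 40}, {"block": 5, "delta": -30}],
        )
        t = simulate_pair(cfg)
        assert t.replay().residues == t.derived.residues

    def test_event_on_deleted_block_rejected(self):
        cfg = SimulationConfig(
            seed=1, ancestor_length_bp=8000, n_blocks=4,
            events=[{"type": "deletion", "start": 3, "end": 3}],
            qry_indels=[{"block": 4, "delta": 20}],
        )
        with pytest.raises(ConfigurationError, match="absent"):
            simulate_pair(cfg)

    def test_snp_truth_coordinates_and_classes(self):
        cfg = SimulationConfig(
            seed=9, ancestor_length_bp=15000, n_blocks=3,
            events=[{"type": "inversion", "start": 2, "end": 2}],
            n_snps=40, n_transitions=25,
        )
        t = simulate_pair(cfg)
        assert len(t.snp_truth) == 40
        assert sum(1 for s in t.snp_truth if s.snp_class == "transition") == 25
        for s in t.snp_truth:
            assert t.ref.residues[s.ref_pos] == s.ref_base
            assert s.ref_base != s.qry_base
            assert classify_snp(s.ref_base, s.qry_base) == s.snp_class


class TestApplySnps:
    def test_rate_zero(self):
        from conftest import random_sequence

        s = random_sequence(1, 500)
        mut, truth = apply_snps(s, 0.0, 2.0, seed=1)
        assert mut.residues == s.residues and truth == []

    def test_mutated_base_always_differs(self):
        from conftest import random_sequence

        s = random_sequence(2, 5000)
        _, truth = apply_snps(s, 0.01, 2.0, seed=3)
        assert truth and all(t.ref_base != t.qry_base for t in truth)

    def test_transition_fraction_binomial(self):
        """ts:tv = 2 gives a transition fraction of 2/3; the mean over many
        seeded replicates must sit within 3 binomial standard deviations."""
        from conftest import random_sequence

        s = random_sequence(4, 100_000)
        n_ts = n_tot = 0
        for seed in range(20):
            _, truth = apply_snps(s, 0.002, 2.0, seed=seed)
            n_ts += sum(1 for t in truth if t.snp_class == "transition")
            n_tot += len(truth)
        p = 2 / 3
        sd = (p * (1 - p) / n_tot) ** 0.5
        assert abs(n_ts / n_tot - p) < 3 * sd

    def test_rate_bounds(self):
        from conftest import random_sequence

        with pytest.raises(ValidationError):
            apply_snps(random_sequence(1, 100), 0.5, 2.0, seed=1)


class TestSimulateQpcr:
    def test_equal_copies_equal_ct(self):
        s = simulate_qpcr(100, 100, 1.0, 1.0, ct_noise_sd=0.0)
        assert s.targets["a"].mean_ct == pytest.approx(s.targets["b"].mean_ct)

    def test_1024_fold_is_ten_cycles(self):
        s = simulate_qpcr(1024, 1, 1.0, 1.0, ct_noise_sd=0.0)
        assert s.targets["b"].mean_ct - s.targets["a"].mean_ct == pytest.approx(10.0)

    def test_nonpositive_copies_rejected(self):
        with pytest.raises(ValidationError):
            simulate_qpcr(0, 10)

    def test_ratio_recovery_under_noise(self):
        ok = 0
        for seed in range(20):
            s = simulate_qpcr(5000, 5, 1.0, 1.0, ct_noise_sd=0.1, seed=seed)
            r = copy_ratio(s, "a", "b")
            ok += abs(r.ratio / 1000 - 1) < 0.10
        assert ok >= 18


class TestInversionDesigns:
    def test_nonadjacent_blocks(self):
        for seed in range(10):
            events = random_nonoverlapping_inversions(10, 4, seed=seed)
            picks = sorted(e["start"] for e in events)
            assert len(picks) == 4
            gaps = [b - a for a, b in zip(picks, picks[1:])]
            assert all(g >= 2 for g in gaps)
            assert (picks[0] + 10) - picks[-1] >= 2

    def test_too_many_rejected(self):
        with pytest.raises(ConfigurationError):
            random_nonoverlapping_inversions(6, 4, seed=1)
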