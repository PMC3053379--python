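"""Primer binding model, multiplex products, efficiency and copy ratios."""

import numpy as np
import pytest

from conftest import random_sequence
from mitocompare.assay import (
    PrimerPair,
    QpcrSample,
    TargetReadout,
    copy_ratio,
    estimate_efficiency,
    insilico_pcr,
    multiplex_pcr,
    read_ct_table,
    read_primer_table,
)
from mitocompare.errors import ContractViolation, EstimationError, ValidationError
from mitocompare.genome import CircularSequence, reverse_complement
from mitocompare.simulate import simulate_qpcr


def _pair_from_template(tpl, start, product, name="P"):
    fwd = tpl.residues[start : start + 20]
    rev = reverse_complement(
        CircularSequence("t", tpl.residues[start + product - 20 : start + product])
    ).residues
    return PrimerPair(name, fwd, rev)


class TestPrimerValidation:
    def test_length_bounds(self):
        with pytest.raises(ValidationError):
            PrimerPair("x", "ACGT", "ACGTACGTACGTACGTAC")

    def test_alphabet(self):
        with pytest.raises(ValidationError):
            PrimerPair("x", "ACGTACGTACGTACGTN", "ACGTACGTACGTACGTAC")


class TestInsilicoPcr:
    def test_planted_product(self):
        tpl = random_sequence(61, 4000)
        pair = _pair_from_template(tpl, 500, 500)
        amps = insilico_pcr(tpl, pair)
        assert [a.length_bp for a in amps] == [500]
        assert amps[0].interval.start == 500

    def test_rotation_invariance_with_origin_wrap(self):
        tpl = random_sequence(61, 4000)
        pair = _pair_from_template(tpl, 500, 500)
        rot = tpl.rotated(700)  # product now spans the origin
        amps = insilico_pcr(rot, pair)
        assert [a.length_bp for a in amps] == [500]
        assert amps[0].interval.wraps_origin

    def test_mirrored_on_reverse_complement(self):
        tpl = random_sequence(62, 4000)
        pair = _pair_from_template(tpl, 1000, 300)
        amps = insilico_pcr(reverse_complement(tpl), pair)
        assert [a.length_bp for a in amps] == [300]

    def test_three_prime_seed_mismatches_block_binding(self):
        tpl = random_sequence(63, 4000)
        fwd = tpl.residues[500:520]
        rev_seq = reverse_complement(CircularSequence("t", tpl.residues[980:1000])).residues
        # corrupt 3 bases inside the reverse primer's 3' decamer
        broken = list(rev_seq)
        for i in (12, 15, 18):
            broken[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[broken[i]]
        pair = PrimerPair("broken", fwd, "".join(broken))
        assert insilico_pcr(tpl, pair) == []

    def test_distal_mismatches_tolerated(self):
        tpl = random_sequence(64, 4000)
        fwd = list(tpl.residues[500:520])
        for i in (0, 5):  # 5' end, outside the seed
            fwd[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[fwd[i]]
        rev = reverse_complement(CircularSequence("t", tpl.residues[980:1000])).residues
        amps = insilico_pcr(tpl, PrimerPair("mm", "".join(fwd), rev))
        assert [a.length_bp for a in amps] == [500]
        assert amps[0].fwd_site.mismatches == 2


class TestMultiplex:
    def test_two_templates_one_band_each(self):
        tpl_a, tpl_b = random_sequence(65, 5000, ident="a"), random_sequence(66, 5000, ident="b")
        pa = _pair_from_template(tpl_a, 600, 841, "Ppol")
        pb = _pair_from_template(tpl_b, 900, 226, "Pnap")
        assert [a.length_bp for a in multiplex_pcr(tpl_a, [pa, pb])] == [841]
        assert [a.length_bp for a in multiplex_pcr(tpl_b, [pa, pb])] == [226]

    def test_shared_forward_two_products(self):
        tpl = random_sequence(67, 6000)
        fwd = tpl.residues[1000:1020]
        rev1 = reverse_complement(CircularSequence("t", tpl.residues[1400:1420])).residues
        rev2 = reverse_complement(CircularSequence("t", tpl.residues[2980:3000])).residues
        pairs = [PrimerPair("s1", fwd, rev1), PrimerPair("s2", fwd, rev2)]
        lengths = sorted(a.length_bp for a in multiplex_pcr(tpl, pairs))
        assert lengths == [420, 2000]

    def test_no_binding_empty(self):
        tpl = random_sequence(68, 3000)
        other = random_sequence(69, 3000)
        pair = _pair_from_template(other, 100, 400)
        assert multiplex_pcr(tpl, [pair]) == []

    def test_empty_pool_rejected(self):
        with pytest.raises(ContractViolation):
            multiplex_pcr(random_sequence(70, 2000), [])


class TestEfficiency:
    def test_perfect_doubling_slope(self):
        fit = estimate_efficiency([(0, 20.0), (-1, 23.3219), (-2, 26.6438), (-3, 29.9657)])
        assert fit.efficiency == pytest.approx(1.000, abs=1e-3)

    def test_slope_minus_346(self):
        pts = [(d, 20.0 - 3.46 * d) for d in (0, -1, -2, -3)]
        fit = estimate_efficiency(pts)
        assert fit.efficiency == pytest.approx(0.945, abs=0.001)

    def test_two_points_rejected(self):
        with pytest.raises(ContractViolation):
            estimate_efficiency([(0, 20.0), (-1, 23.3)])

    def test_positive_slope_rejected(self):
        with pytest.raises(EstimationError):
            estimate_efficiency([(0, 20.0), (-1, 18.0), (-2, 16.0)])


class TestCopyRatio:
    def _sample(self, ct_a, ct_b, e_a=1.0, e_b=1.0):
        return QpcrSample(
            name="s",
            targets={
                "a": TargetReadout((ct_a,), e_a),
                "b": TargetReadout((ct_b,), e_b),
            },
        )

    def test_equal_everything_unity(self):
        r = copy_ratio(self._sample(20.0, 20.0), "a", "b")
        assert r.ratio == pytest.approx(1.0)

    def test_ten_cycles_is_1024(self):
        r = copy_ratio(self._sample(10.0, 20.0), "a", "b")
        assert r.ratio == pytest.approx(1024.0)

    def test_published_efficiencies_closed_form(self):
        # E_a = 99.7%, E_b = 100.1%, equal Ct 20 -> (2.001/1.997)^20
        r = copy_ratio(self._sample(20.0, 20.0, 0.997, 1.001), "a", "b")
        assert r.ratio == pytest.approx((2.001 / 1.997) ** 20)
        assert r.ratio == pytest.approx(1.041, abs=0.002)

    def test_reciprocity_exact(self):
        s = self._sample(17.3, 24.9, 0.95, 1.02)
        assert copy_ratio(s, "a", "b").ratio * copy_ratio(s, "b", "a").ratio == pytest.approx(1.0, rel=1e-12)

    def test_missing_target(self):
        with pytest.raises(ValidationError):
            copy_ratio(self._sample(20, 20), "a", "c")

    def test_end_to_end_recovery(self):
        ok = 0
        for seed in range(25):
            s = simulate_qpcr(10_000, 10, 1.0, 1.0, ct_noise_sd=0.1, seed=seed)
            ok += abs(copy_ratio(s, "a", "b").ratio / 1000 - 1) < 0.10
        assert ok >= 23


class TestTables:
    def test_primer_table_roundtrip(self, tmp_path):
        p = tmp_path / "primers.tsv"
        p.write_text(
            "name\tfwd\trev\texpected_mitotype\texpected_product_bp\n"
            "P1\tACGTACGTACGTACGTAC\tTTGCACGTACGTACGTCA\tpol\t841\n"
        )
        pairs = read_primer_table(p)
        assert pairs[0].name == "P1" and pairs[0].expected_product_bp == 841

    def test_ct_table_grouping(self, tmp_path):
        p = tmp_path / "ct.csv"
        p.write_text(
            "sample,target,replicate,ct,efficiency\n"
            "s1,orf224,1,20.1,0.997\n"
            "s1,orf224,2,20.3,0.997\n"
            "s1,orf222,1,25.0,1.001\n"
        )
        (s,) = read_ct_table(p)
        assert s.targets["orf224"].mean_ct == pytest.approx(20.2)
        r = copy_ratio(s, "orf224", "orf222")
        assert r.ratio > 1
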