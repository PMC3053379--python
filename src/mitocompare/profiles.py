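"""The pol/nap study profile: a full-scale two-mitotype scenario.

This module encodes, as simulation inputs, the published structural
configuration of the two *Brassica napus* mitotypes: a 223,412 bp reference
genome (the pol arrangement) at 45.22% G+C; eleven syntenic blocks of which
three are inverted in the other mitotype, separated by five recombination
events (three block inversions plus one transposition, which the DCJ model
counts as two events); a 2,427 bp direct repeat pair whose copies sit
86,232 bp apart, so that recombination across it yields 86.2 kb and
137.1 kb subgenomic circles; dispersed 30–500 bp repeats covering 4.75% of
the reference; mitotype-specific segments making up 4.53% of the reference
and 3.63% of the query; small within-block indels leaving the query
1,559 bp shorter; and exactly 197 SNPs (102 transitions, 95 transversions).

Only the residue content, SNP/indel placements and primer extraction are
random (seeded); the structural design constants above are fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assay import PrimerPair
from .errors import ConfigurationError
from .genome import CircularSequence, reverse_complement
from .simulate import (
    PlantedRepeat,
    SimulationConfig,
    SimulationTruth,
    simulate_pair,
)

POL_LENGTH = 223_412
LENGTH_DIFFERENCE = 1_559
GC = 0.4522
N_BLOCKS = 11
POL_SPECIFIC_BP = round(0.0453 * POL_LENGTH)  # 10,121
NAP_LENGTH = POL_LENGTH - LENGTH_DIFFERENCE  # 221,853
NAP_SPECIFIC_BP = round(0.0363 * NAP_LENGTH)  # 8,053
CORE_POL = POL_LENGTH - POL_SPECIFIC_BP  # 213,291
CORE_NAP = NAP_LENGTH - NAP_SPECIFIC_BP  # 213,800
NET_INDEL = CORE_NAP - CORE_POL  # +509 bp gained by the query blocks
LARGE_REPEAT_BP = 2_427
SUBCIRCLE_SEPARATION = 86_232  # start-to-start distance of the direct pair
DISPERSED_COVERAGE_BP = round(0.0475 * POL_LENGTH)  # 10,612
N_SNPS = 197
N_TRANSITIONS = 102

# three single-block inversions plus one single-block transposition;
# under DCJ (transposition = 2 operations) the minimum event count is 5
EVENTS = [
    {"type": "inversion", "start": 1, "end": 1},
    {"type": "inversion", "start": 3, "end": 3},
    {"type": "inversion", "start": 5, "end": 5},
    {"type": "transposition", "start": 8, "end": 8, "insert_after": 9},
]

# within-block insertions in the query; each under the 100 bp chaining gap
QRY_INDELS = [
    {"block": 2, "delta": 70},
    {"block": 3, "delta": 70},
    {"block": 5, "delta": 70},
    {"block": 7, "delta": 70},
    {"block": 8, "delta": 70},
    {"block": 10, "delta": 70},
    {"block": 11, "delta": 70},
    {"block": 1, "delta": 19},
]

# dispersed repeat copy lengths; both copies of each pair are planted at
# distinct loci, so detector coverage is 2 * sum(lengths) = 10,612 bp
DISPERSED_LENGTHS = [146, 233, 50] + [450] * 10 + [377]
assert 2 * sum(DISPERSED_LENGTHS) == DISPERSED_COVERAGE_BP


def _specific_lengths(total: int, n: int) -> list[int]:
    base, extra = divmod(total, n)
    return [base + (1 if i < extra else 0) for i in range(n)]


@dataclass
class PolNapProfile:
    truth: SimulationTruth
    pol: CircularSequence
    nap: CircularSequence
    config: SimulationConfig


def _pol_coord_of_ancestor(a: int, block_starts, insert_lens) -> int:
    """Map an ancestor coordinate into the reference (with junction inserts)."""
    bi = int(np.searchsorted(block_starts, a, side="right")) - 1
    return a + sum(insert_lens[:bi])


def _plan_repeats(rng: np.random.Generator) -> list[PlantedRepeat]:
    """Choose ancestor loci for every planted repeat, non-overlapping, inside
    blocks, clear of block edges, with the large pair at the separation that
    fixes the subgenomic-circle sizes."""
    block_len = CORE_POL // N_BLOCKS
    lengths = [block_len + (1 if i < CORE_POL % N_BLOCKS else 0) for i in range(N_BLOCKS)]
    starts = np.concatenate(([0], np.cumsum(lengths)))[:-1]
    insert_lens = _specific_lengths(POL_SPECIFIC_BP, N_BLOCKS)

    margin = 350
    taken: list[tuple[int, int]] = []

    def free(s, ell):
        if s < 0 or s + ell > CORE_POL:
            return False
        bi = int(np.searchsorted(starts, s, side="right")) - 1
        if s < starts[bi] + margin or s + ell > starts[bi] + lengths[bi] - margin:
            return False
        return all(not (s < te + 120 and t - 120 < s + ell) for t, te in taken)

    planted = []

    # large direct pair: find ancestor coords whose reference coordinates are
    # exactly SUBCIRCLE_SEPARATION apart
    placed = False
    for a1 in range(2_000, CORE_POL, 997):
        p1 = _pol_coord_of_ancestor(a1, starts, insert_lens)
        p2 = p1 + SUBCIRCLE_SEPARATION
        # invert the reference coordinate map
        a2 = p2
        for bi in range(N_BLOCKS):
            cand = p2 - sum(insert_lens[:bi])
            if starts[bi] <= cand < starts[bi] + lengths[bi]:
                a2 = cand
                break
        else:
            continue
        if _pol_coord_of_ancestor(a2, starts, insert_lens) != p2:
            continue
        if free(a1, LARGE_REPEAT_BP) and free(a2, LARGE_REPEAT_BP):
            planted.append(
                PlantedRepeat(LARGE_REPEAT_BP, "direct", 1.0, positions=(a1, a2))
            )
            taken.extend([(a1, a1 + LARGE_REPEAT_BP), (a2, a2 + LARGE_REPEAT_BP)])
            placed = True
            break
    if not placed:
        raise ConfigurationError("could not place the large direct repeat pair")

    for i, ell in enumerate(DISPERSED_LENGTHS):
        orientation = "inverted" if i % 3 == 0 else "direct"
        for _ in range(10_000):
            s1 = int(rng.integers(CORE_POL))
            s2 = int(rng.integers(CORE_POL))
            if abs(s2 - s1) < ell + 240:
                continue
            if free(s1, ell) and free(s2, ell):
                planted.append(
                    PlantedRepeat(ell, orientation, 1.0, positions=tuple(sorted((s1, s2))))
                )
                taken.extend([(s1, s1 + ell), (s2, s2 + ell)])
                break
        else:
            raise ConfigurationError("could not place a dispersed repeat pair")
    return planted


def polnap_profile(seed: int = 0) -> PolNapProfile:
    """Build the full-scale two-mitotype scenario for the given seed."""
    rng = np.random.default_rng(seed)
    planted = _plan_repeats(rng)
    config = SimulationConfig(
        seed=seed,
        ancestor_length_bp=CORE_POL,
        n_blocks=N_BLOCKS,
        gc_content=GC,
        events=[dict(e) for e in EVENTS],
        n_snps=N_SNPS,
        n_transitions=N_TRANSITIONS,
        planted_repeats=planted,
        ref_specific_lengths=_specific_lengths(POL_SPECIFIC_BP, N_BLOCKS),
        qry_specific_lengths=_specific_lengths(NAP_SPECIFIC_BP, N_BLOCKS),
        qry_indels=[dict(d) for d in QRY_INDELS],
    )
    truth = simulate_pair(config)
    pol = CircularSequence(id="pol", residues=truth.ref.residues)
    nap = CircularSequence(id="nap", residues=truth.derived.residues)
    return PolNapProfile(truth=truth, pol=pol, nap=nap, config=config)


# ---------------------------------------------------------------------------
# diagnostic multiplex primers (extracted from the generated genomes)


def diagnostic_primers(profile: PolNapProfile) -> list[PrimerPair]:
    """A two-pair multiplex set producing an 841 bp product from the
    reference-specific sequence and a 226 bp product from the query-specific
    sequence — one diagnostic band per mitotype, as in a coexistence assay."""
    out = []
    for name, genome, specific, product in (
        ("P10pol", profile.pol, profile.truth.ref_specific, 841),
        ("P10nap", profile.nap, profile.truth.qry_specific, 226),
    ):
        seg = next(iv for iv in specific if iv.span_bp(genome.length_bp) >= product + 40)
        s = seg.start + 20
        fwd = genome.residues[s : s + 20]
        rev = reverse_complement(
            CircularSequence("t", genome.residues[s + product - 20 : s + product])
        ).residues
        out.append(PrimerPair(name=name, fwd_seq=fwd, rev_seq=rev,
                              expected_mitotype=name[3:], expected_product_bp=product))
    return out


# ---------------------------------------------------------------------------
# divergent reading-frame pair (nucleotide vs peptide similarity)


_FOURFOLD = ["CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"]  # NN + any 3rd base
_STOPS = {"TAA", "TAG", "TGA"}


def divergent_orf_pair(
    seed: int = 0,
    n_codons: int = 100,
    n_nonsyn: int = 23,
    n_syn: int = 25,
) -> tuple[str, str]:
    """Two reading frames differing by single-nucleotide changes in
    ``n_nonsyn`` codons (amino acid replaced) and ``n_syn`` codons
    (synonymous third-position change); with the defaults the pair shows
    84% nucleotide and 77% peptide identity in a gapless global alignment."""
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    codons_a, codons_b = [], []
    roles = ["syn"] * n_syn + ["nonsyn"] * n_nonsyn + ["same"] * (
        n_codons - n_syn - n_nonsyn
    )
    roles = [roles[i] for i in rng.permutation(n_codons)]
    for role in roles:
        if role == "syn":
            fam = _FOURFOLD[rng.integers(len(_FOURFOLD))]
            third = rng.integers(4)
            alt = (third + 1 + rng.integers(3)) % 4
            codons_a.append(fam + bases[third])
            codons_b.append(fam + bases[alt])
        else:
            while True:
                cod = "".join(bases[rng.integers(4)] for _ in range(3))
                if cod in _STOPS:
                    continue
                if role == "same":
                    codons_a.append(cod)
                    codons_b.append(cod)
                    break
                aa = str(Seq(cod).translate())
                pos = int(rng.integers(3))
                alts = [b for b in bases if b != cod[pos]]
                rng.shuffle(alts)
                done = False
                for nb in alts:
                    alt_cod = cod[:pos] + nb + cod[pos + 1 :]
                    if alt_cod in _STOPS:
                        continue
                    if str(Seq(alt_cod).translate()) != aa:
                        codons_a.append(cod)
                        codons_b.append(alt_cod)
                        done = True
                        break
                if done:
                    break
    return "".join(codons_a), "".join(codons_b)
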