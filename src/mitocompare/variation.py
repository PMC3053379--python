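"""SNP census inside syntenic blocks and ORF similarity.

SNPs are called only within retained 1:1 synteny blocks — mitotype-specific
sequence has no homologous counterpart and contributes nothing to the
census.  Mismatched alignment columns within a configurable distance of an
alignment gap are excluded, guarding against indel-placement artifacts.
Transitions are the purine–purine and pyrimidine–pyrimidine changes
(A<->G, C<->T); everything else is a transversion.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Seq import Seq

from .errors import ContractViolation, ValidationError
from .genome import CircularSequence
from .synteny import SyntenyBlock

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SnpRecord:
    block_id: int
    ref_pos: int
    qry_pos: int
    ref_base: str
    qry_base: str
    snp_class: str


@dataclass(frozen=True)
class SnpSummary:
    n_total: int
    n_ts: int
    n_tv: int
    denominator_bp: int
    rate_per_10kb: float


@dataclass(frozen=True)
class SimilarityResult:
    nt_identity: float
    aa_identity: float
    alignment_length_nt: int
    warnings: tuple = ()


def classify_snp(ref_base: str, qry_base: str) -> str:
    """'transition' for A<->G / C<->T, 'transversion' otherwise."""
    a, b = ref_base.upper(), qry_base.upper()
    if a not in "ACGT" or b not in "ACGT":
        raise ValidationError(f"ambiguous or invalid bases {a!r}/{b!r}")
    if a == b:
        raise ValidationError("bases are equal; not a SNP")
    if (a in _PURINES) == (b in _PURINES):
        return "transition"
    return "transversion"


def call_snps(
    ref: CircularSequence,
    qry: CircularSequence,
    blocks: list[SyntenyBlock],
    gap_exclusion_bp: int = 5,
) -> list[SnpRecord]:
    """Every mismatched non-gap column of every block alignment.

    Columns within ``gap_exclusion_bp`` columns of an indel are skipped
    (set 0 to disable).  Positions are reported on both genomes' forward
    strands; the query base is given in the alignment orientation, i.e.
    complemented for minus-strand blocks, so the ref->qry change is read
    directly off the homologous strands.
    """
    Lr, Lq = ref.length_bp, qry.length_bp
    out = []
    for b in blocks:
        if not b.cigar:
            raise ContractViolation(f"block {b.block_id} carries no alignment")
        # column flags for gap proximity
        cols = []
        for op, ln in b.cigar:
            cols.extend([op] * ln)
        near_gap = [False] * len(cols)
        if gap_exclusion_bp > 0:
            for i, op in enumerate(cols):
                if op in "ID":
                    lo = max(0, i - gap_exclusion_bp)
                    hi = min(len(cols), i + gap_exclusion_bp + 1)
                    for t in range(lo, hi):
                        near_gap[t] = True
        roff = qoff = 0
        rstart = b.ref_interval.start
        qstart = b.qry_interval.start
        qspan = b.qry_interval.span_bp(Lq)
        for i, op in enumerate(cols):
            if op == "X" and not near_gap[i]:
                ref_pos = (rstart + roff) % Lr
                ref_base = ref.residues[ref_pos]
                if b.strand == "+":
                    qry_pos = (qstart + qoff) % Lq
                    qry_base = qry.residues[qry_pos]
                else:
                    qry_pos = (qstart + qspan - 1 - qoff) % Lq
                    qry_base = _COMP.get(qry.residues[qry_pos], "N")
                if ref_base in "ACGT" and qry_base in "ACGT":
                    out.append(
                        SnpRecord(
                            block_id=b.block_id,
                            ref_pos=ref_pos,
                            qry_pos=qry_pos,
                            ref_base=ref_base,
                            qry_base=qry_base,
                            snp_class=classify_snp(ref_base, qry_base),
                        )
                    )
            if op in "=X":
                roff += 1
                qoff += 1
            elif op == "D":
                roff += 1
            elif op == "I":
                qoff += 1
    out.sort(key=lambda r: r.ref_pos)
    return out


def summarize_snps(records: list[SnpRecord], denominator_bp: int) -> SnpSummary:
    """Counts, ts/tv split and the rate per 10 kb over the given denominator."""
    if denominator_bp <= 0:
        raise ValidationError("denominator must be positive")
    n_ts = sum(1 for r in records if r.snp_class == "transition")
    n = len(records)
    return SnpSummary(
        n_total=n,
        n_ts=n_ts,
        n_tv=n - n_ts,
        denominator_bp=denominator_bp,
        rate_per_10kb=10_000.0 * n / denominator_bp,
    )


def _aligner(protein: bool) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -8
    al.extend_gap_score = -1
    return al


def _identity_from_alignment(aln) -> tuple[float, int]:
    a, b = str(aln[0]), str(aln[1])
    cols = len(a)
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / cols, cols


def pairwise_orf_similarity(seq_a: str, seq_b: str) -> SimilarityResult:
    """Global nucleotide and peptide identity of two reading frames.

    Nucleotide identity is matches over all alignment columns (gaps count).
    Both sequences are translated in frame 1 with the standard genetic code
    (plant mitochondria use the standard code); an internal stop truncates
    the translation and is recorded as a warning.
    """
    if not seq_a or not seq_b:
        raise ValidationError("empty sequence")
    nt = _aligner(False).align(seq_a.upper(), seq_b.upper())[0]
    nt_identity, cols = _identity_from_alignment(nt)
    warnings = []
    prots = []
    for name, s in (("a", seq_a), ("b", seq_b)):
        trimmed = s[: len(s) - len(s) % 3]
        aa = str(Seq(trimmed).translate())
        if "*" in aa[:-1]:
            warnings.append(f"internal stop in sequence {name}; translation truncated")
        aa = aa.split("*")[0]
        if not aa:
            raise ValidationError(f"sequence {name} translates to nothing")
        prots.append(aa)
    pa = _aligner(True).align(prots[0], prots[1])[0]
    aa_identity, _ = _identity_from_alignment(pa)
    return SimilarityResult(
        nt_identity=round(nt_identity, 6),
        aa_identity=round(aa_identity, 6),
        alignment_length_nt=cols,
        warnings=tuple(warnings),
    )


def snps_to_vcf(
    records: list[SnpRecord], ref: CircularSequence, path
) -> None:
    """Write the SNP census as a minimal VCF (reference coordinates,
    1-based per the standard)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.id},length={ref.length_bp}>\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="transition or transversion">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(
                f"{ref.id}\t{r.ref_pos + 1}\t.\t{r.ref_base}\t{r.qry_base}\t.\t.\tCLASS={r.snp_class}\n"
            )
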