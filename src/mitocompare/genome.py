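"""Circular DNA sequence model, file I/O and coordinate arithmetic.

Plant mitochondrial genomes are (at least formally) circular molecules with
no distinguished origin, so every coordinate reported by this package refers
to the *canonical rotation* of the forward strand: the lexicographically
minimal rotation, which is well defined and deterministic.  Coordinates are
0-based, half-open.  Intervals may wrap the origin; a wrapping interval has
``start > end`` and denotes ``[start, L) ∪ [0, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ContractViolation, UndefinedValueError, ValidationError

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric codes used by the numpy-based scanners (repeats, synteny, assay)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(residues: str) -> np.ndarray:
    """Map a residue string to a uint8 code array (A=0, C=1, G=2, T=3, N=4)."""
    return _ENCODE_TABLE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[codes]


def _normalize_residues(raw: str, *, record_id: str = "?") -> str:
    s = raw.upper().replace("U", "T")
    bad = set(s) - ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(s) if c in bad)
        raise ValidationError(
            f"record {record_id!r}: illegal residue {s[pos]!r} at position {pos}"
        )
    return s


@dataclass(frozen=True)
class CircularSequence:
    """A DNA sequence with explicit (circular or linear) topology.

    Equality of two *circular* sequences is decidable up to rotation via
    :meth:`equals_rotation`; dataclass equality remains literal.
    """

    id: str
    residues: str
    topology: str = "circular"

    def __post_init__(self):
        if self.topology not in ("circular", "linear"):
            raise ValidationError(f"unknown topology {self.topology!r}")
        object.__setattr__(
            self, "residues", _normalize_residues(self.residues, record_id=self.id)
        )
        if len(self.residues) == 0:
            raise ValidationError(f"record {self.id!r}: empty sequence")

    @property
    def length_bp(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def codes(self) -> np.ndarray:
        return encode(self.residues)

    def rotated(self, offset: int) -> "CircularSequence":
        """Rotate so that current position ``offset`` becomes position 0."""
        if not self.is_circular:
            raise ContractViolation("cannot rotate a linear sequence")
        off = offset % self.length_bp
        return replace(self, residues=self.residues[off:] + self.residues[:off])

    def equals_rotation(self, other: "CircularSequence") -> bool:
        """True iff the two circular sequences are equal up to rotation."""
        if self.length_bp != other.length_bp:
            return False
        if not (self.is_circular and other.is_circular):
            return self.residues == other.residues
        return self.residues in (other.residues + other.residues)


def reverse_complement(seq: CircularSequence) -> CircularSequence:
    """Watson–Crick reverse complement (N maps to N); an involution."""
    return replace(seq, residues=seq.residues.translate(_COMPLEMENT)[::-1])


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically minimal rotation."""
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_rotation(seq: CircularSequence) -> tuple[CircularSequence, int]:
    """Return the lexicographically minimal rotation and the offset applied.

    All downstream coordinates (blocks, repeats, SNPs, amplicons) refer to
    this rotation, which makes reports reproducible regardless of how the
    input record happened to be linearized.
    """
    if not seq.is_circular:
        raise ContractViolation("canonical_rotation requires a circular sequence")
    off = _least_rotation(seq.residues)
    return seq.rotated(off), off


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a circle; ``start > end`` wraps the origin."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.start < 0 or self.end < 0:
            raise ValidationError("negative coordinate")

    @property
    def wraps_origin(self) -> bool:
        return self.start >= self.end

    def span_bp(self, L: int) -> int:
        """Length of the interval on a circle of length ``L``; in (0, L]."""
        if not (0 <= self.start < L and 0 < self.end <= L or self.wraps_origin):
            raise ContractViolation(f"interval {self} outside [0,{L})")
        if self.start >= L or self.end > L:
            raise ContractViolation(f"interval {self} outside [0,{L})")
        span = (self.end - self.start) % L
        if span == 0:
            if self.start == self.end:
                raise ContractViolation("zero-length interval")
            span = L
        return span

    def shifted(self, delta: int, L: int) -> "Interval":
        return Interval((self.start + delta) % L, ((self.end - 1 + delta) % L) + 1, self.strand)

    def positions(self, L: int) -> np.ndarray:
        """All circle positions covered, in 5'→3' order on the + strand."""
        return (np.arange(self.start, self.start + self.span_bp(L)) % L)


def subsequence(seq: CircularSequence, iv: Interval) -> str:
    """Extract the residues of ``iv``; strand '-' returns the reverse complement."""
    L = seq.length_bp
    span = iv.span_bp(L)
    if iv.wraps_origin:
        if not seq.is_circular:
            raise ContractViolation("wrapping interval on a linear sequence")
        s = seq.residues[iv.start:] + seq.residues[: iv.end]
    else:
        s = seq.residues[iv.start : iv.end]
    assert len(s) == span
    if iv.strand == "-":
        s = s.translate(_COMPLEMENT)[::-1]
    return s


def gc_content(seq: CircularSequence) -> float:
    """(G+C)/(A+C+G+T); N excluded from numerator and denominator."""
    c = seq.codes()
    acgt = int(np.count_nonzero(c < 4))
    if acgt == 0:
        raise UndefinedValueError(f"record {seq.id!r}: GC content undefined (all N)")
    gc = int(np.count_nonzero((c == 1) | (c == 2)))
    return gc / acgt


def read_sequences(path, format: str = "fasta", topology: str = "circular") -> list[CircularSequence]:
    """Read FASTA or GenBank records as (by default) circular sequences.

    Sequence only; GenBank features are ignored.  Residues are upper-cased
    and U is mapped to T.  Illegal residues raise :class:`ValidationError`
    naming the record.
    """
    if format not in ("fasta", "genbank"):
        raise ValidationError(f"unsupported format {format!r}")
    records = list(SeqIO.parse(str(path), format))
    return [
        CircularSequence(id=r.id, residues=str(r.seq), topology=topology)
        for r in records
    ]


def write_fasta(path, seqs) -> None:
    """Write sequences as 60-column-wrapped FASTA."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")
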