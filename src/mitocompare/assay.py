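"""In-silico PCR and TaqMan-style relative copy-number quantification.

The primer binding model is deliberately simple and fully exposed: a
primer anneals where its 3'-most ``seed_3prime`` bases match the template
exactly and the remaining (5') bases carry at most ``max_mismatch_5prime``
mismatches.  Any two sites on opposite strands with 3' ends facing each
other within ``max_product`` yield an amplicon; circular templates can
produce origin-spanning products.

Copy-number ratios follow the exponential amplification model: with
per-cycle efficiency E, the starting amount is proportional to
``(1+E)^(-Ct)``, so the ratio of target a to target b is
``(1+E_b)^(Ct_b) / (1+E_a)^(Ct_a)``.  Efficiencies come from a dilution
series: E = 10^(-1/slope) - 1, where slope is d(Ct)/d(log10 input).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractViolation, EstimationError, ValidationError
from .genome import CircularSequence, Interval, encode, complement_codes

# ---------------------------------------------------------------------------
# data types


@dataclass(frozen=True)
class PrimerPair:
    name: str
    fwd_seq: str
    rev_seq: str
    expected_mitotype: str = "both"
    expected_product_bp: int | None = None

    def __post_init__(self):
        for label, s in (("fwd", self.fwd_seq), ("rev", self.rev_seq)):
            if not 15 <= len(s) <= 35:
                raise ValidationError(f"{self.name} {label} primer length {len(s)} outside 15–35")
            if set(s.upper()) - set("ACGT"):
                raise ValidationError(f"{self.name} {label} primer has non-ACGT residues")
        object.__setattr__(self, "fwd_seq", self.fwd_seq.upper())
        object.__setattr__(self, "rev_seq", self.rev_seq.upper())


@dataclass(frozen=True)
class BindingSite:
    primer: str  # primer label
    strand: str  # "+": primes rightward; "-": primes leftward
    position: int  # leftmost template coordinate of the covered site
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    interval: Interval
    length_bp: int
    fwd_site: BindingSite
    rev_site: BindingSite


@dataclass(frozen=True)
class TargetReadout:
    ct_replicates: tuple
    efficiency: float

    def __post_init__(self):
        if not self.ct_replicates:
            raise ValidationError("at least one Ct replicate required")
        if not 0 < self.efficiency <= 1.1:
            raise ValidationError("efficiency must be in (0, 1.1]")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))


@dataclass(frozen=True)
class QpcrSample:
    name: str
    targets: dict


@dataclass(frozen=True)
class CopyRatioResult:
    ratio: float
    log10_ratio: float
    target_a: str
    target_b: str
    sample: str


@dataclass(frozen=True)
class EfficiencyFit:
    efficiency: float
    slope: float
    r_squared: float


# ---------------------------------------------------------------------------
# primer binding


def _site_positions(
    template_codes2: np.ndarray, L: int, primer: str, strand: str,
    seed_3prime: int, max_mismatch_5prime: int,
):
    """Start positions (leftmost template coordinate) where the primer binds.

    '+' sites: template[p : p+n] equals the primer (3' end at the right).
    '-' sites: template[p : p+n] equals revcomp(primer) (3' end at the left).
    """
    prim = encode(primer)
    n = len(prim)
    if strand == "-":
        prim = complement_codes(prim)[::-1]
    seed = min(seed_3prime, n)
    if strand == "+":
        seed_slice = slice(n - seed, n)
    else:
        seed_slice = slice(0, seed)
    pos = np.arange(L)
    mm = np.zeros(L, dtype=np.int32)
    seed_ok = np.ones(L, dtype=bool)
    for t in range(n):
        neq = template_codes2[pos + t] != prim[t]
        in_seed = seed_slice.start <= t < seed_slice.stop
        if in_seed:
            seed_ok &= ~neq
        else:
            mm += neq
    hits = np.flatnonzero(seed_ok & (mm <= max_mismatch_5prime))
    return [(int(p), int(mm[p])) for p in hits]


def _all_sites(template: CircularSequence, primers: dict, seed_3prime, max_mm):
    codes2 = np.tile(template.codes(), 2)
    L = template.length_bp
    sites = []
    for label, seq in primers.items():
        for strand in "+-":
            for p, m in _site_positions(codes2, L, seq, strand, seed_3prime, max_mm):
                sites.append(BindingSite(primer=label, strand=strand, position=p, mismatches=m))
    return sites


def _pair_sites(template, sites, primers, max_product):
    L = template.length_bp
    plus = [s for s in sites if s.strand == "+"]
    minus = [s for s in sites if s.strand == "-"]
    out = []
    for f in plus:
        lf = len(primers[f.primer])
        for r in minus:
            lr = len(primers[r.primer])
            length = (r.position + lr - f.position) % L
            if length == 0:
                length = L
            if length < lf + lr or length > max_product:
                continue
            iv = Interval(f.position, (f.position + length - 1) % L + 1)
            out.append(
                Amplicon(
                    template_id=template.id,
                    interval=iv,
                    length_bp=length,
                    fwd_site=f,
                    rev_site=r,
                )
            )
    out.sort(key=lambda a: (a.interval.start, a.length_bp))
    return out


def insilico_pcr(
    template: CircularSequence,
    pair: PrimerPair,
    max_product: int = 5000,
    max_mismatch_5prime: int = 2,
    seed_3prime: int = 10,
) -> list[Amplicon]:
    """Predicted amplicons for one primer pair on a (circular) template.

    Both primers are scanned on both strands, so products are found
    regardless of template orientation or rotation; an empty list means no
    product."""
    primers = {f"{pair.name}.fwd": pair.fwd_seq, f"{pair.name}.rev": pair.rev_seq}
    sites = _all_sites(template, primers, seed_3prime, max_mismatch_5prime)
    return _pair_sites(template, sites, primers, max_product)


def multiplex_pcr(
    template: CircularSequence,
    pairs: list[PrimerPair],
    max_product: int = 5000,
    max_mismatch_5prime: int = 2,
    seed_3prime: int = 10,
) -> list[Amplicon]:
    """Amplicons from pooling all primers of all pairs in one reaction.

    Every convergent combination of binding sites is reported, including
    cross-pair products, which is what makes a multiplex set able to emit
    one mitotype-diagnostic band per template."""
    if not pairs:
        raise ContractViolation("at least one primer pair required")
    primers = {}
    seen_seqs = {}
    for p in pairs:
        for role, seq in (("fwd", p.fwd_seq), ("rev", p.rev_seq)):
            if seq in seen_seqs:  # the same oligo pooled twice is one oligo
                continue
            label = f"{p.name}.{role}"
            seen_seqs[seq] = label
            primers[label] = seq
    sites = _all_sites(template, primers, seed_3prime, max_mismatch_5prime)
    return _pair_sites(template, sites, primers, max_product)


# ---------------------------------------------------------------------------
# quantification


def estimate_efficiency(dilution_series) -> EfficiencyFit:
    """Amplification efficiency from a dilution series.

    ``dilution_series`` is a sequence of (log10_input, mean_ct) points, at
    least three.  E = 10^(-1/slope) - 1; perfect doubling gives slope
    -3.3219 and E = 1.0."""
    pts = list(dilution_series)
    if len(pts) < 3:
        raise ContractViolation("need at least 3 dilution points")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise EstimationError(
            f"non-monotone dilution series (slope {fit.slope:.3f} >= 0)"
        )
    eff = 10 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyFit(
        efficiency=float(eff), slope=float(fit.slope), r_squared=float(fit.rvalue**2)
    )


def copy_ratio(sample: QpcrSample, target_a: str, target_b: str) -> CopyRatioResult:
    """Copy-number ratio (copies of a per copy of b) from Ct values and E.

    Ct per target is the arithmetic mean of replicates; the ratio is
    (1+E_b)^Ct_b / (1+E_a)^Ct_a.  Reciprocity holds exactly:
    ratio(a,b) * ratio(b,a) = 1."""
    for t in (target_a, target_b):
        if t not in sample.targets:
            raise ValidationError(f"target {t!r} missing from sample {sample.name!r}")
    ta, tb = sample.targets[target_a], sample.targets[target_b]
    log_ratio = tb.mean_ct * math.log(1 + tb.efficiency) - ta.mean_ct * math.log(
        1 + ta.efficiency
    )
    ratio = math.exp(log_ratio)
    return CopyRatioResult(
        ratio=ratio,
        log10_ratio=log_ratio / math.log(10),
        target_a=target_a,
        target_b=target_b,
        sample=sample.name,
    )


# ---------------------------------------------------------------------------
# tables


def read_primer_table(path) -> list[PrimerPair]:
    """TSV with columns name, fwd, rev[, expected_mitotype, expected_product_bp]."""
    df = pd.read_csv(path, sep="\t")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            PrimerPair(
                name=str(row["name"]),
                fwd_seq=str(row["fwd"]),
                rev_seq=str(row["rev"]),
                expected_mitotype=str(row.get("expected_mitotype", "both")),
                expected_product_bp=(
                    int(row["expected_product_bp"])
                    if "expected_product_bp" in df.columns and not pd.isna(row["expected_product_bp"])
                    else None
                ),
            )
        )
    return pairs


def read_ct_table(path) -> list[QpcrSample]:
    """CSV with columns sample, target, replicate, ct, efficiency."""
    df = pd.read_csv(path)
    samples = []
    for name, sub in df.groupby("sample", sort=True):
        targets = {}
        for tname, tsub in sub.groupby("target", sort=True):
            effs = tsub["efficiency"].unique()
            if len(effs) != 1:
                raise ValidationError(
                    f"inconsistent efficiency for {name}/{tname}"
                )
            targets[str(tname)] = TargetReadout(
                ct_replicates=tuple(float(c) for c in tsub["ct"]),
                efficiency=float(effs[0]),
            )
        samples.append(QpcrSample(name=str(name), targets=targets))
    return samples


def amplicons_table(amplicons: list[Amplicon]) -> pd.DataFrame:
    rows = []
    for a in amplicons:
        rows.append(
            {
                "template": a.template_id,
                "start": a.interval.start,
                "end": a.interval.end,
                "length": a.length_bp,
                "wraps_origin": a.interval.wraps_origin,
                "fwd_primer": a.fwd_site.primer,
                "rev_primer": a.rev_site.primer,
                "fwd_mismatches": a.fwd_site.mismatches,
                "rev_mismatches": a.rev_site.mismatches,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "template", "start", "end", "length", "wraps_origin",
            "fwd_primer", "rev_primer", "fwd_mismatches", "rev_mismatches",
        ],
    )
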