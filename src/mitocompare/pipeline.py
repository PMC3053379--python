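"""End-to-end two-genome comparison: one call, one structured report.

The stages mirror how a comparative mitogenome analysis is reported:
genome summaries, synteny decomposition, signed permutation and minimum
recombination-event count, repeat landscape and coverage, predicted
subgenomic circles from the largest direct repeat, the SNP census, the
mitotype-specific fractions and the junction table.  Every number in the
report is recomputable from the inputs plus the recorded parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import assay, rearrangement, repeats, synteny, variation
from .errors import MitocompareError
from .genome import (
    CircularSequence,
    canonical_rotation,
    gc_content,
    read_sequences,
    write_fasta,
)

log = logging.getLogger("mitocompare")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class CompareConfig:
    min_block_len: int = 2000
    min_block_identity: float = 0.99
    anchor_k: int = 15
    chain_gap: int = 100
    repeat_min_len: int = 30
    repeat_max_len: int = 500
    repeat_min_identity: float = 0.90
    repeat_seed_len: int = 20
    large_repeat_min: int = 1000
    large_repeat_identity: float = 0.99
    gap_exclusion_bp: int = 5
    breakpoint_window_bp: int = 500
    canonicalize: bool = True
    snp_denominator: str = "genome"  # "genome" | "aligned"


@dataclass
class ComparisonReport:
    schema_version: int
    parameters: dict
    genomes: list
    blocks: list
    permutation: list
    dcj: dict
    specific_fraction_ref: float
    specific_fraction_qry: float
    dispersed_repeats: list
    repeat_coverage: float
    large_repeats: list
    subcircles: list
    snp_summary: dict
    snp_records: list
    breakpoint_annotations: list
    junctions: list
    dotplot: list

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
        _write_tsv(out / "blocks.tsv", self.blocks)
        _write_tsv(out / "repeats.tsv", self.dispersed_repeats)
        _write_tsv(out / "snps.tsv", self.snp_records)
        _write_tsv(out / "dotplot.tsv", self.dotplot)


def _write_tsv(path, rows):
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _as_sequence(x, format="fasta") -> CircularSequence:
    if isinstance(x, CircularSequence):
        return x
    seqs = read_sequences(x, format=format)
    if not seqs:
        raise MitocompareError(f"no sequences in {x}")
    return seqs[0]


def run_compare(ref, qry, config: CompareConfig | None = None) -> ComparisonReport:
    """Full comparison of two circular genomes (paths or sequences)."""
    cfg = config or CompareConfig()
    ref = _as_sequence(ref)
    qry = _as_sequence(qry)
    if cfg.canonicalize:
        ref, _ = canonical_rotation(ref)
        qry, _ = canonical_rotation(qry)
    Lr, Lq = ref.length_bp, qry.length_bp

    log.info("synteny: detecting blocks (min_len=%d, min_identity=%.3f)",
             cfg.min_block_len, cfg.min_block_identity)
    blocks = synteny.detect_blocks(
        ref, qry,
        min_len=cfg.min_block_len,
        min_identity=cfg.min_block_identity,
        k=cfg.anchor_k,
        max_gap=cfg.chain_gap,
    )

    perm_list, dcj = [], {"distance": None, "cycles": None, "n": 0}
    if blocks:
        perm = rearrangement.blocks_to_permutation(blocks)
        res = rearrangement.dcj_distance(perm)
        perm_list = list(perm.signs_and_order)
        dcj = {"distance": res.distance, "cycles": res.cycles, "n": res.n, "model": res.model}
    log.info("rearrangement: %d blocks, distance %s", len(blocks), dcj["distance"])

    sf_ref = synteny.specific_fraction(ref, blocks, "ref") if blocks else 1.0
    sf_qry = synteny.specific_fraction(qry, blocks, "qry") if blocks else 1.0

    log.info("repeats: dispersed scan on reference")
    disp = repeats.find_dispersed_repeats(
        ref,
        min_len=cfg.repeat_min_len,
        max_len=cfg.repeat_max_len,
        min_identity=cfg.repeat_min_identity,
        seed_len=cfg.repeat_seed_len,
    )
    coverage = repeats.repeat_coverage(ref, disp)
    large = repeats.find_large_repeats(
        ref, large_min=cfg.large_repeat_min, min_identity=cfg.large_repeat_identity
    )
    anns = repeats.repeats_at_breakpoints(
        blocks, disp, Lr, window_bp=cfg.breakpoint_window_bp
    ) if blocks else []

    subcircles = []
    direct_large = [p for p in large if p.orientation == "direct"]
    if direct_large:
        biggest = max(direct_large, key=lambda p: p.length_bp)
        c1, c2 = rearrangement.enumerate_subcircles(Lr, biggest)
        subcircles = [
            {"length_bp": c.length_bp, "start": c.interval.start,
             "end": c.interval.end, "retains_repeat_copy": c.retains_repeat_copy}
            for c in (c1, c2)
        ]

    log.info("variation: SNP census inside %d blocks", len(blocks))
    snps = variation.call_snps(ref, qry, blocks, gap_exclusion_bp=cfg.gap_exclusion_bp)
    aligned_bp = sum(b.length_bp for b in blocks)
    denom = Lr if cfg.snp_denominator == "genome" else max(aligned_bp, 1)
    summary = variation.summarize_snps(snps, denom)

    junctions = []
    if len(blocks) > 1:
        for b in sorted(blocks, key=lambda x: x.qry_interval.start):
            try:
                j = rearrangement.characterize_junction(
                    ref, qry, blocks, (b.block_id, "end"), pairs=disp
                )
            except MitocompareError:
                continue
            junctions.append(
                {
                    "block_id": j.block_id,
                    "side": j.side,
                    "kind": j.kind,
                    "shared_prefix_bp": j.shared_prefix_bp,
                    "shared_suffix_bp": j.shared_suffix_bp,
                    "lost_bp": j.lost_bp,
                    "inserted_bp": j.inserted_bp,
                    "inserted_anonymous": j.inserted_anonymous,
                }
            )

    report = ComparisonReport(
        schema_version=SCHEMA_VERSION,
        parameters=dataclasses.asdict(cfg),
        genomes=[
            {"id": s.id, "length_bp": s.length_bp, "gc": round(gc_content(s), 6)}
            for s in (ref, qry)
        ],
        blocks=synteny.blocks_table(blocks, Lr, Lq).to_dict("records"),
        permutation=perm_list,
        dcj=dcj,
        specific_fraction_ref=round(sf_ref, 6),
        specific_fraction_qry=round(sf_qry, 6),
        dispersed_repeats=[_repeat_row(p) for p in disp],
        repeat_coverage=round(coverage, 6),
        large_repeats=[_repeat_row(p) for p in large],
        subcircles=subcircles,
        snp_summary={
            "n_total": summary.n_total,
            "n_transitions": summary.n_ts,
            "n_transversions": summary.n_tv,
            "denominator_bp": summary.denominator_bp,
            "rate_per_10kb": round(summary.rate_per_10kb, 1),
            "aligned_bp": aligned_bp,
        },
        snp_records=[dataclasses.asdict(r) for r in snps],
        breakpoint_annotations=[
            {
                "block_id": a.block_id,
                "side": a.side,
                "distance_bp": a.distance_bp,
                "orientation": a.repeat.orientation,
                "repeat_length": a.repeat.length_bp,
                "pattern": a.pattern,
            }
            for a in anns
        ],
        junctions=junctions,
        dotplot=synteny.dotplot_table(blocks, Lr, Lq).to_dict("records"),
    )
    return report


def run_simulate(config, out_dir) -> Path:
    """Generate a synthetic genome pair and write genomes plus truth."""
    from . import simulate as sim

    if not isinstance(config, sim.SimulationConfig):
        config = load_simulation_config(config)
    truth = sim.simulate_pair(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "ref.fasta", [truth.ref])
    write_fasta(out / "qry.fasta", [truth.derived])
    write_fasta(out / "ancestor.fasta", [truth.ancestor])
    truth_dict = {
        "event_log": truth.event_log,
        "ref_insert_log": truth.ref_insert_log,
        "block_map": [
            {
                "block_id": p.block_id,
                "sign": p.sign,
                "qry_start": p.qry_interval.start,
                "qry_end": p.qry_interval.end,
                "is_duplicate": p.is_duplicate,
            }
            for p in truth.block_map
        ],
        "ref_blocks": {
            str(bid): [iv.start, iv.end] for bid, iv in truth.ref_blocks.items()
        },
        "repeat_truth": [_repeat_row(p) for p in truth.repeat_truth],
        "ref_specific": [[iv.start, iv.end] for iv in truth.ref_specific],
        "qry_specific": [[iv.start, iv.end] for iv in truth.qry_specific],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_dict, fh, indent=1)
    with open(out / "snps.tsv", "w") as fh:
        fh.write("ref_pos\tqry_pos\tref_base\tqry_base\tclass\n")
        for s in truth.snp_truth:
            fh.write(f"{s.ref_pos}\t{s.qry_pos}\t{s.ref_base}\t{s.qry_base}\t{s.snp_class}\n")
    return out


def load_simulation_config(path):
    """Plain-text key/value (YAML) simulation config file."""
    import yaml

    from . import simulate as sim

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    planted = [
        sim.PlantedRepeat(**p) for p in raw.pop("planted_repeats", [])
    ]
    return sim.SimulationConfig(planted_repeats=planted, **raw)


def _repeat_row(p) -> dict:
    return {
        "start_a": p.interval_a.start,
        "end_a": p.interval_a.end,
        "start_b": p.interval_b.start,
        "end_b": p.interval_b.end,
        "length": p.length_bp,
        "orientation": p.orientation,
        "identity": p.identity,
        "family_id": p.family_id,
    }


def run_assay_pcr(genome_paths, primers_path, multiplex: bool = False):
    """In-silico PCR of a primer table against one or more genomes."""
    pairs = assay.read_primer_table(primers_path)
    rows = []
    for path in genome_paths:
        template = _as_sequence(path)
        if multiplex:
            amps = assay.multiplex_pcr(template, pairs)
        else:
            amps = []
            for p in pairs:
                amps.extend(assay.insilico_pcr(template, p))
        rows.append((template.id, assay.amplicons_table(amps)))
    return rows


def run_assay_ratio(ct_path, target_a: str, target_b: str):
    """Copy-number ratio table from a Ct CSV."""
    import pandas as pd

    samples = assay.read_ct_table(ct_path)
    rows = []
    for s in samples:
        r = assay.copy_ratio(s, target_a, target_b)
        rows.append(
            {"sample": s.name, "ratio": r.ratio, "log10_ratio": r.log10_ratio}
        )
    return pd.DataFrame(rows)
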