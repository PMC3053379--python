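"""Synthetic circular genome pairs with known structural ground truth.

The generator emulates how two plant mitochondrial mitotypes diverge from a
common ancestor: a set of conserved sequence blocks is rearranged by
repeat-mediated recombination (inversions, transpositions, duplications,
deletions), mitotype-specific segments are inserted at junctions, small
indels and point substitutions accumulate inside the conserved blocks, and
dispersed repeats (direct and inverted, 30–500 bp, plus the occasional
multi-kilobase pair) are planted at known loci.  Every derived feature is
recorded as machine-checkable truth so detectors can be scored without any
external data.

Determinism: the same config (including its seed) yields byte-identical
genomes.  The event log is replayable — applying it to the ancestor
regenerates the derived genome exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .genome import CircularSequence, Interval, reverse_complement
from .repeats import RepeatPair

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PlantedRepeat:
    """A repeat pair to engrave into the ancestor (both copies overwritten)."""

    length_bp: int
    orientation: str = "direct"  # direct | inverted
    identity: float = 1.0
    positions: tuple[int, int] | None = None  # ancestor start coordinates
    flank_block: int | None = None  # place copies just outside this block


@dataclass
class SimulationConfig:
    seed: int = 0
    ancestor_length_bp: int = 50_000
    n_blocks: int = 10
    block_lengths: list[int] | None = None  # equal split when omitted
    gc_content: float = 0.45
    events: list[dict] = field(default_factory=list)
    snp_rate: float = 0.0
    tstv_ratio: float = 2.0
    n_snps: int | None = None  # exact-count mode (overrides snp_rate)
    n_transitions: int | None = None  # exact transition count with n_snps
    planted_repeats: list[PlantedRepeat] = field(default_factory=list)
    ref_specific_lengths: list[int] = field(default_factory=list)
    qry_specific_lengths: list[int] = field(default_factory=list)
    qry_indels: list[dict] = field(default_factory=list)  # {"block": id, "delta": n}

    def resolved_block_lengths(self) -> list[int]:
        if self.block_lengths is not None:
            if sum(self.block_lengths) != self.ancestor_length_bp:
                raise ConfigurationError("block_lengths must sum to ancestor_length_bp")
            return list(self.block_lengths)
        base, extra = divmod(self.ancestor_length_bp, self.n_blocks)
        return [base + (1 if i < extra else 0) for i in range(self.n_blocks)]

    def validate(self):
        if not 0 <= self.snp_rate <= 0.1:
            raise ValidationError("snp_rate must be in [0, 0.1]")
        if self.tstv_ratio <= 0:
            raise ValidationError("tstv_ratio must be > 0")
        for pr in self.planted_repeats:
            if not 0 < pr.length_bp < self.ancestor_length_bp:
                raise ConfigurationError(
                    f"planted repeat length {pr.length_bp} impossible on "
                    f"{self.ancestor_length_bp} bp ancestor"
                )
        for ev in self.events:
            if "size_bp" in ev and not 0 < ev["size_bp"] < self.ancestor_length_bp:
                raise ConfigurationError("event size out of range")


# ---------------------------------------------------------------------------
# truth containers


@dataclass(frozen=True)
class SnpTruth:
    ref_pos: int
    qry_pos: int
    ref_base: str
    qry_base: str
    snp_class: str  # transition | transversion


@dataclass(frozen=True)
class BlockPlacement:
    block_id: int
    sign: int
    qry_interval: Interval
    is_duplicate: bool = False


@dataclass
class SimulationTruth:
    config: SimulationConfig
    ancestor: CircularSequence
    ref: CircularSequence
    derived: CircularSequence
    event_log: list[dict]
    ref_insert_log: list[dict]
    block_map: list[BlockPlacement]
    ref_blocks: dict[int, Interval]
    snp_truth: list[SnpTruth]
    repeat_truth: list[RepeatPair]  # reference-genome coordinates
    ref_specific: list[Interval]
    qry_specific: list[Interval]

    def replay(self) -> CircularSequence:
        """Re-derive the query genome from the ancestor and the event log."""
        blocks = _split_blocks(self.ancestor.residues, self.config.resolved_block_lengths())
        segs = _apply_log(blocks, self.event_log)
        residues = "".join(s["seq"] for s in segs)
        return CircularSequence(id=self.derived.id, residues=residues)

    def expected_permutation(self, chain_gap: int = 100) -> list[int]:
        """The signed block order a synteny detector should recover.

        Adjacent blocks that remain collinear in both genomes with no
        spacer longer than the chaining gap between them are merged into a
        single detected block, exactly as an anchor-chaining detector would
        merge them; merged units are renumbered along the reference.
        """
        n = self.config.n_blocks
        ref_break = set()  # block id i such that a ref insert separates i, i+1
        for ins in self.ref_insert_log:
            if len(ins["sequence"]) > chain_gap:
                ref_break.add(ins["after_block"])

        def succ(i):  # circular successor in reference order
            return i % n + 1

        def collinear(pid, psign, bid, sign):
            if sign != psign:
                return False
            if sign > 0:
                return bid == succ(pid) and pid not in ref_break
            return pid == succ(bid) and bid not in ref_break

        units = []  # list of list[(block_id, sign)]
        prev = None
        for entry in self._qry_walk(chain_gap):
            if entry == "break":
                prev = None
                continue
            bid, sign = entry
            if prev is not None and collinear(*prev, bid, sign):
                units[-1].append((bid, sign))
                prev = (bid, sign)
                continue
            units.append([(bid, sign)])
            prev = (bid, sign)
        # circular closure: first and last unit may merge across the seam
        if len(units) > 1:
            bid, sign = units[0][0]
            pid, psign = units[-1][-1]
            if collinear(pid, psign, bid, sign) and self._first_last_contiguous(chain_gap):
                units[-1].extend(units.pop(0))
        # renumber units the way a detector numbers blocks: by reference
        # start coordinate of each unit's first block in reference
        # orientation (the block whose ref predecessor is outside the unit)
        def ref_entry_start(u):
            ids = {b for b, _ in u}
            for b, _ in u:
                pred = n if b == 1 else b - 1
                if pred not in ids or len(ids) == n:
                    return self.ref_blocks[b].start if len(ids) < n else min(
                        self.ref_blocks[x].start for x in ids
                    )
            return min(self.ref_blocks[b].start for b, _ in u)

        keyed = sorted(units, key=ref_entry_start)
        number = {id(u): i + 1 for i, u in enumerate(keyed)}
        return [number[id(u)] * (1 if u[0][1] > 0 else -1) for u in units]

    def _qry_walk(self, chain_gap: int):
        out = []
        for seg, placement in zip(self._segments_cache, self._placements_cache):
            if placement is None:
                if len(seg["seq"]) > chain_gap:
                    out.append("break")
                continue
            if placement.is_duplicate:
                out.append("break")
                continue
            out.append((placement.block_id, placement.sign))
        return out

    def _first_last_contiguous(self, chain_gap: int) -> bool:
        # no long non-block segment between the end and the start of the circle
        segs = self._segments_cache
        i = len(segs) - 1
        while i >= 0 and self._placements_cache[i] is None:
            if len(segs[i]["seq"]) > chain_gap:
                return False
            i -= 1
        j = 0
        while j < len(segs) and self._placements_cache[j] is None:
            if len(segs[j]["seq"]) > chain_gap:
                return False
            j += 1
        return True


# ---------------------------------------------------------------------------
# ancestor construction


def _split_blocks(residues: str, lengths: list[int]) -> list[dict]:
    blocks, pos = [], 0
    for i, ell in enumerate(lengths, start=1):
        blocks.append({"id": i, "sign": 1, "seq": residues[pos : pos + ell]})
        pos += ell
    return blocks


def _degrade(unit: str, identity: float, rng: np.random.Generator) -> str:
    """Introduce evenly spaced substitutions so the copy's ungapped identity
    is at least the requested value.  The mismatch count is capped so every
    exact run between mismatches spans at least 1/(1-identity) - 1 bases;
    this guarantees a threshold-matched detector can absorb the whole copy
    run by run without its running identity ever dipping below threshold."""
    import math

    ell = len(unit)
    if identity >= 1.0:
        return unit
    n_mm = math.floor((1.0 - identity) * ell + 1e-9)
    while n_mm > 0 and ell / (n_mm + 1) < 1.0 / (1.0 - identity):
        n_mm -= 1
    if n_mm == 0:
        return unit
    pos = np.linspace(ell / (n_mm + 1), ell - ell / (n_mm + 1), n_mm)
    pos = np.unique(np.clip(np.round(pos).astype(int), 1, ell - 2))
    out = list(unit)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_ancestor(config: SimulationConfig) -> CircularSequence:
    """Uniform-random circular ancestor with planted repeats engraved.

    Deterministic in the config seed.  Overlapping planted loci raise
    :class:`ConfigurationError`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.ancestor_length_bp
    residues = list(_random_seq(rng, L, config.gc_content))
    lengths = config.resolved_block_lengths()
    starts = np.concatenate(([0], np.cumsum(lengths)))[:-1]

    taken: list[tuple[int, int]] = []

    def claim(s, ell):
        s %= L
        for t, te in taken:
            if s < te and t < s + ell:
                raise ConfigurationError(
                    f"planted repeats overlap near position {s}"
                )
        if s + ell > L:
            raise ConfigurationError("planted repeat runs past the origin")
        taken.append((s, s + ell))

    for pr in config.planted_repeats:
        unit = _random_seq(rng, pr.length_bp, config.gc_content)
        if pr.flank_block is not None:
            k = pr.flank_block - 1
            s1 = int(starts[k]) - pr.length_bp - 5
            s2 = int(starts[k]) + lengths[k] + 5
            if s1 < 0:
                s1 += L
        else:
            if pr.positions is None:
                raise ConfigurationError("planted repeat needs positions or flank_block")
            s1, s2 = pr.positions
        copy2 = unit
        if pr.orientation == "inverted":
            copy2 = unit.translate(_COMPLEMENT)[::-1]
        copy2 = _degrade(copy2, pr.identity, rng)
        for s, copy in ((s1, unit), (s2, copy2)):
            claim(s, pr.length_bp)
            residues[s : s + pr.length_bp] = copy
    return CircularSequence(id="ancestor", residues="".join(residues))


# ---------------------------------------------------------------------------
# event log application (pure; replayable)


def _apply_log(blocks: list[dict], log: list[dict]) -> list[dict]:
    segs = [dict(b, orig_indels=[]) for b in blocks]
    for ev in log:
        op = ev["op"]
        if op == "rearrange":
            s, e = ev["start"], ev["end"]
            if not (0 <= s <= e < len(segs)):
                raise ConfigurationError(f"event range {s}..{e} out of bounds")
            if ev["type"] == "inversion":
                piece = segs[s : e + 1][::-1]
                for seg in piece:
                    seg["sign"] = -seg["sign"]
                    seg["seq"] = seg["seq"].translate(_COMPLEMENT)[::-1]
                segs[s : e + 1] = piece
            elif ev["type"] == "transposition":
                piece = segs[s : e + 1]
                rest = segs[:s] + segs[e + 1 :]
                ia = ev["insert_after"]
                if ia >= s:
                    ia -= len(piece)
                segs = rest[: ia + 1] + piece + rest[ia + 1 :]
            elif ev["type"] == "deletion":
                del segs[s : e + 1]
            elif ev["type"] == "duplication":
                piece = [dict(x, is_duplicate=True) for x in segs[s : e + 1]]
                if ev.get("inverted"):
                    piece = piece[::-1]
                    for seg in piece:
                        seg["sign"] = -seg["sign"]
                        seg["seq"] = seg["seq"].translate(_COMPLEMENT)[::-1]
                ia = ev["insert_after"]
                segs = segs[: ia + 1] + piece + segs[ia + 1 :]
            else:
                raise ConfigurationError(f"unknown event type {ev['type']!r}")
        elif op == "insert_segment":
            seg = {"id": None, "sign": 1, "seq": ev["sequence"], "orig_indels": []}
            ia = ev["after"]
            segs = segs[: ia + 1] + [seg] + segs[ia + 1 :]
        elif op == "indel":
            seg = segs[ev["segment"]]
            p, d = ev["pos"], ev["delta"]
            if d > 0:
                seg["seq"] = seg["seq"][:p] + ev["sequence"] + seg["seq"][p:]
            else:
                seg["seq"] = seg["seq"][:p] + seg["seq"][p - d :]
            seg["orig_indels"].append((p, d))
        elif op == "snp":
            seg = segs[ev["segment"]]
            p = ev["pos"]
            if seg["seq"][p] == ev["to"]:
                raise ConfigurationError("snp event does not change the base")
            seg["seq"] = seg["seq"][:p] + ev["to"] + seg["seq"][p + 1 :]
        else:
            raise ConfigurationError(f"unknown op {op!r}")
    return segs


# ---------------------------------------------------------------------------
# full pair simulation


def apply_rearrangements(seq: CircularSequence, config: SimulationConfig) -> SimulationTruth:
    """Derive a rearranged, mutated query genome from ``seq`` and record truth.

    Rearrangement events are applied in order, then mitotype-specific
    segments are inserted, then block-internal indels, then SNPs.  The
    returned truth carries both genomes, coordinates of every feature, and a
    replayable event log.
    """
    config.validate()
    if seq.length_bp != config.ancestor_length_bp:
        raise ConfigurationError("sequence length does not match config")
    rng = np.random.default_rng(config.seed + 1)
    lengths = config.resolved_block_lengths()
    blocks = _split_blocks(seq.residues, lengths)

    log: list[dict] = []
    # 1. structural events
    for ev in config.events:
        log.append(dict(ev, op="rearrange"))
    segs = _apply_log(blocks, log)

    # 2. query-specific insertions at junctions, spread evenly
    n_ins = len(config.qry_specific_lengths)
    if n_ins:
        if n_ins > len(segs):
            raise ConfigurationError("more specific segments than junctions")
        slots = [int(round(i * len(segs) / n_ins)) for i in range(n_ins)]
        for slot, ell in sorted(zip(slots, config.qry_specific_lengths), reverse=True):
            log.append(
                {
                    "op": "insert_segment",
                    "after": min(slot, len(segs) - 1),
                    "sequence": _random_seq(rng, ell, config.gc_content),
                }
            )
    segs = _apply_log(blocks, log)

    def seg_index_of_block(bid):
        for i, s in enumerate(segs):
            if s["id"] == bid and not s.get("is_duplicate"):
                return i
        raise ConfigurationError(f"block {bid} absent from derived genome")

    # 3. block-internal indels
    for indel in config.qry_indels:
        si = seg_index_of_block(indel["block"])
        seg = segs[si]
        d = indel["delta"]
        room = len(seg["seq"]) - 200 - max(-d, 0)
        if room <= 0:
            raise ConfigurationError("block too small for requested indel")
        p = 100 + int(rng.integers(room))
        ins = _random_seq(rng, d, config.gc_content) if d > 0 else None
        log.append(
            {"op": "indel", "segment": si, "pos": p, "delta": d, "sequence": ins}
        )
        segs = _apply_log(blocks, log)

    # 4. SNPs inside block copies
    snp_events = _choose_snps(segs, config, rng)
    log.extend(snp_events)
    segs = _apply_log(blocks, log)

    # 5. assemble genomes and truth coordinates
    rng_ref = np.random.default_rng(config.seed + 2)
    ref_insert_log = []
    n_rins = len(config.ref_specific_lengths)
    if n_rins:
        n_junctions = len(blocks)
        if n_rins > n_junctions:
            raise ConfigurationError("more ref-specific segments than junctions")
        slots = [int(round(i * n_junctions / n_rins)) + 1 for i in range(n_rins)]
        for slot, ell in zip(slots, config.ref_specific_lengths):
            ref_insert_log.append(
                {
                    "after_block": min(slot, n_junctions),
                    "sequence": _random_seq(rng_ref, ell, config.gc_content),
                }
            )

    truth = _assemble_truth(seq, blocks, segs, log, ref_insert_log, config)
    return truth


def _choose_snps(segs, config: SimulationConfig, rng) -> list[dict]:
    # SNPs are kept 25 bp clear of block edges (an anchor length, so the
    # flanking exact seeds survive) and, in exact-count mode, at least 8 bp
    # apart (outside each other's gap-exclusion window and clear of
    # alignment-tie artifacts); closer pairs are not reliably attributable.
    eligible = []  # (segment index, current position)
    margin = 25
    min_spacing = 8
    for si, seg in enumerate(segs):
        if seg["id"] is None or seg.get("is_duplicate"):
            continue
        n = len(seg["seq"])
        bad = np.zeros(n, dtype=bool)
        bad[:margin] = True
        bad[n - margin :] = True
        # a random insertion can chance-match its context, letting the
        # aligner smear the gap tens of bases sideways and swallow nearby
        # mismatch columns, so the exclusion zone is generous
        indel_margin = 60
        for p, d in seg["orig_indels"]:
            if d > 0:
                lo, hi = max(p - indel_margin, 0), min(p + d + indel_margin, n)
            else:
                lo, hi = max(p - indel_margin, 0), min(p + indel_margin, n)
            bad[lo:hi] = True
        for pos in np.flatnonzero(~bad):
            eligible.append((si, int(pos)))
    if not eligible:
        return []
    events = []
    if config.n_snps is not None:
        if config.n_snps > len(eligible):
            raise ConfigurationError("not enough eligible sites for requested SNPs")
        order = rng.permutation(len(eligible))
        chosen: list[int] = []
        taken: dict[int, list[int]] = {}
        for idx in order.tolist():
            si, pos = eligible[idx]
            near = taken.setdefault(si, [])
            if any(abs(pos - p) < min_spacing for p in near):
                continue
            near.append(pos)
            chosen.append(idx)
            if len(chosen) == config.n_snps:
                break
        if len(chosen) < config.n_snps:
            raise ConfigurationError("not enough well-spaced sites for requested SNPs")
        pick = np.array(chosen)
        n_ts = (
            config.n_transitions
            if config.n_transitions is not None
            else int(round(config.n_snps * config.tstv_ratio / (1 + config.tstv_ratio)))
        )
        is_ts = np.zeros(config.n_snps, dtype=bool)
        is_ts[:n_ts] = True
        is_ts = is_ts[rng.permutation(config.n_snps)]
    elif config.snp_rate > 0:
        hit = rng.random(len(eligible)) < config.snp_rate
        pick = np.flatnonzero(hit)
        p_ts = config.tstv_ratio / (1 + config.tstv_ratio)
        is_ts = rng.random(len(pick)) < p_ts
    else:
        return []
    for j, idx in enumerate(np.asarray(pick).tolist()):
        si, pos = eligible[idx]
        base = segs[si]["seq"][pos]
        if bool(is_ts[j]):
            to = _TRANSITION[base]
        else:
            tv = _TRANSVERSIONS[base]
            to = tv[rng.integers(2)]
        events.append({"op": "snp", "segment": si, "pos": pos, "to": to})
    # one event per site (events carry current positions; SNPs never stack
    # because sites are drawn without replacement)
    return events


def _assemble_truth(ancestor, blocks, segs, log, ref_insert_log, config):
    # reference genome: blocks in identity order with ref-specific inserts
    ref_parts, ref_blocks, ref_specific = [], {}, []
    pos = 0
    inserts_after = {}
    for ins in ref_insert_log:
        inserts_after.setdefault(ins["after_block"], []).append(ins["sequence"])
    for b in blocks:
        ref_parts.append(b["seq"])
        ref_blocks[b["id"]] = Interval(pos, pos + len(b["seq"]))
        pos += len(b["seq"])
        for s in inserts_after.get(b["id"], []):
            ref_parts.append(s)
            ref_specific.append(Interval(pos, pos + len(s)))
            pos += len(s)
    ref = CircularSequence(id="ref", residues="".join(ref_parts))

    qry_parts, block_map, qry_specific = [], [], []
    pos = 0
    seg_starts = []
    for seg in segs:
        seg_starts.append(pos)
        qry_parts.append(seg["seq"])
        iv = Interval(pos, pos + len(seg["seq"]))
        if seg["id"] is None:
            qry_specific.append(iv)
        else:
            block_map.append(
                BlockPlacement(
                    block_id=seg["id"],
                    sign=seg["sign"],
                    qry_interval=iv,
                    is_duplicate=bool(seg.get("is_duplicate")),
                )
            )
        pos += len(seg["seq"])
    qry = CircularSequence(id="qry", residues="".join(qry_parts))

    # SNP truth with coordinates in both genomes
    snp_truth = []
    for ev in log:
        if ev["op"] != "snp":
            continue
        si, p = ev["segment"], ev["pos"]
        seg = segs[si]
        qry_pos = seg_starts[si] + p
        orig = _orig_of_current(seg["orig_indels"], p)
        bid, sign = seg["id"], seg["sign"]
        blk_len = len(blocks[bid - 1]["seq"])
        if sign > 0:
            ref_off = orig
            ref_base = blocks[bid - 1]["seq"][orig]
            qry_base = ev["to"]
        else:
            # indels were applied after the orientation flip, so orig refers
            # to an offset on the reverse-complemented copy
            ref_off = blk_len - 1 - orig
            ref_base = blocks[bid - 1]["seq"][ref_off]
            qry_base = ev["to"].translate(_COMPLEMENT)
        klass = (
            "transition" if _TRANSITION[ref_base] == qry_base else "transversion"
        )
        ref_pos = ref_blocks[bid].start + ref_off
        snp_truth.append(
            SnpTruth(
                ref_pos=ref_pos,
                qry_pos=qry_pos,
                ref_base=ref_base,
                qry_base=qry_base,
                snp_class=klass,
            )
        )

    # planted repeat truth mapped to reference coordinates
    repeat_truth = _repeat_truth_in_ref(ancestor, config, ref_blocks, blocks)

    truth = SimulationTruth(
        config=config,
        ancestor=ancestor,
        ref=ref,
        derived=qry,
        event_log=log,
        ref_insert_log=ref_insert_log,
        block_map=block_map,
        ref_blocks=ref_blocks,
        snp_truth=snp_truth,
        repeat_truth=repeat_truth,
        ref_specific=ref_specific,
        qry_specific=qry_specific,
    )
    truth._segments_cache = segs
    placements = []
    it = iter(block_map)
    for seg in segs:
        placements.append(None if seg["id"] is None else next(it))
    truth._placements_cache = placements
    return truth


def _orig_of_current(indels, c):
    """Map a current within-segment offset back through recorded indels."""
    for p, d in reversed(indels):
        if d > 0:
            if c >= p + d:
                c -= d
            elif c >= p:
                return None  # inside inserted material
        else:
            if c >= p:
                c -= d
    return c


def _repeat_truth_in_ref(ancestor, config, ref_blocks, blocks):
    # planted positions are a pure function of the config (the rng only
    # draws residue content), so truth coordinates need no replay
    lengths = config.resolved_block_lengths()
    starts = np.concatenate(([0], np.cumsum(lengths)))[:-1]
    L = config.ancestor_length_bp

    def anc_to_ref(p):
        # locate containing block, apply ref offset
        bi = int(np.searchsorted(starts, p, side="right")) - 1
        off = p - int(starts[bi])
        return ref_blocks[bi + 1].start + off

    out = []
    for pr in config.planted_repeats:
        unit_len = pr.length_bp
        if pr.flank_block is not None:
            k = pr.flank_block - 1
            s1 = int(starts[k]) - unit_len - 5
            s2 = int(starts[k]) + lengths[k] + 5
            if s1 < 0:
                s1 += L
        else:
            s1, s2 = pr.positions
        r1, r2 = anc_to_ref(s1), anc_to_ref(s2)
        a, b = sorted((r1, r2))
        out.append(
            RepeatPair(
                interval_a=Interval(a, a + unit_len),
                interval_b=Interval(b, b + unit_len),
                length_bp=unit_len,
                orientation=pr.orientation,
                identity=pr.identity,
            )
        )
    return out


def simulate_pair(config: SimulationConfig) -> SimulationTruth:
    """Convenience wrapper: ancestor construction plus full derivation."""
    return apply_rearrangements(simulate_ancestor(config), config)


# ---------------------------------------------------------------------------
# standalone SNP process


def apply_snps(
    seq: CircularSequence, snp_rate: float, tstv_ratio: float, seed: int
) -> tuple[CircularSequence, list[SnpTruth]]:
    """Mutate each site independently with probability ``snp_rate``.

    A mutated site becomes a transition with probability tstv/(1+tstv),
    otherwise one of its two transversions uniformly; the new base always
    differs from the old.  No site mutates twice (single pass).
    """
    if not 0 <= snp_rate <= 0.1:
        raise ValidationError("snp_rate must be in [0, 0.1]")
    if tstv_ratio <= 0:
        raise ValidationError("tstv_ratio must be > 0")
    rng = np.random.default_rng(seed)
    res = list(seq.residues)
    n = len(res)
    hits = np.flatnonzero(rng.random(n) < snp_rate)
    p_ts = tstv_ratio / (1 + tstv_ratio)
    truth = []
    for pos in hits.tolist():
        base = res[pos]
        if base == "N":
            continue
        if rng.random() < p_ts:
            to, klass = _TRANSITION[base], "transition"
        else:
            to, klass = _TRANSVERSIONS[base][rng.integers(2)], "transversion"
        res[pos] = to
        truth.append(
            SnpTruth(
                ref_pos=pos, qry_pos=pos, ref_base=base, qry_base=to, snp_class=klass
            )
        )
    return CircularSequence(id=seq.id + "_mut", residues="".join(res)), truth


# ---------------------------------------------------------------------------
# qPCR observation model


def simulate_qpcr(
    copies_a: float,
    copies_b: float,
    efficiency_a: float = 1.0,
    efficiency_b: float = 1.0,
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    c0: float = 40.0,
    target_a: str = "a",
    target_b: str = "b",
):
    """Simulated threshold cycles for two targets at given template amounts.

    Under exponential amplification, Ct = C0 - log(copies)/log(1+E) plus
    Gaussian cycle noise per replicate; C0 is the instrument constant (cycle
    at which a single starting copy crosses threshold, default 40).
    """
    from .assay import QpcrSample, TargetReadout  # local import avoids a cycle

    if copies_a <= 0 or copies_b <= 0:
        raise ValidationError("copy numbers must be positive")
    rng = np.random.default_rng(seed)
    targets = {}
    for name, copies, eff in (
        (target_a, copies_a, efficiency_a),
        (target_b, copies_b, efficiency_b),
    ):
        if not 0 < eff <= 1.1:
            raise ValidationError("efficiency must be in (0, 1.1]")
        ct = c0 - np.log(copies) / np.log(1 + eff)
        cts = ct + rng.normal(0.0, ct_noise_sd, size=n_replicates)
        targets[name] = TargetReadout(ct_replicates=tuple(cts.tolist()), efficiency=eff)
    return QpcrSample(name="simulated", targets=targets)


# ---------------------------------------------------------------------------
# helpers for experiment design


def random_nonoverlapping_inversions(
    n_blocks: int, k: int, seed: int
) -> list[dict]:
    """k single-block inversion events at pairwise non-adjacent blocks.

    Non-adjacency (circular) keeps the k inversions' breakpoints disjoint,
    so the minimum rearrangement distance of the derived genome is exactly k.
    """
    if 2 * k > n_blocks:
        raise ConfigurationError("too many inversions for the block count")
    rng = np.random.default_rng(seed)
    while True:
        picks = sorted(rng.choice(n_blocks, size=k, replace=False).tolist())
        ok = all(b - a >= 2 for a, b in zip(picks, picks[1:]))
        if ok and not (picks and (picks[0] + n_blocks) - picks[-1] < 2):
            break
    return [
        {"type": "inversion", "start": p, "end": p} for p in picks
    ]
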