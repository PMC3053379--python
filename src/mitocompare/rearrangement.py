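"""Rearrangement distance, subgenomic circles and junction anatomy.

The block order of the query genome relative to the reference defines a
signed circular permutation.  The minimum number of recombination events
separating the two arrangements is computed under the double-cut-and-join
(DCJ) model, which treats inversions, transpositions, fusions and fissions
uniformly: on a single circular chromosome the distance is ``n - c`` where
``c`` is the number of cycles in the breakpoint graph on block extremities.
A breadth-first search over genome space provides an exact (exponential)
oracle for small ``n``.

Homologous recombination between the two copies of a *direct* repeat splits
the master circle into two subgenomic circles whose lengths sum to the
master length — the classic multipartite structure of plant mitochondrial
genomes; an *inverted* pair instead yields an inversion isomer, not two
circles.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import edlib
import numpy as np

from .errors import ContractViolation, ValidationError
from .genome import CircularSequence, Interval, subsequence
from .repeats import RepeatPair
from .synteny import SyntenyBlock

# ---------------------------------------------------------------------------
# signed circular permutations


@dataclass(frozen=True)
class BlockPermutation:
    """Signed circular order of query blocks, reference order = +1..+n.

    The representation is normalized up to rotation and global reflection
    of the circle: rotated so block 1 comes first, reflected so it carries
    a plus sign.
    """

    signs_and_order: tuple

    def __post_init__(self):
        order = tuple(int(x) for x in self.signs_and_order)
        n = len(order)
        if sorted(abs(x) for x in order) != list(range(1, n + 1)) or n == 0:
            raise ValidationError("not a signed permutation of 1..n")
        object.__setattr__(self, "signs_and_order", _normalize(order))

    @property
    def n(self) -> int:
        return len(self.signs_and_order)

    @property
    def n_inverted(self) -> int:
        return sum(1 for x in self.signs_and_order if x < 0)


def _normalize(order: tuple) -> tuple:
    i = next(j for j, x in enumerate(order) if abs(x) == 1)
    rot = order[i:] + order[:i]
    if rot[0] < 0:
        rot = tuple(-x for x in reversed(rot))
        i = next(j for j, x in enumerate(rot) if abs(x) == 1)
        rot = rot[i:] + rot[:i]
    return tuple(rot)


@dataclass(frozen=True)
class RearrangementResult:
    distance: int
    model: str
    cycles: int
    n: int


def blocks_to_permutation(blocks: list[SyntenyBlock]) -> BlockPermutation:
    """Signed permutation of block ids in query order.

    Blocks are sorted by query start coordinate; the sign is the block's
    strand.  Blocks must be disjoint on both genomes (as produced by
    :func:`mitocompare.synteny.detect_blocks`).
    """
    if not blocks:
        raise ContractViolation("no blocks")
    order = sorted(blocks, key=lambda b: b.qry_interval.start)
    signed = tuple(
        b.block_id if b.strand == "+" else -b.block_id for b in order
    )
    return BlockPermutation(signed)


# ---------------------------------------------------------------------------
# DCJ distance (breakpoint graph)


def _adjacency_matching(order) -> frozenset:
    """Adjacency set of a circular signed block order.

    Extremities: tail(i) = 2(i-1), head(i) = 2(i-1)+1.  Each adjacency
    joins the right extremity of a block to the left extremity of its
    successor on the circle.
    """
    n = len(order)
    pairs = []
    for t in range(n):
        a, b = order[t], order[(t + 1) % n]
        right = 2 * (abs(a) - 1) + (1 if a > 0 else 0)
        left = 2 * (abs(b) - 1) + (0 if b > 0 else 1)
        pairs.append(frozenset((right, left)))
    return frozenset(pairs)


def dcj_distance(perm: BlockPermutation) -> RearrangementResult:
    """Minimum DCJ operation count between query and reference orders.

    Builds the breakpoint graph on block extremities and applies
    ``distance = n - cycles`` (single circular chromosome).
    """
    n = perm.n
    qry = _adjacency_matching(perm.signs_and_order)
    ref = _adjacency_matching(tuple(range(1, n + 1)))
    # count cycles in the union of the two perfect matchings
    neigh: dict[int, list[int]] = {}
    for match in (qry, ref):
        for pair in match:
            pair = tuple(pair)
            if len(pair) == 1:  # self-adjacency (n == 1): counts as a cycle
                a = b = pair[0]
            else:
                a, b = pair
            neigh.setdefault(a, []).append(b)
            neigh.setdefault(b, []).append(a)
    seen = set()
    cycles = 0
    for start in neigh:
        if start in seen:
            continue
        cycles += 1
        stack = [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(neigh[v])
    return RearrangementResult(distance=n - cycles, model="dcj", cycles=cycles, n=n)


def dcj_distance_between(a: BlockPermutation, b: BlockPermutation) -> int:
    """DCJ distance between two arrangements of the same blocks: n minus the
    cycle count of the union of their adjacency matchings."""
    if a.n != b.n:
        raise ContractViolation("permutations are over different block sets")
    n = a.n
    ma = _adjacency_matching(a.signs_and_order)
    mb = _adjacency_matching(b.signs_and_order)
    neigh: dict[int, list[int]] = {}
    for match in (ma, mb):
        for pair in match:
            x, y = tuple(pair) if len(pair) == 2 else (tuple(pair)[0],) * 2
            neigh.setdefault(x, []).append(y)
            neigh.setdefault(y, []).append(x)
    seen, cycles = set(), 0
    for start in neigh:
        if start in seen:
            continue
        cycles += 1
        stack = [start]
        while stack:
            v = stack.pop()
            if v not in seen:
                seen.add(v)
                stack.extend(neigh[v])
    return n - cycles


# ---------------------------------------------------------------------------
# exact BFS oracle

_DIST_MAPS: dict[int, dict] = {}


def _genome_neighbors(matching: frozenset) -> list[frozenset]:
    """All genomes one DCJ away (cut two adjacencies, rejoin both ways)."""
    adjs = list(matching)
    out = []
    for i in range(len(adjs)):
        for j in range(i + 1, len(adjs)):
            p, q = tuple(adjs[i]), tuple(adjs[j])
            rest = [a for t, a in enumerate(adjs) if t != i and t != j]
            a, b = p if len(p) == 2 else (p[0], p[0])
            c, d = q if len(q) == 2 else (q[0], q[0])
            for na, nb in ((frozenset((a, c)), frozenset((b, d))),
                           (frozenset((a, d)), frozenset((b, c)))):
                out.append(frozenset(rest + [na, nb]))
    return out


def _distance_map(n: int) -> dict:
    """BFS from the identity genome over all multichromosomal circular
    genomes on n blocks (perfect matchings of 2n extremities)."""
    if n in _DIST_MAPS:
        return _DIST_MAPS[n]
    identity = _adjacency_matching(tuple(range(1, n + 1)))
    dist = {identity: 0}
    queue = deque([identity])
    while queue:
        g = queue.popleft()
        d = dist[g]
        for nb in _genome_neighbors(g):
            if nb not in dist:
                dist[nb] = d + 1
                queue.append(nb)
    _DIST_MAPS[n] = dist
    return dist


def brute_force_distance(perm: BlockPermutation, max_n: int = 8) -> int:
    """Exact minimum DCJ count by exhaustive search; test oracle only.

    Explores genome space (all perfect matchings of block extremities,
    i.e. including multi-circle intermediates) breadth-first from the
    identity.  Refuses n > ``max_n``.
    """
    if perm.n > max_n:
        raise ContractViolation(f"brute force limited to n <= {max_n}")
    dmap = _distance_map(perm.n)
    return dmap[_adjacency_matching(perm.signs_and_order)]


def inversion_only_distance(perm: BlockPermutation, max_depth: int = 10) -> int:
    """Minimum number of arc inversions, by bidirectional BFS (small n only)."""

    def neighbors(order):
        n = len(order)
        res = []
        for i in range(n):
            for ln in range(1, n):
                piece = tuple(-x for x in reversed((order * 2)[i : i + ln]))
                new = list(order)
                for t in range(ln):
                    new[(i + t) % n] = piece[t]
                res.append(_normalize(tuple(new)))
        return res

    start = perm.signs_and_order
    goal = _normalize(tuple(range(1, perm.n + 1)))
    if start == goal:
        return 0
    fronts = ({start: 0}, {goal: 0})
    borders = ([start], [goal])
    for depth in range(1, max_depth + 1):
        side = depth % 2
        new_border = []
        for order in borders[side]:
            for nb in neighbors(order):
                if nb in fronts[1 - side]:
                    return fronts[side][order] + 1 + fronts[1 - side][nb]
                if nb not in fronts[side]:
                    fronts[side][nb] = fronts[side][order] + 1
                    new_border.append(nb)
        borders = (new_border, borders[1]) if side == 0 else (borders[0], new_border)
    raise ContractViolation(f"inversion distance exceeds search depth {max_depth}")


# ---------------------------------------------------------------------------
# subgenomic circles


@dataclass(frozen=True)
class SubgenomicCircle:
    length_bp: int
    interval: Interval  # master-circle arc contained in this circle
    retains_repeat_copy: str  # "a" | "b"


def enumerate_subcircles(L: int, repeat: RepeatPair) -> tuple[SubgenomicCircle, SubgenomicCircle]:
    """The two circles produced by recombination across a direct repeat.

    Their lengths are (start_b - start_a) mod L and the complement; each
    retains one full repeat copy, and the lengths sum to the master length.
    An inverted pair cannot produce two circles (it yields an inversion
    isomer) and is rejected.
    """
    if repeat.orientation != "direct":
        raise ContractViolation(
            "recombination across an inverted repeat yields an inversion "
            "isomer of the master circle, not two subgenomic circles"
        )
    sa, sb = repeat.interval_a.start, repeat.interval_b.start
    len1 = (sb - sa) % L
    len2 = L - len1
    c1 = SubgenomicCircle(
        length_bp=len1,
        interval=Interval(sa, (sb - 1) % L + 1),
        retains_repeat_copy="a",
    )
    c2 = SubgenomicCircle(
        length_bp=len2,
        interval=Interval(sb, (sa - 1) % L + 1),
        retains_repeat_copy="b",
    )
    return c1, c2


# ---------------------------------------------------------------------------
# junction anatomy


@dataclass(frozen=True)
class BreakpointJunction:
    block_id: int
    side: str
    kind: str  # "collinear" | "rearrangement" | "probe"
    shared_prefix_bp: int
    shared_suffix_bp: int
    lost_bp: int
    inserted_bp: int
    inserted_anonymous: bool
    flanking_repeats: tuple = ()


def _query_order(blocks):
    return sorted(blocks, key=lambda b: b.qry_interval.start)


def _ref_edge(block: SyntenyBlock, qry_side: str, Lr: int) -> int:
    """Reference coordinate facing the junction at the block's query edge."""
    if (qry_side == "end") == (block.strand == "+"):
        return block.ref_interval.end % Lr  # ref right edge (exclusive)
    return block.ref_interval.start


def characterize_junction(
    ref: CircularSequence,
    qry: CircularSequence,
    blocks: list[SyntenyBlock],
    boundary: tuple,
    probe: Interval | None = None,
    window_bp: int = 2000,
    min_anchor: int = 20,
    pairs: list[RepeatPair] | None = None,
) -> BreakpointJunction:
    """Anatomy of the junction at a block's query-side edge.

    ``boundary`` is ``(block_id, "end"|"start")`` on the query forward
    strand; the junction lies between this block and the next (resp.
    previous) block in query order.  For a collinear junction (the
    neighbouring block continues on the reference in the same orientation),
    the reference arc skipped between the two blocks is the *lost*
    sequence and the query gap is the *inserted* sequence; an insertion
    with no >= 90%-identity match elsewhere in either genome is labelled
    anonymous.  With ``probe`` (a query interval spanning the junction,
    e.g. a disrupted reading frame) the probe sequence is aligned to its
    best locus on the reference and the alignment is parsed into shared
    prefix/suffix and internal loss/insertion.
    """
    Lr, Lq = ref.length_bp, qry.length_bp
    by_id = {b.block_id: b for b in blocks}
    if boundary[0] not in by_id:
        raise ContractViolation(f"unknown block {boundary[0]}")
    block = by_id[boundary[0]]
    qside = boundary[1]
    if qside not in ("start", "end"):
        raise ContractViolation("boundary side must be 'start' or 'end'")
    order = _query_order(blocks)
    idx = next(i for i, b in enumerate(order) if b.block_id == block.block_id)
    if qside == "end":
        left, right = block, order[(idx + 1) % len(order)]
    else:
        left, right = order[(idx - 1) % len(order)], block

    j_left = left.qry_interval.end % Lq
    j_right = right.qry_interval.start
    gap_q = (j_right - j_left) % Lq
    if gap_q > Lq // 2:
        gap_q = 0  # defensive: adjacent blocks only

    if probe is not None:
        return _probe_junction(ref, qry, block, qside, probe, min_anchor)

    # are the two blocks collinear on the reference across this junction?
    rl = _ref_edge(left, "end", Lr)
    rr = _ref_edge(right, "start", Lr)
    collinear = left.strand == right.strand
    if collinear:
        if left.strand == "+":
            arc = (rr - rl) % Lr
        else:
            arc = (rl - rr) % Lr
        if arc > window_bp:
            collinear = False
    if collinear:
        lost = arc
        kind = "collinear"
    else:
        lost = 0
        kind = "rearrangement"

    inserted_seq = (
        subsequence(qry, Interval(j_left, (j_right - 1) % Lq + 1)) if gap_q else ""
    )
    anonymous = bool(inserted_seq) and not (
        _has_similar_hit(inserted_seq, ref) or _has_similar_hit(inserted_seq, qry, exclude=(j_left, gap_q))
    )
    prefix = min(window_bp, left.qry_span(Lq))
    suffix = min(window_bp, right.qry_span(Lq))
    flank = tuple(
        p
        for p in (pairs or [])
        if _near(p.interval_a, rl, window_bp, Lr) or _near(p.interval_b, rl, window_bp, Lr)
        or _near(p.interval_a, rr, window_bp, Lr) or _near(p.interval_b, rr, window_bp, Lr)
    )
    return BreakpointJunction(
        block_id=block.block_id,
        side=qside,
        kind=kind,
        shared_prefix_bp=prefix,
        shared_suffix_bp=suffix,
        lost_bp=lost,
        inserted_bp=gap_q,
        inserted_anonymous=anonymous,
        flanking_repeats=flank,
    )


def _near(iv: Interval, pos: int, window: int, L: int) -> bool:
    rel = (pos - iv.start) % L
    span = (iv.end - iv.start) % L or L
    if rel < span:
        return True
    return min((pos - (iv.start + span - 1)) % L, (iv.start - pos) % L) <= window


def _has_similar_hit(seq: str, genome: CircularSequence, exclude=None) -> bool:
    """True if ``seq`` matches somewhere in the (doubled) genome at >= 90%
    identity, excluding its own locus."""
    target = genome.residues * 2
    max_ed = int(0.10 * len(seq))
    res = edlib.align(seq, target, mode="HW", task="locations", k=max_ed)
    locs = res.get("locations") or []
    if exclude is None:
        return bool(locs)
    ex_start, ex_len = exclude
    L = genome.length_bp
    for s, e in locs:
        if s is None:
            continue
        if not _overlaps_mod(s, e + 1 - s, ex_start, ex_len, L):
            return True
    return False


def _overlaps_mod(s1, l1, s2, l2, L):
    for d in (-L, 0, L):
        if s1 < s2 + d + l2 and s2 + d < s1 + l1:
            return True
    return False


def _extend_match(a: str, b: str) -> int:
    """Length of the matching prefix of two strings, absorbing a mismatch
    run g only when followed by a match run of at least 3g (the same
    local-support rule used by the repeat finder)."""
    i = 0
    n = min(len(a), len(b))
    while i < n:
        if a[i] == b[i]:
            i += 1
            continue
        g = 0
        while i + g < n and a[i + g] != b[i + g]:
            g += 1
            if g > 10:
                return i
        r = 0
        while i + g + r < n and a[i + g + r] == b[i + g + r]:
            r += 1
        if r >= 3 * g:
            i += g + r
        else:
            return i
    return i


def _probe_junction(ref, qry, block, qside, probe: Interval, min_anchor: int):
    """Anchor both probe ends on the reference and extend inwards.

    The lost segment is the reference arc between the two anchored
    extensions; the inserted bases are the probe middle covered by neither.
    Both strands of the (doubled, circular) reference are tried.
    """
    from .genome import reverse_complement as _rc

    probe_seq = subsequence(qry, probe)
    m = len(probe_seq)
    k0 = min(max(min_anchor, 20), m)
    Lr = ref.length_bp
    best = None
    for strand, target in (("+", ref.residues * 2), ("-", _rc(ref).residues * 2)):
        head = edlib.align(probe_seq[:k0], target, mode="HW", task="locations", k=2)
        tail = edlib.align(probe_seq[-k0:], target, mode="HW", task="locations", k=2)
        hl = head.get("locations") or []
        tl = tail.get("locations") or []
        if not hl or not tl:
            continue
        h0 = hl[0][0]
        prefix = _extend_match(probe_seq, target[h0 : h0 + m + 64])
        t_end = tl[0][1] + 1
        suffix = _extend_match(probe_seq[::-1], target[max(t_end - m - 64, 0) : t_end][::-1])
        if prefix + suffix > m:  # anchors overlap: nothing lost in between
            suffix = m - prefix
        ref_prefix_end = h0 + prefix
        ref_suffix_start = t_end - suffix
        lost = max(ref_suffix_start - ref_prefix_end, 0) % Lr
        inserted = max(m - prefix - suffix, 0)
        score = prefix + suffix
        if best is None or score > best[0]:
            best = (score, prefix, suffix, lost, inserted)
    if best is None:
        prefix = suffix = lost = inserted = 0
    else:
        _, prefix, suffix, lost, inserted = best
    return BreakpointJunction(
        block_id=block.block_id,
        side=qside,
        kind="probe",
        shared_prefix_bp=prefix,
        shared_suffix_bp=suffix,
        lost_bp=lost,
        inserted_bp=inserted,
        inserted_anonymous=False,
        flanking_repeats=(),
    )


def _parse(cigar: str):
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out
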