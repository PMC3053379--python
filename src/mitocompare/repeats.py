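"""Dispersed and large repeat detection on circular genomes.

The repeat model follows the classic plant-mitochondrial definitions: a
*dispersed repeat* is a pair of equal-length loci, 30–500 bp, at least 90%
identical under an ungapped (Hamming) comparison, in either direct or
inverted orientation; a *large repeat* is the same object at >= 1 kb and
>= 99% identity.  Equal-length ungapped copies lie on one (anti-)diagonal of
the self-comparison matrix, so detection reduces to scanning diagonals of
the circular Hamming self-match.

A reported pair is a *maximal diagonal window*: both ends are matching
positions, Hamming identity >= the threshold, and the window cannot be
extended by absorbing the adjacent mismatch gap ``g`` plus the next exact
run ``r`` while (a) keeping identity >= the threshold and (b) satisfying
``r >= 3 g`` — a local-support rule that stops windows from creeping into
random flanking sequence.  Windows are grown from seeds (maximal exact runs
of at least ``min_run`` positions), where ``min_run`` is provably small
enough that every window meeting the thresholds contains such a run
(pigeonhole on the mismatch count), so the seeded scan is complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ContractViolation
from .genome import CircularSequence, Interval, complement_codes

# ---------------------------------------------------------------------------
# data types


@dataclass(frozen=True)
class RepeatPair:
    """Two equal-length genome intervals that are near-identical copies."""

    interval_a: Interval
    interval_b: Interval
    length_bp: int
    orientation: str  # "direct" | "inverted"
    identity: float
    family_id: int | None = None

    def key(self) -> tuple:
        return (
            self.orientation,
            self.interval_a.start,
            self.interval_b.start,
            self.length_bp,
        )


@dataclass(frozen=True)
class BreakpointRepeatAnnotation:
    block_id: int
    side: str  # "left" | "right" (reference interval edge)
    repeat: RepeatPair
    copy: str  # "a" | "b" — which copy is near the boundary
    distance_bp: int
    pattern: str | None = None  # "inversion-candidate" | "junction-candidate"


# ---------------------------------------------------------------------------
# seed-length guarantee

def guaranteed_seed(min_len: int, max_len: int | None, min_identity: float) -> int:
    """Longest exact run guaranteed inside any window meeting the thresholds.

    A window of length ``l`` with identity >= ``t`` has at most
    ``floor((1-t) l)`` mismatches, hence contains an exact run of at least
    ``ceil((l - m)/(m + 1))`` positions.  The minimum over admissible window
    lengths is a seed length below which the seeded scan cannot miss any
    qualifying window.
    """
    hi = max_len if max_len is not None else min_len * 4 + 400
    best = None
    for ell in range(min_len, hi + 1):
        m = math.floor((1.0 - min_identity) * ell + 1e-9)
        run = math.ceil((ell - m) / (m + 1))
        if best is None or run < best:
            best = run
    return max(best, 1)


def min_matches(length: int, min_identity: float) -> int:
    """Smallest match count for which matches/length >= min_identity."""
    return math.ceil(min_identity * length - 1e-9)


# ---------------------------------------------------------------------------
# window extension along a (anti-)diagonal

def extend_window(mget, pos: int, run_len: int, theta: float, cap: int):
    """Greedy maximal extension of an exact run on a diagonal.

    ``mget(x)`` is the match indicator at diagonal offset ``x``.  Returns
    ``(start, length, matches)`` of the maximal window under the absorb rule
    (identity >= theta and run >= 3*gap), never exceeding ``cap`` columns.
    Absorbing prefers the side with the larger ``r - g``; ties go right.
    """
    a, b = pos, pos + run_len  # current window [a, b)
    matches = run_len
    g_limit = int((1.0 - theta) * cap) + 2

    def probe(direction: int):
        g = 0
        while g <= g_limit and (b - a) + g < cap:
            x = (b + g) if direction > 0 else (a - 1 - g)
            if mget(x):
                break
            g += 1
        else:
            return None
        if g == 0 or g > g_limit:
            return None  # a maximal run never abuts a match
        r = 0
        while (b - a) + g + r < cap:
            x = (b + g + r) if direction > 0 else (a - 1 - g - r)
            if not mget(x):
                break
            r += 1
        if r == 0:
            return None
        return g, r

    while True:
        best = None  # (r - g, direction, g, r); tuple order prefers right on tie
        for direction in (+1, -1):
            pr = probe(direction)
            if pr is None:
                continue
            g, r = pr
            new_len = (b - a) + g + r
            if r >= 3 * g and matches + r >= min_matches(new_len, theta):
                cand = (r - g, direction, g, r)
                if best is None or cand > best:
                    best = cand
        if best is None:
            break
        _, direction, g, r = best
        if direction > 0:
            b += g + r
        else:
            a -= g + r
        matches += r
    return a, b - a, matches


# ---------------------------------------------------------------------------
# seeding helpers

def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of all circular k-mers of a circular code array."""
    n = len(codes)
    ext = np.concatenate((codes, codes[: k - 1]))
    out = np.zeros(n, dtype=np.int64)
    for t in range(k):
        out = out * 4 + ext[t : t + n].astype(np.int64)
    return out


def _seed_pairs_within(keys: np.ndarray):
    """All unordered index pairs (i < j) sharing a k-mer code."""
    order = np.argsort(keys, kind="stable")
    sk = keys[order]
    bounds = np.flatnonzero(np.diff(sk) != 0) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [len(sk)]))
    ii, jj = [], []
    for s, e in zip(starts.tolist(), ends.tolist()):
        if e - s < 2:
            continue
        idx = np.sort(order[s:e])
        a, b = np.meshgrid(idx, idx, indexing="ij")
        m = a < b
        ii.append(a[m])
        jj.append(b[m])
    if not ii:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(ii), np.concatenate(jj)


def _seed_pairs_cross(keys_a: np.ndarray, keys_b: np.ndarray):
    """All index pairs (i, j) with keys_a[i] == keys_b[j]."""
    order_a = np.argsort(keys_a, kind="stable")
    order_b = np.argsort(keys_b, kind="stable")
    sa, sb = keys_a[order_a], keys_b[order_b]
    ii, jj = [], []
    ia = ib = 0
    na, nb = len(sa), len(sb)
    while ia < na and ib < nb:
        if sa[ia] < sb[ib]:
            ia += 1
        elif sa[ia] > sb[ib]:
            ib += 1
        else:
            v = sa[ia]
            ea = ia
            while ea < na and sa[ea] == v:
                ea += 1
            eb = ib
            while eb < nb and sb[eb] == v:
                eb += 1
            a, b = np.meshgrid(order_a[ia:ea], order_b[ib:eb], indexing="ij")
            ii.append(a.ravel())
            jj.append(b.ravel())
            ia, ib = ea, eb
    if not ii:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(ii), np.concatenate(jj)


def _collapse_runs(I: np.ndarray, G: np.ndarray):
    """Keep one seed per exact run: drop seeds whose predecessor on the same
    (anti-)diagonal ``G`` sits at the adjacent position."""
    if len(I) == 0:
        return I, G
    order = np.lexsort((I, G))
    I, G = I[order], G[order]
    keep = np.ones(len(I), dtype=bool)
    keep[1:] = (np.diff(G) != 0) | (np.diff(I) != 1)
    return I[keep], G[keep]


def _density_filter(match_at, n: int, w: int, need: int, chunk: int = 400_000):
    """Keep seeds having some w-window (containing the seed start) with at
    least ``need`` matches; complete for any window meeting the thresholds."""
    keep = np.zeros(n, dtype=bool)
    for s in range(0, n, chunk):
        idx = np.arange(s, min(s + chunk, n))
        m = np.empty((len(idx), 2 * w - 1), dtype=np.uint8)
        for col, t in enumerate(range(-(w - 1), w)):
            m[:, col] = match_at(idx, t)
        cs = np.cumsum(m, axis=1, dtype=np.int32)
        wsum = cs[:, w - 1 :].copy()
        wsum[:, 1:] -= cs[:, : w - 1]
        keep[idx] = wsum.max(axis=1) >= need
    return keep


def _intervals_overlap(s1: int, l1: int, s2: int, l2: int, L: int) -> bool:
    for d in (-L, 0, L):
        if s1 < s2 + d + l2 and s2 + d < s1 + l1:
            return True
    return False


def _overlap_len(s1: int, l1: int, s2: int, l2: int, L: int) -> int:
    best = 0
    for d in (-L, 0, L):
        best = max(best, min(s1 + l1, s2 + d + l2) - max(s1, s2 + d))
    return max(best, 0)


# ---------------------------------------------------------------------------
# core scan

def _find_repeats(
    seq: CircularSequence,
    min_len: int,
    max_len: int | None,
    min_identity: float,
    seed_len: int | None,
    filter_threshold: int = 20_000,
) -> list[RepeatPair]:
    L = seq.length_bp
    codes = seq.codes()
    S4 = np.tile(codes, 4)
    C4 = complement_codes(S4)
    cap_hard = max(L // 2, 1)
    g_seed = guaranteed_seed(min_len, max_len, min_identity)
    k = min(seed_len, g_seed) if seed_len is not None else g_seed
    k = max(4, min(k, min_len))
    if L <= 2 * k:
        return []
    reach = (max_len if max_len is not None else cap_hard)
    reach = min(reach + int((1.0 - min_identity) * cap_hard) + 16, L)

    keys_f = _kmer_codes(codes, k)
    # key of revcomp(seq[j : j + k]) indexed by forward start j
    rc = complement_codes(codes)[::-1].copy()
    keys_r_raw = _kmer_codes(rc, k)
    keys_rc = keys_r_raw[(L - np.arange(L) - k) % L]

    w = min_len
    need = min_matches(w, min_identity)
    results: dict[tuple, tuple] = {}

    # ---- direct orientation ----
    I, J = _seed_pairs_within(keys_f)
    if len(I):
        D = (J - I) % L
        I, D = _collapse_runs(I, D)
        if len(I) > filter_threshold:
            def match_at(idx, t):
                return (S4[I[idx] + L + t] == S4[I[idx] + D[idx] + L + t]).astype(np.uint8)

            keep = _density_filter(match_at, len(I), w, need)
            I, D = I[keep], D[keep]
        for i, d in zip(I.tolist(), D.tolist()):
            cap = min(cap_hard, d, L - d)
            if cap < min_len:
                continue
            base = i + L

            def mget(x, base=base, d=d):
                return bool(S4[base + x] == S4[base + d + x])

            lo = 0
            while lo > -reach and mget(lo - 1):
                lo -= 1
            hi = 0
            while hi < reach and mget(hi):
                hi += 1
            run_len = hi - lo
            if run_len < k:
                continue
            run_len = min(run_len, cap)
            a, ell, matches = extend_window(mget, lo, run_len, min_identity, cap)
            if ell < min_len or (max_len is not None and ell > max_len):
                continue
            sa, sb = (i + a) % L, (i + a + d) % L
            if _intervals_overlap(sa, ell, sb, ell, L):
                continue
            p, q = sorted((sa, sb))
            results.setdefault(("direct", p, q, ell), (p, q, ell, matches / ell, "direct"))

    # ---- inverted orientation ----
    I, J = _seed_pairs_cross(keys_f, keys_rc)
    if len(I):
        # seq[i:i+k] == revcomp(seq[j:j+k]); anti-diagonal c = i + j + k - 1
        Cc = (I + J + k - 1) % L
        I, Cc = _collapse_runs(I, Cc)
        if len(I) > filter_threshold:
            def match_at_inv(idx, t):
                return (S4[I[idx] + L + t] == C4[(Cc[idx] - I[idx] - t) + 2 * L]).astype(np.uint8)

            keep = _density_filter(match_at_inv, len(I), w, need)
            I, Cc = I[keep], Cc[keep]
        for i, c in zip(I.tolist(), Cc.tolist()):
            cap = min(cap_hard, reach)
            base = i + L

            def mgeti(x, i=i, c=c):
                return bool(S4[i + L + x] == C4[(c - i - x) + 2 * L])

            lo = 0
            while lo > -reach and mgeti(lo - 1):
                lo -= 1
            hi = 0
            while hi < reach and mgeti(hi):
                hi += 1
            run_len = hi - lo
            if run_len < k:
                continue
            run_len = min(run_len, cap)
            a, ell, matches = extend_window(mgeti, lo, run_len, min_identity, cap)
            if ell < min_len or (max_len is not None and ell > max_len):
                continue
            sa = (i + a) % L
            sb = (c - (i + a) - ell + 1) % L
            if _intervals_overlap(sa, ell, sb, ell, L):
                continue
            p, q = sorted((sa, sb))
            results.setdefault(("inverted", p, q, ell), (p, q, ell, matches / ell, "inverted"))

    pairs = []
    for p, q, ell, ident, orient in results.values():
        pairs.append(
            RepeatPair(
                interval_a=Interval(p, (p + ell - 1) % L + 1),
                interval_b=Interval(q, (q + ell - 1) % L + 1),
                length_bp=ell,
                orientation=orient,
                identity=round(ident, 6),
            )
        )
    pairs.sort(key=lambda r: r.key())
    return _assign_families(pairs, L)


def _assign_families(pairs: list[RepeatPair], L: int) -> list[RepeatPair]:
    """Single-linkage grouping: pairs sharing a copy locus (reciprocal
    overlap of at least half the shorter copy) belong to one family."""
    parent = list(range(len(pairs)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    loci = []
    for idx, p in enumerate(pairs):
        loci.append((p.interval_a.start, p.length_bp, idx))
        loci.append((p.interval_b.start, p.length_bp, idx))
    for i in range(len(loci)):
        s1, l1, p1 = loci[i]
        for j in range(i + 1, len(loci)):
            s2, l2, p2 = loci[j]
            if find(p1) == find(p2):
                continue
            if _overlap_len(s1, l1, s2, l2, L) * 2 >= min(l1, l2):
                parent[find(p2)] = find(p1)
    roots: dict[int, int] = {}
    out = []
    for idx, p in enumerate(pairs):
        fam = roots.setdefault(find(idx), len(roots) + 1)
        out.append(replace(p, family_id=fam))
    return out


# ---------------------------------------------------------------------------
# public operations

def find_dispersed_repeats(
    seq: CircularSequence,
    min_len: int = 30,
    max_len: int = 500,
    min_identity: float = 0.90,
    seed_len: int = 20,
) -> list[RepeatPair]:
    """All maximal equal-length repeat pairs with 30–500 bp copies at >= 90%
    ungapped identity, both orientations, origin wrap included.

    The effective seed is shortened to the guaranteed-complete run length
    whenever ``seed_len`` exceeds it, so the seeded scan misses nothing the
    thresholds admit.  Copies overlapping each other (tandem-like) are not
    reported; windows whose maximal extension exceeds ``max_len`` belong to
    :func:`find_large_repeats` and are suppressed here.
    """
    if max_len < min_len:
        raise ContractViolation("max_len < min_len")
    return _find_repeats(seq, min_len, max_len, min_identity, seed_len)


def find_large_repeats(
    seq: CircularSequence,
    large_min: int = 1000,
    min_identity: float = 0.99,
) -> list[RepeatPair]:
    """Maximal near-identical repeat pairs with copies >= ``large_min`` bp.

    These are the recombination substrates behind the multipartite plant
    mitochondrial genome; the classic *Brassica* example is a ~2.4 kb
    direct pair.
    """
    seed = min(31, guaranteed_seed(large_min, None, min_identity))
    return _find_repeats(seq, large_min, None, min_identity, seed)


def repeat_coverage(seq: CircularSequence, pairs: list[RepeatPair]) -> float:
    """Fraction of the genome covered by the union of all repeat copies."""
    L = seq.length_bp
    mask = np.zeros(L, dtype=bool)
    for p in pairs:
        mask[p.interval_a.positions(L)] = True
        mask[p.interval_b.positions(L)] = True
    return float(mask.sum()) / L


def repeats_at_breakpoints(
    blocks,
    pairs: list[RepeatPair],
    L: int,
    window_bp: int = 500,
) -> list[BreakpointRepeatAnnotation]:
    """Annotate repeat copies lying near synteny-block boundaries.

    An inverted pair with one copy near each end of the *same* block is an
    inversion candidate (the repeat could have mediated re-orientation of
    that block); an inverted pair with copies near ends of two *different*
    blocks is a junction candidate.
    """

    def circ_dist(pos, iv: Interval):
        s = iv.start
        ell = (iv.end - iv.start) % L or L
        rel = (pos - s) % L
        if rel < ell:
            return 0
        return min((pos - ((s + ell - 1) % L)) % L, (s - pos) % L)

    anns = []
    hits: dict[tuple, set] = {}
    for blk in blocks:
        iv = blk.ref_interval
        boundaries = {"left": iv.start, "right": (iv.end - 1) % L}
        for side, pos in boundaries.items():
            for pi, p in enumerate(pairs):
                for copy_name, civ in (("a", p.interval_a), ("b", p.interval_b)):
                    dist = circ_dist(pos, civ)
                    if dist <= window_bp:
                        anns.append(
                            BreakpointRepeatAnnotation(
                                block_id=blk.block_id,
                                side=side,
                                repeat=p,
                                copy=copy_name,
                                distance_bp=dist,
                            )
                        )
                        hits.setdefault((pi, blk.block_id), set()).add(side)
    flagged = []
    for ann in anns:
        pat = None
        pi = next(i for i, p in enumerate(pairs) if p is ann.repeat)
        if ann.repeat.orientation == "inverted":
            sides = hits.get((pi, ann.block_id), set())
            if {"left", "right"} <= sides:
                pat = "inversion-candidate"
            elif any(b != ann.block_id for (qpi, b) in hits if qpi == pi):
                pat = "junction-candidate"
        flagged.append(replace(ann, pattern=pat))
    return flagged
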