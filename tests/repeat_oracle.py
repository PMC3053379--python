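"""Brute-force repeat-finder oracle: exhaustive scan of every diagonal.

Independent of the seeded detector: no k-mer indexing, no density filter —
every (anti-)diagonal of the circular self-comparison is materialized as a
match vector, every maximal exact run long enough to support a qualifying
window is extended with a straightforward re-implementation of the stated
maximal-window rule, and the resulting pair set is canonicalized.
Quadratic; suitable for genomes up to ~10 kb.
"""

from __future__ import annotations

import numpy as np

from mitocompare.genome import CircularSequence, complement_codes
from mitocompare.repeats import guaranteed_seed, min_matches


def _runs_of_true(m: np.ndarray, min_run: int = 1):
    """Maximal circular runs of True of length >= min_run, as (start, length)
    with start in [0, L)."""
    L = len(m)
    if m.all():
        return [(0, L)]
    if not m.any():
        return []
    m2 = np.concatenate((m, m)).astype(np.int8)
    d = np.diff(m2)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m2[0]:
        starts = np.concatenate(([0], starts))
    # pair each start with the first end after it (both sorted)
    pos = np.searchsorted(ends, starts, side="right")
    ok = pos < len(ends)
    starts, pos = starts[ok], pos[ok]
    lens = ends[pos] - starts
    keep = (starts < L) & (lens >= min_run)
    seen = set()
    out = []
    for s, ln in zip(starts[keep].tolist(), lens[keep].tolist()):
        key = (s % L, min(int(ln), L))
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def _extend_simple(mvec: np.ndarray, start: int, run_len: int, theta: float, cap: int):
    """Plain re-implementation of the maximal-window rule on a circular
    match vector: absorb adjacent (gap g, run r) while r >= 3g and global
    identity stays >= theta; prefer larger r - g, ties to the right."""
    L = len(mvec)

    def m(x):
        return bool(mvec[x % L])

    a, b = start, start + run_len
    matches = run_len

    def look(direction):
        g = 0
        while (b - a) + g < cap:
            x = (b + g) if direction > 0 else (a - 1 - g)
            if m(x):
                break
            g += 1
        else:
            return None
        if g == 0:
            return None
        r = 0
        while (b - a) + g + r < cap:
            x = (b + g + r) if direction > 0 else (a - 1 - g - r)
            if not m(x):
                break
            r += 1
        return (g, r) if r else None

    while True:
        options = []
        for direction in (1, -1):
            got = look(direction)
            if got is None:
                continue
            g, r = got
            if r >= 3 * g and matches + r >= min_matches((b - a) + g + r, theta):
                options.append(((r - g, direction), direction, g, r))
        if not options:
            break
        options.sort(reverse=True)
        _, direction, g, r = options[0]
        if direction > 0:
            b += g + r
        else:
            a -= g + r
        matches += r
    return a, b - a, matches


def _overlap(s1, l1, s2, l2, L):
    for d in (-L, 0, L):
        if s1 < s2 + d + l2 and s2 + d < s1 + l1:
            return True
    return False


def brute_force_repeats(
    seq: CircularSequence,
    min_len: int = 30,
    max_len: int | None = 500,
    min_identity: float = 0.90,
    seed_len: int = 20,
) -> set[tuple]:
    """Canonical keys {(orientation, start_a, start_b, length)} of every
    maximal repeat window, by exhaustive diagonal scan."""
    L = seq.length_bp
    codes = seq.codes()
    comp = complement_codes(codes)
    cap_hard = max(L // 2, 1)
    min_run = max(4, min(seed_len, guaranteed_seed(min_len, max_len, min_identity)))
    found = set()

    # direct diagonals
    for d in range(1, L):
        m = codes == np.roll(codes, -d)
        cap = min(cap_hard, d, L - d)
        if cap < min_len:
            continue
        for s, ln in _runs_of_true(m, min_run):
            ln = min(ln, cap)
            a, ell, _ = _extend_simple(m, s, ln, min_identity, cap)
            if ell < min_len or (max_len is not None and ell > max_len):
                continue
            sa, sb = a % L, (a + d) % L
            if _overlap(sa, ell, sb, ell, L):
                continue
            p, q = sorted((sa, sb))
            found.add(("direct", p, q, ell))

    # inverted anti-diagonals
    for c in range(L):
        idx = (c - np.arange(L)) % L
        m = codes == comp[idx]
        cap = min(cap_hard, L)
        for s, ln in _runs_of_true(m, min_run):
            ln = min(ln, cap)
            a, ell, _ = _extend_simple(m, s, ln, min_identity, cap)
            if ell < min_len or (max_len is not None and ell > max_len):
                continue
            sa = a % L
            sb = (c - a - ell + 1) % L
            if _overlap(sa, ell, sb, ell, L):
                continue
            p, q = sorted((sa, sb))
            found.add(("inverted", p, q, ell))
    return found
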