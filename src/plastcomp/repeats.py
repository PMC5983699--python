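"""Dispersed repeat pairs (forward and palindromic) and tandem repeats.

Dispersed repeats follow the REPuter-style definition: two copies of length
>= 30 with Hamming distance <= 3 (mismatches only, no indels) and identity
>= 90%.  A copy pair lives on one alignment diagonal (forward: the genome
against itself at a positive offset; palindromic: the genome against its
reverse complement).  Reported pairs are *maximal*: extending the window in
either direction would exceed the mismatch budget or run off the sequence;
terminal mismatches are trimmed so every pair starts and ends on a match.
Nested pairs (both copies contained in another pair's copies) are removed.

Tandem repeats use a deterministic offset-scoring scan: for each candidate
period p the sequence is compared against itself shifted by p; maximal
scoring segments under +match/-mismatch scoring (Ruzzo-Tompa decomposition)
with score >= min_score become tandem tracts.  Overlapping calls across
periods resolve to the highest-scoring period.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .model import Interval, revcomp


@dataclass(frozen=True)
class RepeatPair:
    kind: str  # forward | palindromic
    length: int
    pos1: Interval
    pos2: Interval
    mismatches: int

    @property
    def identity(self) -> float:
        return 100.0 * (self.length - self.mismatches) / self.length


@dataclass
class TandemRepeat:
    period: int
    copies: float
    consensus: str
    score: int
    interval: Interval


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------


def _maximal_windows(mismatch_flags, max_mismatch: int):
    """Maximal windows with <= max_mismatch mismatches over one diagonal.

    ``mismatch_flags`` is a boolean sequence (True = mismatch).  Windows are
    bounded by the (max_mismatch+1)-th mismatch on each side (sequence ends
    act as sentinels), then trimmed so they start and end on a match.
    Yields (start, end, n_mismatches) with end exclusive.
    """
    L = len(mismatch_flags)
    xs = [-1] + [i for i, f in enumerate(mismatch_flags) if f] + [L]
    m = max_mismatch
    seen = set()
    # window j runs from just after mismatch xs[j] to just before xs[j+m+1];
    # when the whole diagonal holds fewer than m mismatches the only maximal
    # window is the full diagonal
    for j in range(max(1, len(xs) - m - 1)):
        lo = xs[j] + 1
        hi = xs[min(j + m + 1, len(xs) - 1)]
        if hi <= lo:
            continue
        # trim terminal mismatches (possible when interior mismatches abut
        # the window edge after clipping at sequence ends -- cannot happen
        # here since lo/hi are bounded by mismatches, but guard anyway)
        while lo < hi and mismatch_flags[lo]:
            lo += 1
        while hi > lo and mismatch_flags[hi - 1]:
            hi -= 1
        if hi <= lo:
            continue
        inner = sum(1 for i in range(lo, hi) if mismatch_flags[i])
        key = (lo, hi)
        if key not in seen:
            seen.add(key)
            yield lo, hi, inner


def _window_qualifies(length: int, mismatches: int, min_len: int, min_identity: float) -> bool:
    return length >= min_len and 100.0 * (length - mismatches) / length >= min_identity


def _enumerate_around_seed(s: str, t: str, i: int, j: int, k: int, max_mm: int):
    """Maximal mismatch-bounded windows on diagonal (j - i) containing the
    exact k-mer seed s[i:i+k] == t[j:j+k].

    Returns windows as (a, b, mm) in s-coordinates; the aligned t-window is
    (a + d, b + d) with d = j - i.
    """
    d = j - i
    n = min(len(s), len(t) - d)
    lo0 = max(0, -d)

    def _is_mm(p: int) -> bool:
        return s[p] != t[p + d] or s[p] == "N"

    # nearest-first mismatch positions flanking the seed (at most max_mm+1
    # each side; beyond that a window containing the seed cannot reach them)
    left: list[int] = []
    p = i - 1
    while p >= lo0 and len(left) <= max_mm:
        if _is_mm(p):
            left.append(p)
        p -= 1
    right: list[int] = []
    p = i + k
    while p < n and len(right) <= max_mm:
        if _is_mm(p):
            right.append(p)
        p += 1

    def _bounds(u: int, v: int) -> tuple[int, int] | None:
        a = left[u] + 1 if u < len(left) else lo0
        b = right[v] if v < len(right) else n
        return (a, b) if a < b else None

    windows: list[tuple[int, int]] = []
    if len(left) + len(right) <= max_mm:
        # whole diagonal fits the budget: single maximal window
        windows.append((lo0, n))
    else:
        # maximal windows contain exactly max_mm interior mismatches, split
        # u left / v right of the seed (clipped at sequence ends)
        for u in range(0, max_mm + 1):
            v = max_mm - u
            if u > len(left) or v > len(right):
                continue
            w = _bounds(u, v)
            if w:
                windows.append(w)
    seen = set()
    for a, b in windows:
        # trim terminal mismatches (adjacent interior mismatches can sit on
        # the window edge)
        while a < b and _is_mm(a):
            a += 1
        while b > a and _is_mm(b - 1):
            b -= 1
        if b <= a or (a, b) in seen:
            continue
        seen.add((a, b))
        mm = sum(1 for q in range(a, b) if _is_mm(q))
        yield a, b, mm


def _pairs_on_diagonal(s: str, t: str, d: int, kind: str, n_orig: int,
                       min_len: int, max_mm: int, min_identity: float):
    """Exhaustively enumerate qualifying maximal windows on one s-vs-t
    diagonal; used by the brute-force path (`exhaustive=True`)."""
    lo = max(0, -d)
    hi = min(len(s), len(t) - d)
    if hi - lo < min_len:
        return
    flags = [s[p] != t[p + d] or s[p] == "N" for p in range(lo, hi)]
    for a, b, mm in _maximal_windows(flags, max_mm):
        a, b = a + lo, b + lo
        if _window_qualifies(b - a, mm, min_len, min_identity):
            yield _make_pair(kind, a, b, d, mm, n_orig)


def _make_pair(kind: str, a: int, b: int, d: int, mm: int, n: int) -> RepeatPair | None:
    """Map an s-coordinate window (a, b) on diagonal d to a canonical
    RepeatPair in genome coordinates."""
    length = b - a
    if kind == "forward":
        p1 = (a, b)
        p2 = (a + d, b + d)
    else:
        # t is the reverse complement; t-window (a+d, b+d) maps back to
        # genome window (n - (b + d), n - (a + d))
        p1 = (a, b)
        p2 = (n - (b + d), n - (a + d))
    if p1 == p2:
        return None  # self-match
    if p1 > p2:
        p1, p2 = p2, p1
    return RepeatPair(kind, length, Interval(*p1), Interval(*p2), mm)


def _seed_scan(s: str, t: str, kind: str, n_orig: int, min_len: int,
               max_mm: int, min_identity: float, self_compare: bool) -> set[RepeatPair]:
    """Seed-and-extend scan of s against t (t = s for forward repeats,
    t = revcomp(s) for palindromic)."""
    k = max(2, (min_len - max_mm) // (max_mm + 1))
    buckets: dict[str, list[int]] = defaultdict(list)
    for j in range(len(t) - k + 1):
        word = t[j : j + k]
        if "N" not in word:
            buckets[word].append(j)
    found: set[RepeatPair] = set()
    for i in range(len(s) - k + 1):
        word = s[i : i + k]
        hits = buckets.get(word)
        if not hits:
            continue
        for j in hits:
            d = j - i
            if self_compare and d <= 0:
                continue  # forward diagonals are symmetric; keep d > 0
            # only the leftmost seed of each exact run on a diagonal needs
            # processing: every maximal window containing a later seed of
            # the run also contains the earlier one
            if i > 0 and j > 0 and s[i - 1] == t[j - 1] and s[i - 1] != "N":
                continue
            for a, b, mm in _enumerate_around_seed(s, t, i, j, k, max_mm):
                if _window_qualifies(b - a, mm, min_len, min_identity):
                    pair = _make_pair(kind, a, b, d, mm, n_orig)
                    if pair is not None:
                        found.add(pair)
    return found


def find_dispersed_repeats(
    sequence: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    min_identity: float = 90.0,
    exhaustive: bool = False,
) -> list[RepeatPair]:
    """All maximal forward and palindromic repeat pairs.

    ``exhaustive=True`` scans every diagonal directly instead of seeding on
    shared k-mers; both paths implement the same definition.
    """
    s = sequence.upper()
    n = len(s)
    if n < min_len:
        return []
    t = revcomp(s)
    pairs: set[RepeatPair] = set()
    if exhaustive:
        for d in range(1, n):
            for p in _pairs_on_diagonal(s, s, d, "forward", n, min_len, max_mismatch, min_identity):
                if p is not None:
                    pairs.add(p)
        for d in range(-(n - 1), n):
            for p in _pairs_on_diagonal(s, t, d, "palindromic", n, min_len, max_mismatch, min_identity):
                if p is not None:
                    pairs.add(p)
    else:
        pairs |= _seed_scan(s, s, "forward", n, min_len, max_mismatch, min_identity, True)
        pairs |= _seed_scan(s, t, "palindromic", n, min_len, max_mismatch, min_identity, False)
    return dedupe_repeats(pairs)


def dedupe_repeats(pairs) -> list[RepeatPair]:
    """Containment filter: drop any pair whose both copies lie within the
    corresponding copies of another (longer) pair of the same kind.
    Deterministic order: by pos1 start, then length descending."""
    pairs = list(set(pairs))
    pairs.sort(key=lambda p: (-p.length, p.pos1.start, p.pos2.start, p.mismatches))
    kept: list[RepeatPair] = []

    def _contains(big: Interval, small: Interval) -> bool:
        return big.start <= small.start and small.end <= big.end

    for p in pairs:
        nested = any(
            q.kind == p.kind and _contains(q.pos1, p.pos1) and _contains(q.pos2, p.pos2)
            for q in kept
        )
        if not nested:
            kept.append(p)
    kept.sort(key=lambda p: (p.pos1.start, -p.length, p.pos2.start))
    return kept


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------


def _ruzzo_tompa(scores: list[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """All maximal scoring subsequences (Ruzzo & Tompa 1999).

    ``scores`` is a run-length-compressed list of (score, length) blocks;
    returns (start_index, end_index, score) over the *expanded* positions.
    """
    # expand block boundaries into cumulative coordinates
    starts = []
    pos = 0
    for _, ln in scores:
        starts.append(pos)
        pos += ln
    total_len = pos
    I: list[list[int]] = []  # [Lpos, Rpos, Lcum, Rcum]
    cum = 0
    for (sc, ln), bstart in zip(scores, starts):
        left_cum = cum
        cum += sc
        if sc <= 0:
            continue
        seg = [bstart, bstart + ln, left_cum, cum]
        while True:
            j = None
            for idx in range(len(I) - 1, -1, -1):
                if I[idx][2] < seg[2]:
                    j = idx
                    break
            if j is None:
                I.append(seg)
                break
            if I[j][3] >= seg[3]:
                I.append(seg)
                break
            merged = [I[j][0], seg[1], I[j][2], seg[3]]
            del I[j:]
            seg = merged
    out = [(l, r, rc - lc) for l, r, lc, rc in I]
    return out


def find_tandem_repeats(
    sequence: str,
    match: int = 2,
    mismatch: int = 7,
    min_score: int = 50,
    max_period: int = 500,
) -> list[TandemRepeat]:
    """Deterministic tandem-repeat scan by offset scoring.

    For each period p, position i >= p scores +match when the base equals
    the one a period earlier and -mismatch otherwise; maximal scoring
    segments with score >= min_score become tracts spanning one leading
    period plus the scored segment.  Overlapping tracts across periods keep
    the highest score (ties: smaller period, then leftmost).
    """
    s = sequence.upper()
    n = len(s)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_n = arr == ord("N")
    candidates: list[TandemRepeat] = []
    for p in range(1, min(max_period, n - 1) + 1):
        good = (arr[p:] == arr[:-p]) & ~is_n[p:]
        if not good.any():
            continue
        # run-length compress the +match/-mismatch profile
        change = np.flatnonzero(np.diff(good)) + 1
        bounds = np.concatenate(([0], change, [len(good)]))
        lens = np.diff(bounds)
        vals = np.where(good[bounds[:-1]], match * lens, -mismatch * lens)
        # cheap vectorized Kadane bound: skip the period when no segment can
        # reach the score threshold
        c = np.cumsum(vals)
        best = float(np.max(c - np.minimum.accumulate(np.concatenate(([0], c[:-1])))))
        if best < min_score:
            continue
        blocks = list(zip((int(v) for v in vals), (int(l) for l in lens)))
        for seg_start, seg_end, score in _ruzzo_tompa(blocks):
            if score < min_score:
                continue
            # segment indices are offsets into [p, n); the tract spans one
            # leading period plus the scored segment
            tract_start = seg_start
            tract_end = seg_end + p
            interval = Interval(tract_start, tract_end)
            period_seq = _consensus(s, tract_start, tract_end, p)
            candidates.append(
                TandemRepeat(p, round((tract_end - tract_start) / p, 1), period_seq, score, interval)
            )
    # resolve overlaps: highest score wins
    candidates.sort(key=lambda t: (-t.score, t.period, t.interval.start))
    kept: list[TandemRepeat] = []
    for c in candidates:
        if all(c.interval.end <= k.interval.start or k.interval.end <= c.interval.start for k in kept):
            kept.append(c)
    kept.sort(key=lambda t: t.interval.start)
    return kept


def _consensus(s: str, start: int, end: int, period: int) -> str:
    cols = [{} for _ in range(period)]
    for i in range(start, end):
        col = (i - start) % period
        b = s[i]
        cols[col][b] = cols[col].get(b, 0) + 1
    return "".join(max(sorted(c), key=lambda b: c[b]) if c else "N" for c in cols)
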