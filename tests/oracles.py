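"""Independent brute-force oracles used to validate the detectors.

These deliberately use naive strategies (per-start enumeration, exhaustive
diagonal scans, exhaustive alignment enumeration, library translation)
rather than the implementation's own search paths.
"""

from itertools import product

from Bio.Seq import Seq

DEFAULT_SSR_THRESHOLDS = {1: 8, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}


def _primitive(motif: str) -> bool:
    n = len(motif)
    return not any(n % p == 0 and motif == motif[:p] * (n // p) for p in range(1, n))


def ssr_oracle(seq: str, thresholds=None) -> set[tuple]:
    """All maximal perfect SSR tracts by checking every (start, period)."""
    thresholds = thresholds or DEFAULT_SSR_THRESHOLDS
    n = len(seq)
    out = set()
    for p, min_units in thresholds.items():
        for start in range(n - p):
            motif = seq[start : start + p]
            if "N" in motif or not _primitive(motif):
                continue
            if start - 1 >= 0 and seq[start - 1] == seq[start - 1 + p] and seq[start - 1] != "N":
                continue  # not left-maximal
            end = start + p
            while end < n and seq[end] == seq[end - p] and seq[end] != "N":
                end += 1
            units, rem = divmod(end - start, p)
            if units >= min_units:
                out.add((motif, p, units, rem, start, end))
    return out


def ssr_set(loci) -> set[tuple]:
    return {(l.motif, l.unit_len, l.n_units, l.remainder, l.interval.start, l.interval.end) for l in loci}


def alignment_score_oracle(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-10.0, gap_extend=-2.0) -> float:
    """Optimal global affine-gap score by exhaustive enumeration of all
    alignments (feasible for sequences up to ~8 nt)."""

    best = [float("-inf")]

    def gap_cost(length: int) -> float:
        return gap_open + gap_extend * length if length else 0.0

    def rec(i, j, score, gap_state):
        # gap_state: 0 none, 1 gap in b (consumed a), 2 gap in a
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, 0)
        if i < len(a):
            extra = gap_extend if gap_state == 1 else gap_open + gap_extend
            rec(i + 1, j, score + extra, 1)
        if j < len(b):
            extra = gap_extend if gap_state == 2 else gap_open + gap_extend
            rec(i, j + 1, score + extra, 2)

    rec(0, 0, 0.0, 0)
    return best[0]


def translate11(codon: str) -> str:
    """Library route (Biopython, table 11) for translation, independent of
    the package's codon table wiring."""
    return str(Seq(codon).translate(table=11))


def ng86_site_counts_oracle(codon: str) -> tuple[float, float]:
    aa = translate11(codon)
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            nb = codon[:pos] + alt + codon[pos + 1 :]
            if translate11(nb) != "*" and translate11(nb) == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def ng86_pathway_oracle(c1: str, c2: str) -> tuple[float, float]:
    """Average (Sd, Nd) over minimal stop-free pathways, via exhaustive
    ordering enumeration with library translation."""
    from itertools import permutations

    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    all_paths = []
    for order in permutations(diffs):
        cur, steps, through_stop = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if translate11(nxt) == "*":
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        all_paths.append((through_stop, steps))
    usable = [s for stop, s in all_paths if not stop] or [s for _, s in all_paths]
    sd = nd = 0.0
    for steps in usable:
        for x, y in steps:
            if translate11(y) != "*" and translate11(x) == translate11(y):
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def all_codons():
    return ["".join(c) for c in product("ACGT", repeat=3)]


def random_additive_tree(rng, n_leaves: int):
    """A random binary tree topology (sequential attachment) with positive
    branch lengths; returns (newick, labels, additive distance matrix)."""
    import numpy as np

    labels = [f"x{i}" for i in range(n_leaves)]
    # adjacency with branch lengths; start from a 3-star
    edges: dict[tuple[int, int], float] = {}
    next_node = n_leaves  # internal ids
    center = next_node
    next_node += 1

    def bl():
        return float(rng.uniform(0.5, 3.0))

    for i in range(3):
        edges[(i, center)] = bl()
    attachable = [(0, center), (1, center), (2, center)]
    for leaf in range(3, n_leaves):
        eidx = int(rng.integers(len(attachable)))
        u, v = attachable.pop(eidx)
        w = edges.pop((u, v) if (u, v) in edges else (v, u))
        mid = next_node
        next_node += 1
        split = float(rng.uniform(0.25, 0.75))
        edges[(u, mid)] = w * split
        edges[(mid, v)] = w * (1 - split)
        edges[(leaf, mid)] = bl()
        attachable += [(u, mid), (mid, v), (leaf, mid)]
    # all-pairs path lengths
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def dist_from(src):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        return seen

    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        di = dist_from(i)
        for j in range(n_leaves):
            d[i, j] = di[j]
    # true bipartitions: leaf sets separated by internal edges
    bips = set()
    for (u, v), _ in edges.items():
        # side of u without crossing (u,v)
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y, _w in adj[x]:
                if (x, y) in ((u, v), (v, u)):
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(labels[i] for i in seen if i < n_leaves)
        if 1 < len(side) < n_leaves - 1:
            other = frozenset(labels[i] for i in range(n_leaves)) - side
            bips.add(frozenset({side, other}))
    return labels, d, bips
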