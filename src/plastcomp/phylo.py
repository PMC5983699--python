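"""Distance-based phylogenetics: p-distances on concatenated alignments,
neighbor-joining with deterministic tie-breaking, column-resampling
bootstrap, and clade-monophyly checks.

This is a deliberate desk-scale stand-in for likelihood tree inference: the
quantity of interest downstream is clade recovery (is a taxon set one side
of one edge?), not branch-length or likelihood estimates.
"""

from __future__ import annotations

import logging
from io import StringIO

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_GOOD = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(alignments_by_locus: dict[str, dict[str, str]]) -> tuple[list[str], np.ndarray]:
    """Concatenate loci into one (taxa x columns) uint8 matrix."""
    if not alignments_by_locus:
        raise ValueError("no loci given")
    taxa: list[str] | None = None
    rows: dict[str, list[bytes]] = {}
    for locus, aln in alignments_by_locus.items():
        if taxa is None:
            taxa = sorted(aln)
            rows = {t: [] for t in taxa}
        missing = set(taxa) ^ set(aln)
        if missing:
            raise ValueError(f"locus {locus}: taxon set mismatch {sorted(missing)}")
        lens = {len(s) for s in aln.values()}
        if len(lens) != 1:
            raise ValueError(f"locus {locus}: unequal aligned lengths")
        for t in taxa:
            rows[t].append(aln[t].upper().encode("ascii"))
    assert taxa is not None
    mat = np.vstack([np.frombuffer(b"".join(rows[t]), dtype=np.uint8) for t in taxa])
    return taxa, mat


def _p_distance_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise proportion of differing columns where both symbols are
    unambiguous bases (pairwise deletion)."""
    n = mat.shape[0]
    ok = np.isin(mat, _GOOD)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError("taxon pair with no comparable columns")
            diff = int((mat[i][both] != mat[j][both]).sum())
            d[i, j] = d[j, i] = diff / m
    return d


def concat_distance_matrix(alignments_by_locus: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Symmetric p-distance matrix over the concatenation of all loci."""
    taxa, mat = _encode(alignments_by_locus)
    return pd.DataFrame(_p_distance_matrix(mat), index=taxa, columns=taxa)


def nj(matrix: pd.DataFrame | np.ndarray, labels: list[str] | None = None) -> dendropy.Tree:
    """Neighbor joining with lowest-index tie-breaking.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling edge.  Returns an unrooted tree (basal trifurcation in the
    Newick serialization).
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(c) for c in matrix.columns]
        d = matrix.to_numpy(dtype=float).copy()
    else:
        d = np.asarray(matrix, dtype=float).copy()
        if labels is None:
            labels = [f"t{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix not symmetric")
    nodes = [f"{_quote(l)}" for l in labels]
    active = list(range(n))

    def _join_lengths(va: float, vb: float) -> tuple[float, float]:
        # clamp negatives, transferring the deficit to the sibling edge
        if va < 0:
            vb += va
            va = 0.0
        if vb < 0:
            va += vb
            vb = 0.0
        return max(va, 0.0), max(vb, 0.0)

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima
        fi, fj = np.unravel_index(int(np.argmin(q)), q.shape)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = d[i, j]
        vi = 0.5 * dij + (R[fi] - R[fj]) / (2.0 * (r - 2))
        vj = dij - vi
        vi, vj = _join_lengths(vi, vj)
        new = d.shape[0]
        # distances from the new node to every other active node
        row = np.zeros(new + 1)
        grown = np.zeros((new + 1, new + 1))
        grown[:new, :new] = d
        for k in active:
            if k in (i, j):
                continue
            grown[new, k] = grown[k, new] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = grown
        nodes.append(f"({nodes[i]}:{vi:.10g},{nodes[j]}:{vj:.10g})")
        active = [k for k in active if k not in (i, j)] + [new]
    a, b, c = active
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    va, vb, vc = (max(v, 0.0) for v in (va, vb, vc))
    newick = f"({nodes[a]}:{va:.10g},{nodes[b]}:{vb:.10g},{nodes[c]}:{vc:.10g});"
    return parse_newick(newick)


def _quote(label: str) -> str:
    return label.replace(" ", "_")


def parse_newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def _leafsets(tree: dendropy.Tree) -> dict[int, frozenset[str]]:
    """node id -> leaf labels under the node (on the tree's arbitrary
    rooting)."""
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[id(node)] = frozenset({node.taxon.label})
        else:
            s: frozenset[str] = frozenset()
            for ch in node.child_nodes():
                s |= out[id(ch)]
            out[id(node)] = s
    return out


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Canonical nontrivial bipartitions of the unrooted tree."""
    leafsets = _leafsets(tree)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        side = leafsets[id(node)]
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(frozenset({side, all_leaves - side}))
    return out


def is_monophyletic(tree: dendropy.Tree, taxa) -> bool:
    """True iff some edge of the unrooted tree separates exactly ``taxa``."""
    taxa = frozenset(taxa)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    unknown = taxa - all_leaves
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if not taxa:
        raise ValueError("empty taxon set")
    if taxa == all_leaves or len(taxa) == 1 or len(all_leaves - taxa) == 1:
        return True  # trivial splits always exist
    leafsets = _leafsets(tree)
    comp = all_leaves - taxa
    return any(s == taxa or s == comp for s in leafsets.values())


def bootstrap_support(
    alignments_by_locus: dict[str, dict[str, str]],
    tree: dendropy.Tree,
    n_reps: int = 200,
    seed: int = 0,
) -> dendropy.Tree:
    """Column-resampling bootstrap: NJ per replicate, bipartition
    frequencies (percent) written onto the internal nodes of ``tree``.

    Reproducible under a fixed seed; columns are resampled from the
    concatenation across loci.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    taxa, mat = _encode(alignments_by_locus)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[frozenset[str]], int] = {}
    ncols = mat.shape[1]
    for _ in range(n_reps):
        idx = rng.integers(0, ncols, size=ncols)
        rep = mat[:, idx]
        try:
            rep_tree = nj(_p_distance_matrix(rep), taxa)
        except ValueError:  # a pair with no comparable columns: skip replicate
            continue
        for bp in _bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    out = tree.clone(depth=1)
    leafsets = _leafsets(out)
    all_leaves = frozenset(l.taxon.label for l in out.leaf_node_iter())
    for node in out.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = leafsets[id(node)]
        if not (1 < len(side) < len(all_leaves) - 1):
            continue
        key = frozenset({side, all_leaves - side})
        support = 100.0 * counts.get(key, 0) / n_reps
        node.label = f"{support:g}"
    return out


def clade_support(tree: dendropy.Tree, taxa) -> float | None:
    """Bootstrap support written by :func:`bootstrap_support` for the edge
    separating ``taxa``, or None when the clade is not in the tree."""
    taxa = frozenset(taxa)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    leafsets = _leafsets(tree)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = leafsets[id(node)]
        if side == taxa or side == all_leaves - taxa:
            return float(node.label) if node.label else None
    return None
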