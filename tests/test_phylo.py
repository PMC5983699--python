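"""Neighbor joining, p-distance concatenation, bootstrap support, and
monophyly checks."""

import numpy as np
import pandas as pd
import pytest

from plastcomp.phylo import (
    _bipartitions,
    bootstrap_support,
    clade_support,
    concat_distance_matrix,
    is_monophyletic,
    nj,
    parse_newick,
    to_newick,
)
from .oracles import random_additive_tree


class TestConcatDistance:
    def test_identical_rows_zero(self):
        aln = {"locus1": {"a": "ACGTACGTAC", "b": "ACGTACGTAC"}}
        dm = concat_distance_matrix(aln)
        assert dm.loc["a", "b"] == 0.0

    def test_hand_counted(self):
        aln = {"locus1": {"a": "AAAAAAAAAA", "b": "CCCAAAAAAA"}}
        assert concat_distance_matrix(aln).loc["a", "b"] == pytest.approx(0.3)

    def test_concatenation_is_length_weighted_mean(self):
        rng = np.random.default_rng(4)
        loci = {}
        for i, ln in enumerate((30, 90, 60)):
            a = "".join(rng.choice(list("ACGT"), size=ln))
            b = "".join(rng.choice(list("ACGT"), size=ln))
            loci[f"l{i}"] = {"a": a, "b": b}
        total = concat_distance_matrix(loci).loc["a", "b"]
        per_locus = [concat_distance_matrix({k: v}).loc["a", "b"] for k, v in loci.items()]
        lens = [30, 90, 60]
        weighted = sum(d * l for d, l in zip(per_locus, lens)) / sum(lens)
        assert total == pytest.approx(weighted)

    def test_missing_taxon_error(self):
        with pytest.raises(ValueError):
            concat_distance_matrix({"l1": {"a": "AC", "b": "AC"}, "l2": {"a": "AC", "c": "AC"}})


class TestNJ:
    def test_additive_four_taxon_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:1)): path distances below
        d = pd.DataFrame(0.0, index=list("ABCD"), columns=list("ABCD"))
        for (a, b), v in {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 3,
                          ("B", "C"): 6, ("B", "D"): 4, ("C", "D"): 4}.items():
            d.loc[a, b] = d.loc[b, a] = v
        tree = nj(d)
        assert is_monophyletic(tree, ["A", "B"])
        assert is_monophyletic(tree, ["C", "D"])
        # exact branch lengths recovered from the additive matrix
        newick = to_newick(tree)
        assert "A:1" in newick and "B:2" in newick and "C:3" in newick

    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
        )
        t = nj(d)
        # star resolution: vA=(3+4-5)/2=1, vB=(3+5-4)/2=2, vC=(4+5-3)/2=3
        nw = to_newick(t)
        assert "A:1" in nw and "B:2" in nw and "C:3" in nw

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj(pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"]))

    def test_recovers_random_additive_trees(self):
        """NJ is exact on additive matrices: compare bipartitions with the
        generating topology (oracle) for n up to 8."""
        rng = np.random.default_rng(99)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            labels, d, true_bips = random_additive_tree(rng, n)
            tree = nj(np.asarray(d), labels)
            assert _bipartitions(tree) == true_bips

    def test_negative_lengths_clamped(self):
        # a non-additive matrix that induces a negative NJ branch
        d = np.array(
            [[0, 2, 2, 2], [2, 0, 0.1, 2], [2, 0.1, 0, 2], [2, 2, 2, 0]], dtype=float
        )
        tree = nj(d, list("abcd"))
        for edge in tree.edges():
            if edge.length is not None:
                assert edge.length >= 0


class TestMonophyly:
    def test_cherry_and_complement(self):
        t = parse_newick("((a:1,b:1):1,(c:1,(d:1,e:1):1):1);")
        assert is_monophyletic(t, ["a", "b"])
        assert is_monophyletic(t, ["c", "d", "e"])  # complement of a clade
        assert not is_monophyletic(t, ["a", "c"])

    def test_unknown_taxon_error(self):
        t = parse_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError):
            is_monophyletic(t, ["a", "z"])

    def test_agreement_with_bipartition_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            labels, d, bips = random_additive_tree(rng, 8)
            tree = nj(np.asarray(d), labels)
            k = int(rng.integers(2, 7))
            taxa = frozenset(rng.choice(labels, size=k, replace=False))
            sides = {s for bp in bips for s in bp}
            trivial = len(taxa) in (1, 7, 8)
            expected = trivial or taxa in sides or (frozenset(labels) - taxa) in sides
            assert is_monophyletic(tree, taxa) == expected


class TestBootstrap:
    def _congruent_loci(self):
        """Zero-homoplasy alignment: each clade supported by unique columns."""
        taxa = ["a", "b", "c", "d", "e"]
        cols = []
        base = {t: "A" for t in taxa}
        for _ in range(40):
            cols.append(dict(base))
        for _ in range(30):  # (a,b) clade columns
            cols.append({**base, "a": "G", "b": "G"})
        for _ in range(30):  # (d,e) clade columns
            cols.append({**base, "d": "C", "e": "C"})
        aln = {t: "".join(c[t] for c in cols) for t in taxa}
        return {"locus1": aln}

    def test_perfect_data_full_support(self):
        loci = self._congruent_loci()
        tree = nj(concat_distance_matrix(loci))
        bt = bootstrap_support(loci, tree, n_reps=100, seed=3)
        assert clade_support(bt, ["a", "b"]) == 100.0
        assert clade_support(bt, ["d", "e"]) == 100.0

    def test_supports_in_range_and_deterministic(self):
        loci = self._congruent_loci()
        tree = nj(concat_distance_matrix(loci))
        t1 = bootstrap_support(loci, tree, n_reps=50, seed=9)
        t2 = bootstrap_support(loci, tree, n_reps=50, seed=9)
        assert to_newick(t1) == to_newick(t2)
        for node in t1.preorder_node_iter():
            if node.label:
                assert 0.0 <= float(node.label) <= 100.0

    def test_invalid_rep_count(self):
        loci = self._congruent_loci()
        tree = nj(concat_distance_matrix(loci))
        with pytest.raises(ValueError):
            bootstrap_support(loci, tree, n_reps=0, seed=1)


def test_planted_clade_recovered_with_high_support():
    """Six-taxon simulation with a four-taxon ingroup on a long shared
    branch: the ingroup is monophyletic with bootstrap >= 95."""
    from plastcomp.regions import extract_coding
    from plastcomp.simulate import clade_config, evolve_on_tree

    records, truth = evolve_on_tree(clade_config(seed=23))
    per = {t: {r.name: r.sequence for r in extract_coding(rec)} for t, rec in records.items()}
    names = set.intersection(*(set(v) for v in per.values()))
    loci = {n: {t: per[t][n] for t in per} for n in sorted(names)}
    dm = concat_distance_matrix(loci)
    tree = nj(dm)
    assert is_monophyletic(tree, ["t1", "t2", "t3", "t4"])
    bt = bootstrap_support(loci, tree, n_reps=200, seed=5)
    assert clade_support(bt, ["t1", "t2", "t3", "t4"]) >= 95.0
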