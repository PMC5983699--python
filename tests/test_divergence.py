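"""K2p distances and hotspot screening: closed-form checks, alignment
optimality vs exhaustive enumeration, Monte-Carlo estimator recovery,
threshold properties, and planted-hotspot identification."""

import math

import numpy as np
import pytest

from plastcomp.divergence import (
    PairwiseAlignment,
    align_pair,
    hotspot_threshold,
    identify_hotspots,
    k2p,
    region_distance_table,
)
from .oracles import alignment_score_oracle


class TestAlign:
    def test_identical(self):
        a = align_pair("ACGT", "ACGT")
        assert a.gapped_a == a.gapped_b == "ACGT"
        assert a.score == 4.0

    def test_single_gap(self):
        a = align_pair("ACGT", "AGT")
        assert a.gapped_a == "ACGT"
        assert a.gapped_b.count("-") == 1
        assert a.score == 3 - 12  # three matches, one opened gap of length 1

    def test_score_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 8))))
            y = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 8))))
            assert align_pair(x, y).score == pytest.approx(alignment_score_oracle(x, y))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


class TestK2p:
    def test_identical_zero(self):
        r = k2p(("ACGTACGT", "ACGTACGT"))
        assert (r.P, r.Q, r.d) == (0.0, 0.0, 0.0)
        assert r.defined

    def test_single_transition_closed_form(self):
        r = k2p(("AAAA", "GAAA"))
        assert r.P == 0.25 and r.Q == 0.0
        assert r.d == pytest.approx(-0.5 * math.log(0.5), abs=1e-10)
        assert r.d == pytest.approx(0.3466, abs=5e-5)

    def test_mixed_closed_form(self):
        # P = 0.1, Q = 0.05 over 20 sites: 2 transitions, 1 transversion
        a = "A" * 20
        b = "G" * 2 + "C" * 1 + "A" * 17
        r = k2p((a, b))
        assert (r.P, r.Q) == (0.1, 0.05)
        assert r.d == pytest.approx(0.1702, abs=5e-5)

    def test_saturation_flagged(self):
        # P = 0.5, Q = 0.1 -> 1 - 2P - Q < 0
        a = "A" * 10
        b = "G" * 5 + "C" + "A" * 4
        r = k2p((a, b))
        assert not r.defined
        assert math.isnan(r.d)

    def test_gaps_and_n_excluded(self):
        r = k2p(PairwiseAlignment("x", "y", "ACGT-N", "ACGTAA"))
        assert r.n_sites == 4
        assert r.d == 0.0

    def test_monotone_in_P_and_Q(self):
        grid = np.linspace(0.0, 0.2, 9)

        def d(P, Q):
            return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))

        for Q in grid:
            vals = [d(P, Q) for P in grid]
            assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))
        for P in grid:
            vals = [d(P, Q) for Q in grid]
            assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))

    def test_estimator_recovers_true_distance(self):
        """Simulate K2p-evolved pairs (10 kb) and require the mean estimate
        within 3 Monte-Carlo standard errors of truth."""
        rng = np.random.default_rng(2718)
        n, reps, kappa = 10_000, 200, 2.0
        bases = np.array(list("ACGT"))
        for d_true in (0.05, 0.1, 0.2):
            at = d_true * kappa / (kappa + 2)
            bt = d_true / (kappa + 2)
            pP = 0.25 + 0.25 * math.exp(-4 * bt) - 0.5 * math.exp(-2 * (at + bt))
            pQ = 0.5 - 0.5 * math.exp(-4 * bt)
            est = []
            for _ in range(reps):
                counts = rng.multinomial(n, [pP, pQ, 1 - pP - pQ])
                a = "A" * n  # representative sites; only the P/Q counts matter
                b = "G" * counts[0] + "C" * counts[1] + "A" * (n - counts[0] - counts[1])
                r = k2p((a, b))
                assert r.defined
                est.append(r.d)
            est = np.array(est)
            se = est.std(ddof=1) / math.sqrt(reps)
            assert abs(est.mean() - d_true) < 3 * se + 1e-9


class TestThreshold:
    def test_constant_values(self):
        assert hotspot_threshold([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_hand_computed(self):
        assert hotspot_threshold([0.1, 0.2, 0.3]) == pytest.approx(0.4)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            hotspot_threshold([0.1])

    def test_permutation_invariance_and_affine_equivariance(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 0.5, size=20)
        t = hotspot_threshold(vals)
        assert hotspot_threshold(vals[::-1]) == pytest.approx(t)
        a, b = 2.5, 0.1
        assert hotspot_threshold(a * vals + b) == pytest.approx(a * t + b)


class TestTableAndHotspots:
    def test_identical_genomes_all_zero(self, root_genome):
        from plastcomp.regions import extract_all

        rec, _ = root_genome
        regions = sum(extract_all(rec).values(), [])
        table = region_distance_table({"a": regions, "b": regions}, prealigned=True)
        assert all(r.d == 0.0 for pairs in table.cells.values() for r in pairs.values())
        assert identify_hotspots(table, 0.0) == []

    def test_truth_alignment_matches_realized_counts(self, default_sim):
        """P and Q from the pipeline equal the generator's realized
        substitution proportions (positional truth alignment)."""
        from plastcomp.regions import extract_all

        records, truth = default_sim
        regions = {t: extract_all(r)["IGS"] for t, r in records.items()}
        table = region_distance_table(regions, prealigned=False)
        checked = 0
        for region in list(table.cells)[:12]:
            for (a, b) in table.cells[region]:
                L, ts, tv = truth.region_diff(a, b, region)
                r = table.get(region, a, b)
                if r.n_sites == L:  # aligner recovered the positional alignment
                    assert round(r.P * L) == ts
                    assert round(r.Q * L) == tv
                    checked += 1
        assert checked > 10

    def test_planted_hotspots_identified(self, default_sim):
        from plastcomp.regions import extract_all

        records, truth = default_sim
        regions = {t: extract_all(r)["IGS"] for t, r in records.items()}
        table = region_distance_table(regions)
        thr = hotspot_threshold(table.defined_values("IGS"))
        assert set(identify_hotspots(table, thr)) == set(truth.hotspot_names())

    def test_threshold_zero_flags_any_divergence(self, default_sim):
        from plastcomp.regions import extract_all

        records, _ = default_sim
        regions = {t: extract_all(r)["IGS"] for t, r in records.items()}
        table = region_distance_table(regions)
        flagged = set(identify_hotspots(table, 0.0))
        diverged = {
            name for name in table.cells
            if table.categories[name] == "IGS" and table.region_max(name) > 0
        }
        assert flagged == diverged
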