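"""Synthetic plastome generator: determinism, structural guarantees,
truth round trips through the detectors, gene losses, and file emission."""

import numpy as np
import pytest

from plastcomp.model import read_genbank
from plastcomp.simulate import SimConfig, emit, evolve_on_tree, generate_root


class TestGenerateRoot:
    def test_structure(self, root_genome):
        rec, _ = root_genome
        cfg = SimConfig()
        assert len(rec.features) == cfg.n_genes
        kinds = [f.kind for f in rec.features]
        assert kinds.count("tRNA") == cfg.n_trna
        assert kinds.count("rRNA") == cfg.n_rrna
        # every CDS is a valid ORF: starts ATG, ends with a stop, no internal stops
        from plastcomp.composition import STOP_CODONS
        from plastcomp.regions import extract_coding

        for r in extract_coding(rec):
            seq = r.sequence
            assert len(seq) % 3 == 0
            assert seq.startswith("ATG") and seq[-3:] in STOP_CODONS
            assert not any(seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - 3, 3))

    def test_intron_genes(self, root_genome):
        rec, _ = root_genome
        from plastcomp.regions import extract_introns

        introns = extract_introns(rec)
        # first CDS gets two introns, the next two one each
        names = sorted(r.name for r in introns)
        assert names == ["gsp1.intron1", "gsp1.intron2", "gsp2.intron1", "gsp3.intron1"]

    def test_fixed_seed_reproducible(self):
        r1, _ = generate_root(SimConfig(seed=42))
        r2, _ = generate_root(SimConfig(seed=42))
        assert r1.sequence == r2.sequence
        r3, _ = generate_root(SimConfig(seed=43))
        assert r3.sequence != r1.sequence

    def test_planted_ssrs_recovered_exactly(self, root_genome):
        from plastcomp.ssr import find_ssrs_circular

        rec, truth = root_genome
        found = {(l.motif, l.interval.start, l.n_units, l.remainder) for l in find_ssrs_circular(rec.sequence)}
        planted = {(r["motif"], r["start"], r["n_units"], 0) for r in truth.planted_ssrs}
        assert planted <= found
        assert len(planted) == len(SimConfig().planted_ssrs)

    def test_planted_repeats_recovered_exactly(self, root_genome):
        from plastcomp.repeats import find_dispersed_repeats

        rec, truth = root_genome
        pairs = find_dispersed_repeats(rec.sequence)
        detected = {(p.kind, p.pos1.start, p.pos1.end, p.pos2.start, p.pos2.end) for p in pairs}
        for rid in {r["repeat_id"] for r in truth.planted_repeats}:
            copies = sorted(
                ((r["start"], r["end"]) for r in truth.planted_repeats if r["repeat_id"] == rid)
            )
            kind = next(r["kind"] for r in truth.planted_repeats if r["repeat_id"] == rid)
            (s1, e1), (s2, e2) = copies
            assert (kind, s1, e1, s2, e2) in detected


class TestEvolve:
    def test_zero_branch_identical(self):
        cfg = SimConfig(seed=2, gene_losses=[], tree="(t1:0.0,t2:0.05);")
        records, truth = evolve_on_tree(cfg)
        root, _ = generate_root(SimConfig(seed=2, gene_losses=[], tree="(t1:0.0,t2:0.05);"))
        assert records["t1"].sequence == root.sequence

    def test_realized_counts_match_sequence_diff(self, default_sim):
        records, truth = default_sim
        # two-taxon diff equals the sum over the connecting path only when
        # sites are hit once; verify instead against the truth layouts
        L, ts, tv = truth.region_diff("t1", "t2", "gsp4-gsp5")
        assert L > 0 and ts >= 0 and tv >= 0

    def test_branch_counts_for_leaf_edges(self):
        """On a two-taxon tree with one zero branch, the t2 branch counts
        equal the observable sequence difference per region."""
        cfg = SimConfig(seed=3, gene_losses=[], tree="(t1:0.0,t2:0.08);")
        records, truth = evolve_on_tree(cfg)
        for region in ("gsp4-gsp5", "gsp9-gsp10", "gsp1"):
            L, ts, tv = truth.region_diff("t1", "t2", region)
            bl = truth.branch_subs[("t2", region)]
            assert (ts, tv) == (bl[1], bl[2])

    def test_gene_losses_applied(self, default_sim):
        records, truth = default_sim
        cfg = truth.config
        for taxon, gene in cfg.gene_losses:
            assert gene not in {f.name for f in records[taxon].features}
            assert not truth.presence[(taxon, gene)]
        # sequence deleted too: lost-gene taxa are shorter
        t_lost = cfg.gene_losses[0][0]
        others = [t for t in records if all(t != x for x, _ in cfg.gene_losses)]
        assert len(records[t_lost]) < len(records[others[0]])

    def test_unknown_hotspot_error(self):
        cfg = SimConfig(hotspot_regions=[("nope-nope", 5.0)])
        with pytest.raises(ValueError):
            evolve_on_tree(cfg)

    def test_unknown_loss_error(self):
        cfg = SimConfig(gene_losses=[("t1", "missing")])
        with pytest.raises(ValueError):
            evolve_on_tree(cfg)

    def test_hotspots_have_top_mean_divergence(self):
        """Rate-boosted spacers carry the largest raw divergence in most
        seeds (checked on the truth alignments, a handful of seeds)."""
        wins = 0
        for seed in range(5):
            cfg = SimConfig(seed=300 + seed)
            records, truth = evolve_on_tree(cfg)
            taxa = sorted(records)
            igs_names = [el for el in truth.layouts["root"] if hasattr(el, "protected")]
            means = {}
            for sp in igs_names:
                vals = []
                for i in range(len(taxa)):
                    for j in range(i + 1, len(taxa)):
                        L, ts, tv = truth.region_diff(taxa[i], taxa[j], sp.name)
                        vals.append((ts + tv) / L)
                means[sp.name] = np.mean(vals)
            top2 = sorted(means, key=means.get, reverse=True)[:2]
            if set(top2) == set(truth.hotspot_names()):
                wins += 1
        assert wins >= 4


class TestEmit:
    def test_roundtrip_and_determinism(self, tmp_path, default_sim):
        records, truth = default_sim
        out1 = tmp_path / "run1"
        files = emit(records, truth, out1)
        assert (out1 / "truth_ssrs.tsv").exists()
        assert (out1 / "config.yaml").exists()
        # GenBank round trip preserves features
        rec = records["t1"]
        back = read_genbank(out1 / "t1.gb")
        assert back.sequence == rec.sequence
        assert {(f.name, f.kind, f.strand) for f in back.features} == {
            (f.name, f.kind, f.strand) for f in rec.features
        }
        # truth table row counts match planted elements (per taxon + root rows)
        import pandas as pd

        df = pd.read_csv(out1 / "truth_ssrs.tsv", sep="\t")
        per_taxon = df.groupby("taxon").size()
        assert all(per_taxon == len(truth.config.planted_ssrs))
        # same seed reproduces files byte-for-byte
        records2, truth2 = evolve_on_tree(SimConfig(seed=truth.config.seed))
        out2 = tmp_path / "run2"
        emit(records2, truth2, out2)
        assert (out1 / "t1.fasta").read_bytes() == (out2 / "t1.fasta").read_bytes()
        assert (out1 / "t2.gb").read_bytes() == (out2 / "t2.gb").read_bytes()

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=7)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg
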