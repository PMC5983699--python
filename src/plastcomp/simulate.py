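"""Synthetic annotated plastome sets with full ground truth.

The generator emulates, at desk scale, the inputs of a multi-species
plastome comparison: a circular single-copy genome assembled gene-by-gene
(CDS / tRNA / rRNA, some multi-exon) with intergenic spacers, evolved along
a dated tree under a two-class (transition/transversion) substitution model
with per-region rate multipliers.  Everything a downstream detector should
find is *planted* and logged: SSR tracts, forward/palindromic repeat pairs,
divergence hotspots (rate-boosted spacers), and gene losses (feature and
sequence deleted, fusing the flanking spacers).

Planted SSRs and repeats are flanked by deliberate mismatch breakers and
excluded from substitution, so their per-taxon coordinates in the truth
table are exact; coordinates differ between taxa only through gene losses
upstream.  Substitutions are single-hit per site per branch and indel-free,
so the positional alignment of any region across taxa is the identity and
realized transition/transversion counts are exactly recoverable by diffing.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import yaml

from .composition import STOP_CODONS, translate_codon
from .model import GeneFeature, Interval, PlastomeRecord, revcomp, write_fasta, write_genbank

log = logging.getLogger(__name__)

SENSE_CODONS = sorted(
    c for c in ("".join((a, b, d)) for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in STOP_CODONS
)

# transition partner of each base
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

BASES = np.array(list("ACGT"))
BASE_PROBS = np.array([0.325, 0.175, 0.175, 0.325])  # AT-rich, plastome-like

# sense-codon sampling weighted by the AT-rich base composition, so coding
# GC lands near real plastome values instead of 50%
_BP = dict(zip("ACGT", BASE_PROBS))
_CODON_W = np.array([_BP[c[0]] * _BP[c[1]] * _BP[c[2]] for c in SENSE_CODONS])
CODON_PROBS = _CODON_W / _CODON_W.sum()


@dataclass
class SimConfig:
    """Study-scale defaults: four taxa in two cherries, 30 genes, two
    rate-boosted hotspot spacers, ten planted SSRs, three planted dispersed
    repeats, and two gene losses."""

    seed: int = 0
    n_taxa: int = 4
    n_genes: int = 30
    n_trna: int = 2
    n_rrna: int = 1
    gene_length: tuple[float, float] = (600.0, 150.0)
    igs_length: tuple[float, float] = (250.0, 80.0)
    intron_genes: int = 3
    intron_length: tuple[float, float] = (300.0, 60.0)
    base_rate: float = 1.0  # substitutions/site per unit branch length
    kappa: float = 2.0  # transition/transversion rate ratio
    hotspot_regions: list[tuple[str, float]] = field(
        default_factory=lambda: [("gsp5-gsp6", 10.0), ("gsp12-gsp13", 10.0)]
    )
    planted_ssrs: list[tuple[str, int, str]] = field(
        default_factory=lambda: [
            ("A", 10, "gsp2-gsp3"),
            ("T", 12, "gsp3-gsp4"),
            ("AT", 6, "gsp6-gsp7"),
            ("AG", 5, "gsp9-gsp10"),
            ("AAT", 5, "gsp13-gsp14"),
            ("ACT", 4, "gsp16-gsp17"),
            ("AATT", 4, "gsp17-gsp18"),
            ("AATC", 3, "gsp19-gsp20"),
            ("AACGT", 3, "gsp21-gsp22"),
            ("AACGTC", 3, "gsp25-gsp26"),
        ]
    )
    planted_repeats: list[tuple[str, int, tuple[str, str]]] = field(
        default_factory=lambda: [
            ("forward", 40, ("gsp8-gsp9", "gsp20-gsp21")),
            ("palindromic", 35, ("gsp10-gsp11", "gsp22-gsp23")),
            ("forward", 32, ("gsp15-gsp16", "gsp24-gsp25")),
        ]
    )
    gene_losses: list[tuple[str, str]] = field(
        default_factory=lambda: [("t2", "gsp7"), ("t4", "gsp18")]
    )
    selection: dict[str, str] = field(default_factory=dict)  # gene -> neutral|syn_only|positive
    tree: str = "((t1:0.03,t2:0.03):0.02,(t3:0.03,t4:0.03):0.02);"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        # YAML round-trips tuples as lists
        cfg.gene_length = tuple(cfg.gene_length)
        cfg.igs_length = tuple(cfg.igs_length)
        cfg.intron_length = tuple(cfg.intron_length)
        cfg.hotspot_regions = [tuple(x) for x in cfg.hotspot_regions]
        cfg.planted_ssrs = [tuple(x) for x in cfg.planted_ssrs]
        cfg.planted_repeats = [(k, l, tuple(p)) for k, l, p in cfg.planted_repeats]
        cfg.gene_losses = [tuple(x) for x in cfg.gene_losses]
        return cfg


# --------------------------------------------------------------------------
# internal genome representation: alternating genes and spacers, sequences
# kept in transcript orientation for genes so coding-aware evolution is
# strand-agnostic
# --------------------------------------------------------------------------


@dataclass
class _Part:
    kind: str  # exon | intron
    seq: str


@dataclass
class _Gene:
    name: str
    kind: str  # CDS | tRNA | rRNA
    strand: str
    parts: list[_Part]

    def coding_seq(self) -> str:
        return "".join(p.seq for p in self.parts if p.kind == "exon")

    def full_len(self) -> int:
        return sum(len(p.seq) for p in self.parts)


@dataclass
class _Spacer:
    name: str
    seq: str
    protected: np.ndarray  # bool mask, True = no substitutions
    plants: list[dict] = field(default_factory=list)  # truth rows, spacer-relative


_Element = _Gene | _Spacer


@dataclass
class Truth:
    """Ground truth for one simulated data set."""

    config: SimConfig
    tree_newick: str
    planted_ssrs: list[dict] = field(default_factory=list)  # per-taxon rows
    planted_repeats: list[dict] = field(default_factory=list)
    presence: dict[tuple[str, str], bool] = field(default_factory=dict)
    branch_subs: dict[tuple[str, str], tuple[int, int, int]] = field(default_factory=dict)
    layouts: dict[str, list] = field(default_factory=dict)  # taxon -> element list

    def region_diff(self, taxon_a: str, taxon_b: str, region: str) -> tuple[int, int, int]:
        """(sites, transitions, transversions) between two taxa for one
        region, from the positional truth alignment."""
        sa = _region_seq(self.layouts[taxon_a], region)
        sb = _region_seq(self.layouts[taxon_b], region)
        if sa is None or sb is None:
            raise KeyError(f"region {region} absent from a layout")
        ts = tv = 0
        for x, y in zip(sa, sb):
            if x == y:
                continue
            if TRANSITION[x] == y:
                ts += 1
            else:
                tv += 1
        return len(sa), ts, tv

    def hotspot_names(self) -> list[str]:
        return [name for name, _ in self.config.hotspot_regions]


def _region_seq(layout: list, region: str) -> str | None:
    for el in layout:
        if isinstance(el, _Spacer) and el.name == region:
            return el.seq
        if isinstance(el, _Gene) and el.name == region:
            return el.coding_seq()
    # introns: gene.intronN
    if ".intron" in region:
        gname, _, num = region.partition(".intron")
        for el in layout:
            if isinstance(el, _Gene) and el.name == gname:
                introns = [p for p in el.parts if p.kind == "intron"]
                idx = int(num) - 1
                if 0 <= idx < len(introns):
                    return introns[idx].seq
    return None


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length, p=BASE_PROBS))


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + sense codons + TAA; length is rounded to a codon multiple."""
    n_codons = max(4, int(round(length / 3)))
    body = rng.choice(SENSE_CODONS, size=n_codons - 2, p=CODON_PROBS)
    return "ATG" + "".join(body) + "TAA"


def _plant_in_spacer(spacer: _Spacer, offset: int, tract: str,
                     left_breaker: str, right_breaker: str, row: dict,
                     rng: np.random.Generator) -> None:
    """Write a planted element plus its flanking mismatch breakers into a
    spacer, protect the span, and record the truth row (spacer-relative).

    The spacer is padded with random sequence when too short; overlapping
    plants are an error."""
    lo = offset - len(left_breaker)
    hi = offset + len(tract) + len(right_breaker)
    if lo < 1:
        offset += 1 - lo
        lo, hi = 1, hi + 1 - lo
    if hi > len(spacer.seq) - 1:
        pad = hi - (len(spacer.seq) - 1)
        spacer.seq += _random_seq(rng, pad)
        spacer.protected = np.concatenate([spacer.protected, np.zeros(pad, dtype=bool)])
    seq = list(spacer.seq)
    if spacer.protected[lo:hi].any():
        raise ValueError(f"planted elements overlap in spacer {spacer.name}")
    seq[lo:offset] = list(left_breaker)
    seq[offset : offset + len(tract)] = list(tract)
    seq[offset + len(tract) : hi] = list(right_breaker)
    spacer.seq = "".join(seq)
    spacer.protected[lo:hi] = True
    row["offset"] = offset
    row["length"] = len(tract)
    spacer.plants.append(row)


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return str(rng.choice(choices))


def build_root_layout(config: SimConfig, rng: np.random.Generator) -> list[_Element]:
    """Assemble the root genome as an alternating gene/spacer element list."""
    n_cds = config.n_genes - config.n_trna - config.n_rrna
    if n_cds < 1:
        raise ValueError("n_genes must exceed n_trna + n_rrna")
    genes: list[_Gene] = []
    mu, sd = config.gene_length
    for i in range(n_cds):
        name = f"gsp{i + 1}"
        length = max(90.0, rng.normal(mu, sd))
        cds = _random_cds(rng, length)
        strand = "-" if i % 3 == 2 else "+"
        if i < config.intron_genes:
            n_introns = 2 if i == 0 else 1
            parts = _split_with_introns(cds, n_introns, config, rng)
        else:
            parts = [_Part("exon", cds)]
        genes.append(_Gene(name, "CDS", strand, parts))
    trna_anticodons = ["trnE-UUC", "trnM-CAU", "trnD-GUC", "trnW-CCA", "trnL-UAA", "trnF-GAA"]
    for i in range(config.n_trna):
        name = trna_anticodons[i % len(trna_anticodons)]
        genes.append(_Gene(name, "tRNA", "-" if i % 2 else "+", [_Part("exon", _random_seq(rng, 74))]))
    for i in range(config.n_rrna):
        genes.append(_Gene(f"rrn{16 + 7 * i}", "rRNA", "+", [_Part("exon", _random_seq(rng, 1500))]))

    imu, isd = config.igs_length
    layout: list[_Element] = []
    for i, gene in enumerate(genes):
        layout.append(gene)
        nxt = genes[(i + 1) % len(genes)]
        length = max(40, int(round(rng.normal(imu, isd))))
        seq = _random_seq(rng, length)
        layout.append(_Spacer(f"{gene.name}-{nxt.name}", seq, np.zeros(length, dtype=bool)))

    spacers = {el.name: el for el in layout if isinstance(el, _Spacer)}

    for motif, n_units, region in config.planted_ssrs:
        sp = spacers.get(region)
        if sp is None:
            raise ValueError(f"planted SSR targets unknown spacer {region}")
        tract = motif * n_units
        # flank breakers stop the tract from extending by chance
        left = _other_base(rng, motif[-1])
        right = _other_base(rng, motif[0])
        offset = max(2, (len(sp.seq) - len(tract)) // 2)
        _plant_in_spacer(
            sp, offset, tract, left, right,
            {"element": "ssr", "motif": motif, "unit_len": len(motif), "n_units": n_units},
            rng,
        )

    for idx, (kind, length, (reg1, reg2)) in enumerate(config.planted_repeats):
        sp1, sp2 = spacers.get(reg1), spacers.get(reg2)
        if sp1 is None or sp2 is None:
            raise ValueError(f"planted repeat targets unknown spacer {reg1} or {reg2}")
        block = _random_seq(rng, length)
        copy2 = block if kind == "forward" else revcomp(block)
        # four consecutive forced mismatches on each flank of each copy pin
        # the maximal repeat window exactly to the planted block
        f1l, f1r = "A" * 4, "C" * 4
        if kind == "forward":
            f2l, f2r = "C" * 4, "A" * 4  # positionwise A vs C and C vs A: mismatch
        else:
            # on the palindromic diagonal, extending left of copy1 (A...) pairs
            # against the complement of copy2's right flank, and extending
            # right of copy1 (C...) against the complement of copy2's left
            # flank: comp(A)=T so the right flank must avoid T, comp(C)=G so
            # the left flank must avoid G
            f2l, f2r = "A" * 4, "C" * 4
        off1 = max(6, len(sp1.seq) // 3)
        off2 = max(6, 2 * len(sp2.seq) // 3)
        _plant_in_spacer(sp1, off1, block, f1l, f1r,
                         {"element": "repeat", "repeat_id": idx, "kind": kind, "copy": 1}, rng)
        _plant_in_spacer(sp2, off2, copy2, f2l, f2r,
                         {"element": "repeat", "repeat_id": idx, "kind": kind, "copy": 2}, rng)
    return layout


def _split_with_introns(cds: str, n_introns: int, config: SimConfig, rng: np.random.Generator) -> list[_Part]:
    imu, isd = config.intron_length
    n_codons = len(cds) // 3
    cut_codons = sorted(rng.choice(np.arange(2, n_codons - 2), size=n_introns, replace=False))
    parts: list[_Part] = []
    prev = 0
    for c in cut_codons:
        parts.append(_Part("exon", cds[prev * 3 : c * 3]))
        intron_len = max(60, int(round(rng.normal(imu, isd))))
        intron = "GT" + _random_seq(rng, intron_len - 4) + "AG"  # canonical-ish ends
        parts.append(_Part("intron", intron))
        prev = c
    parts.append(_Part("exon", cds[prev * 3 :]))
    return parts


# --------------------------------------------------------------------------
# evolution
# --------------------------------------------------------------------------


def _mutate_neutral(seq: str, protected: np.ndarray | None, p_sub: float, kappa: float,
                    rng: np.random.Generator) -> tuple[str, int, int]:
    """Single-hit-per-site substitutions; returns (sequence, ts, tv)."""
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < p_sub)
    if protected is not None:
        hits = hits[~protected[hits]]
    if hits.size == 0:
        return seq, 0, 0
    chars = list(seq)
    ts = tv = 0
    p_ts = kappa / (kappa + 2.0)
    for i in hits:
        base = chars[i]
        if base not in TRANSITION:
            continue
        if rng.random() < p_ts:
            chars[i] = TRANSITION[base]
            ts += 1
        else:
            chars[i] = TRANSVERSIONS[base][int(rng.integers(2))]
            tv += 1
    return "".join(chars), ts, tv


def _mutate_cds(seq: str, p_sub: float, kappa: float, mode: str,
                rng: np.random.Generator) -> tuple[str, int, int]:
    """Codon-aware substitutions: never create a stop codon; ``syn_only``
    accepts only synonymous changes, ``positive`` thins synonymous changes
    to one third (a nonsynonymous excess, omega above 1 by construction)."""
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < p_sub)
    chars = list(seq)
    ts = tv = 0
    p_ts = kappa / (kappa + 2.0)
    for i in hits:
        base = chars[i]
        if base not in TRANSITION:
            continue
        if rng.random() < p_ts:
            new, is_ts = TRANSITION[base], True
        else:
            new, is_ts = TRANSVERSIONS[base][int(rng.integers(2))], False
        c0 = 3 * (i // 3)
        old_codon = "".join(chars[c0 : c0 + 3])
        new_codon = old_codon[: i - c0] + new + old_codon[i - c0 + 1 :]
        if new_codon in STOP_CODONS or old_codon in STOP_CODONS:
            continue
        synonymous = translate_codon(new_codon) == translate_codon(old_codon)
        if mode == "syn_only" and not synonymous:
            continue
        if mode == "positive" and synonymous and rng.random() > 1.0 / 3.0:
            continue
        chars[i] = new
        if is_ts:
            ts += 1
        else:
            tv += 1
    return "".join(chars), ts, tv


def _evolve_layout(layout: list[_Element], branch_length: float, config: SimConfig,
                   rng: np.random.Generator) -> tuple[list[_Element], dict[str, tuple[int, int, int]]]:
    multipliers = dict(config.hotspot_regions)
    out: list[_Element] = []
    subs: dict[str, tuple[int, int, int]] = {}
    for el in layout:
        if isinstance(el, _Spacer):
            rate = config.base_rate * multipliers.get(el.name, 1.0) * branch_length
            p_sub = -np.expm1(-rate)
            seq, ts, tv = _mutate_neutral(el.seq, el.protected, p_sub, config.kappa, rng)
            out.append(_Spacer(el.name, seq, el.protected.copy(), [dict(r) for r in el.plants]))
            subs[el.name] = (len(seq), ts, tv)
        else:
            p_sub = -np.expm1(-config.base_rate * branch_length)
            new_parts: list[_Part] = []
            g_ts = g_tv = 0
            mode = config.selection.get(el.name, "neutral")
            if el.kind == "CDS":
                coding = el.coding_seq()
                mutated, cts, ctv = _mutate_cds(coding, p_sub, config.kappa, mode, rng)
                g_ts, g_tv = cts, ctv
                pos = 0
                for p in el.parts:
                    if p.kind == "exon":
                        new_parts.append(_Part("exon", mutated[pos : pos + len(p.seq)]))
                        pos += len(p.seq)
                    else:
                        iseq, its, itv = _mutate_neutral(p.seq, None, p_sub, config.kappa, rng)
                        new_parts.append(_Part("intron", iseq))
                        idx = sum(1 for q in new_parts if q.kind == "intron")
                        subs[f"{el.name}.intron{idx}"] = (len(iseq), its, itv)
            else:
                for p in el.parts:
                    pseq, pts, ptv = _mutate_neutral(p.seq, None, p_sub, config.kappa, rng)
                    new_parts.append(_Part(p.kind, pseq))
                    g_ts += pts
                    g_tv += ptv
            out.append(_Gene(el.name, el.kind, el.strand, new_parts))
            subs[el.name] = (len(el.coding_seq()), g_ts, g_tv)
    return out, subs


# --------------------------------------------------------------------------
# assembly and public API
# --------------------------------------------------------------------------


def assemble_record(layout: list[_Element], taxon: str, lost_genes: set[str],
                    truth: Truth | None = None) -> PlastomeRecord:
    """Concatenate a layout into a circular annotated record, dropping lost
    genes (sequence deleted, spacers fused) and logging per-taxon planted
    element coordinates into ``truth``."""
    chunks: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for el in layout:
        if isinstance(el, _Spacer):
            for row in el.plants:
                if truth is not None:
                    entry = dict(row)
                    entry["taxon"] = taxon
                    entry["start"] = pos + row["offset"]
                    entry["end"] = pos + row["offset"] + row["length"]
                    entry["region"] = el.name
                    (truth.planted_ssrs if row["element"] == "ssr" else truth.planted_repeats).append(entry)
            chunks.append(el.seq)
            pos += len(el.seq)
            continue
        if el.name in lost_genes:
            continue
        gene_len = el.full_len()
        pre_mrna = "".join(p.seq for p in el.parts)
        genome_seq = pre_mrna if el.strand == "+" else revcomp(pre_mrna)
        exon_ivs = []
        off = 0
        for p in el.parts:
            if p.kind == "exon":
                if el.strand == "+":
                    exon_ivs.append(Interval(pos + off, pos + off + len(p.seq), "+"))
                else:
                    exon_ivs.append(
                        Interval(pos + gene_len - off - len(p.seq), pos + gene_len - off, "-")
                    )
            off += len(p.seq)
        exon_ivs.sort(key=lambda iv: iv.start)
        features.append(GeneFeature(el.name, el.kind, exon_ivs))
        chunks.append(genome_seq)
        pos += gene_len
    return PlastomeRecord(taxon, f"synthetic taxon {taxon}", "".join(chunks), True, features)


def generate_root(config: SimConfig) -> tuple[PlastomeRecord, Truth]:
    """Build the root genome; byte-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    layout = build_root_layout(config, rng)
    truth = Truth(config=config, tree_newick=config.tree)
    truth.layouts["root"] = layout
    record = assemble_record(layout, "root", set(), truth)
    return record, truth


def evolve_on_tree(config: SimConfig) -> tuple[dict[str, PlastomeRecord], Truth]:
    """Generate the root and evolve it along the configured tree.

    Returns per-taxon records plus the complete ground truth (planted
    element coordinates per taxon, presence matrix, per-branch realized
    substitution counts, generating tree).
    """
    rng = np.random.default_rng(config.seed)
    layout = build_root_layout(config, rng)
    truth = Truth(config=config, tree_newick=config.tree)
    truth.layouts["root"] = layout

    tree = dendropy.Tree.get(data=config.tree, schema="newick", preserve_underscores=True)
    taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
    known_regions = {el.name for el in layout if isinstance(el, _Spacer)}
    for name, _ in config.hotspot_regions:
        if name not in known_regions:
            raise ValueError(f"hotspot region {name} not in layout")
    gene_names = {el.name for el in layout if isinstance(el, _Gene)}
    for taxon, gene in config.gene_losses:
        if taxon not in taxa or gene not in gene_names:
            raise ValueError(f"gene loss ({taxon}, {gene}) references unknown taxon or gene")

    layouts_at: dict[int, list[_Element]] = {id(tree.seed_node): layout}
    counter = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_layout = layouts_at[id(node.parent_node)]
        bl = node.edge.length or 0.0
        child_layout, subs = _evolve_layout(parent_layout, bl, config, rng)
        layouts_at[id(node)] = child_layout
        if node.is_leaf():
            label = node.taxon.label
        else:
            counter += 1
            label = node.label or f"node{counter}"
        for region, trip in subs.items():
            truth.branch_subs[(label, region)] = trip
        if node.is_leaf():
            truth.layouts[label] = child_layout

    losses: dict[str, set[str]] = {t: set() for t in taxa}
    for taxon, gene in config.gene_losses:
        losses[taxon].add(gene)
    records: dict[str, PlastomeRecord] = {}
    for t in taxa:
        records[t] = assemble_record(truth.layouts[t], t, losses[t], truth)
        for g in sorted(gene_names):
            truth.presence[(t, g)] = g not in losses[t]
    return records, truth


def emit(records: dict[str, PlastomeRecord], truth: Truth, outdir) -> list[Path]:
    """Write one GenBank + FASTA per taxon, the truth tables as TSV, and an
    echo of the configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for taxon, rec in sorted(records.items()):
        gb = outdir / f"{taxon}.gb"
        fa = outdir / f"{taxon}.fasta"
        write_genbank(rec, gb)
        write_fasta([(rec.id, rec.sequence)], fa)
        written += [gb, fa]

    import pandas as pd

    if truth.planted_ssrs:
        df = pd.DataFrame(truth.planted_ssrs)
        df.to_csv(outdir / "truth_ssrs.tsv", sep="\t", index=False)
        written.append(outdir / "truth_ssrs.tsv")
    if truth.planted_repeats:
        df = pd.DataFrame(truth.planted_repeats)
        df.to_csv(outdir / "truth_repeats.tsv", sep="\t", index=False)
        written.append(outdir / "truth_repeats.tsv")
    if truth.presence:
        rows = [{"taxon": t, "gene": g, "present": "+" if v else "-"} for (t, g), v in sorted(truth.presence.items())]
        pd.DataFrame(rows).to_csv(outdir / "truth_presence.tsv", sep="\t", index=False)
        written.append(outdir / "truth_presence.tsv")
    if truth.branch_subs:
        rows = [
            {"branch": b, "region": r, "sites": L, "transitions": ts, "transversions": tv}
            for (b, r), (L, ts, tv) in sorted(truth.branch_subs.items())
        ]
        pd.DataFrame(rows).to_csv(outdir / "truth_substitutions.tsv", sep="\t", index=False)
        written.append(outdir / "truth_substitutions.tsv")
    truth.config.to_yaml(outdir / "config.yaml")
    written.append(outdir / "config.yaml")
    return written


def clade_config(seed: int = 0) -> SimConfig:
    """Six taxa with a four-taxon ingroup on an elevated shared branch;
    used for clade-recovery and bootstrap checks."""
    return SimConfig(
        seed=seed,
        n_taxa=6,
        gene_losses=[],
        tree="(((t1:0.02,t2:0.02):0.015,(t3:0.02,t4:0.02):0.015):0.06,t5:0.04,t6:0.05);",
    )
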