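"""Composition accounting for a plastome: GC contents (overall, per gene
class, per codon position), codon usage under the plastid (bacterial) genetic
code, and the per-genome summary table.

Percentages are reported half-up-rounded to two decimals; amino-acid usage
percentages use the total codon count (stops included) as denominator, and
gene-class size percentages use total genome length as denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import product

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .model import PlastomeRecord
from .regions import RegionSeq, extract_coding

log = logging.getLogger(__name__)

# NCBI translation table 11: bacterial / archaeal / plant plastid
PLASTID_TABLE = unambiguous_dna_by_id[11]

AMINO_ACIDS = sorted(set(PLASTID_TABLE.forward_table.values()))  # 20 one-letter codes
ALL_CODONS = ["".join(c) for c in product("ACGT", repeat=3)]
STOP_CODONS = set(PLASTID_TABLE.stop_codons)


def translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stop, 'X' for any codon containing N."""
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    return PLASTID_TABLE.forward_table[codon]


def round_percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100*numerator/denominator, rounded half-up to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
    )


def gc_content(sequence: str) -> float:
    """GC fraction; N excluded from the denominator. None if no A/C/G/T."""
    seq = sequence.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        log.warning("gc_content: sequence has no unambiguous bases")
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def gc_by_codon_position(coding_regions: list[RegionSeq | str]) -> tuple[float, float, float]:
    """GC fraction pooled over all regions at codon positions 1, 2, 3.

    Regions whose length is not a codon multiple are excluded with a warning.
    """
    pooled = ["", "", ""]
    for region in coding_regions:
        seq = region if isinstance(region, str) else region.sequence
        if len(seq) % 3 != 0:
            log.warning("gc_by_codon_position: region length %d not a codon multiple; excluded", len(seq))
            continue
        for k in range(3):
            pooled[k] += seq[k::3]
    return tuple(gc_content(p) for p in pooled)  # type: ignore[return-value]


@dataclass
class CodonTable:
    """Codon and amino-acid usage counts for a set of coding regions."""

    codon_counts: dict[str, int]
    aa_counts: dict[str, int]  # 20 amino acids + '*' (stop) + 'X' (ambiguous)
    total_codons: int

    def aa_percent(self, aa: str) -> float:
        return round_percent(self.aa_counts.get(aa, 0), self.total_codons)


def codon_usage(coding_regions: list[RegionSeq | str]) -> CodonTable:
    codon_counts = {c: 0 for c in ALL_CODONS}
    aa_counts = {aa: 0 for aa in AMINO_ACIDS}
    aa_counts["*"] = 0
    aa_counts["X"] = 0
    total = 0
    for region in coding_regions:
        seq = region if isinstance(region, str) else region.sequence
        if len(seq) % 3 != 0:
            raise ValueError(f"coding region length {len(seq)} not divisible by 3")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            total += 1
            if "N" in codon:
                aa_counts["X"] += 1
                continue
            codon_counts[codon] += 1
            aa_counts[translate_codon(codon)] += 1
    return CodonTable(codon_counts, aa_counts, total)


@dataclass
class GenomeSummary:
    """One summary row per plastome, mirroring the standard characteristics
    table (lengths, gene counts, partition sizes and GC contents)."""

    record_id: str
    organism: str
    length: int
    n_genes: int
    n_cds: int
    n_trna: int
    n_rrna: int
    size_cds: int
    size_trna: int
    size_rrna: int
    pct_cds: float
    pct_trna: float
    pct_rrna: float
    gc_overall: float
    gc_cds: float
    gc_trna: float
    gc_rrna: float
    gc_pos1: float
    gc_pos2: float
    gc_pos3: float
    extra: dict = field(default_factory=dict)


def _pct_gc(seq: str) -> float:
    if not seq:
        return float("nan")
    return round_percent(seq.count("G") + seq.count("C"), sum(seq.count(b) for b in "ACGT"))


def genome_summary(record: PlastomeRecord) -> GenomeSummary:
    """Compute the full characteristics row for one annotated record.

    Partition sizes are summed spliced exon lengths per gene class; GC per
    class is computed on the concatenated spliced sequences.
    """
    by_kind: dict[str, list[str]] = {"CDS": [], "tRNA": [], "rRNA": []}
    for name, feat in record.genes_by_name().items():
        by_kind[feat.kind].append(record.feature_sequence(feat))
    cds_cat = "".join(by_kind["CDS"])
    trna_cat = "".join(by_kind["tRNA"])
    rrna_cat = "".join(by_kind["rRNA"])
    n = len(record)
    coding = [r for r in extract_coding(record) if r.frame_ok]
    p1, p2, p3 = gc_by_codon_position(coding) if coding else (float("nan"),) * 3
    return GenomeSummary(
        record_id=record.id,
        organism=record.organism,
        length=n,
        n_genes=len(record.features),
        n_cds=len(by_kind["CDS"]),
        n_trna=len(by_kind["tRNA"]),
        n_rrna=len(by_kind["rRNA"]),
        size_cds=len(cds_cat),
        size_trna=len(trna_cat),
        size_rrna=len(rrna_cat),
        pct_cds=round_percent(len(cds_cat), n),
        pct_trna=round_percent(len(trna_cat), n),
        pct_rrna=round_percent(len(rrna_cat), n),
        gc_overall=_pct_gc(record.sequence),
        gc_cds=_pct_gc(cds_cat),
        gc_trna=_pct_gc(trna_cat),
        gc_rrna=_pct_gc(rrna_cat),
        gc_pos1=round(p1 * 100, 2) if p1 == p1 else p1,
        gc_pos2=round(p2 * 100, 2) if p2 == p2 else p2,
        gc_pos3=round(p3 * 100, 2) if p3 == p3 else p3,
    )
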