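"""Extraction of the three homologous region classes compared across species:
spliced coding sequences (exons), introns, and intergenic spacers (IGS).

IGS regions are defined between *gene extents* (leftmost to rightmost exon
coordinate, introns included) of adjacent genes in genome order, tRNA and
rRNA genes included.  IGS regions are unoriented (+ strand) and named
``upstream-downstream`` using genome order, e.g. ``rps12-clpP``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model import GeneFeature, Interval, PlastomeRecord

log = logging.getLogger(__name__)


@dataclass
class RegionSeq:
    """One extracted homologous region with provenance coordinates."""

    name: str
    category: str  # exon | intron | IGS
    interval: Interval
    sequence: str
    source_id: str
    frame_ok: bool = True  # False for a CDS whose length is not a codon multiple

    def __len__(self) -> int:
        return len(self.sequence)


def extract_coding(record: PlastomeRecord) -> list[RegionSeq]:
    """One spliced, strand-corrected region per protein-coding gene."""
    out = []
    for name, feat in record.genes_by_name().items():
        if feat.kind != "CDS":
            continue
        seq = record.feature_sequence(feat)
        frame_ok = len(seq) % 3 == 0
        if not frame_ok and not feat.pseudo:
            log.warning("CDS %s length %d not divisible by 3", name, len(seq))
        iv = Interval(feat.start, feat.end, feat.strand)
        out.append(RegionSeq(name, "exon", iv, seq, record.id, frame_ok))
    return out


def extract_introns(record: PlastomeRecord) -> list[RegionSeq]:
    """For each gene with k exons, the k-1 gaps between consecutive exons in
    genome orientation, named ``gene.intron1`` ... in transcript order."""
    out = []
    for name, feat in record.genes_by_name().items():
        exons = sorted(feat.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {name}: overlapping exons")
        n_int = len(exons) - 1
        for i in range(n_int):
            start, end = exons[i].end, exons[i + 1].start
            if end <= start:
                continue  # abutting exons: zero-length gap
            # transcript-order numbering: on the minus strand the last genomic
            # gap is intron 1
            idx = i + 1 if feat.strand == "+" else n_int - i
            iv = Interval(start, end, feat.strand)
            out.append(RegionSeq(f"{name}.intron{idx}", "intron", iv, record.slice(iv), record.id))
    return out


def gene_extents(record: PlastomeRecord) -> list[tuple[str, int, int]]:
    """(name, leftmost, rightmost) for every gene, sorted by leftmost."""
    return sorted(
        ((name, f.start, f.end) for name, f in record.genes_by_name().items()),
        key=lambda t: (t[1], t[2]),
    )


def extract_igs(record: PlastomeRecord) -> list[RegionSeq]:
    """Spacers between adjacent gene extents in genome order.

    On circular records the wrap-around spacer between the last and the first
    gene is included (marked ``wraps_origin`` when it crosses the origin).
    Zero- or negative-length spacers (overlapping or abutting genes) are
    omitted.
    """
    extents = gene_extents(record)
    if len(extents) < 2:
        log.warning("record %s has < 2 genes; no IGS extracted", record.id)
        return []
    out = []
    n = len(record)
    # sweep with a running rightmost end so a gene engulfed by its neighbour
    # cannot open a spacer inside the host
    right_name, right_end = extents[0][0], extents[0][2]
    for b_name, b_start, b_end in extents[1:]:
        if b_start > right_end:
            iv = Interval(right_end, b_start, "+")
            out.append(RegionSeq(f"{right_name}-{b_name}", "IGS", iv, record.slice(iv), record.id))
        if b_end > right_end:
            right_name, right_end = b_name, b_end
    if record.circular:
        # wrap-around spacer from the rightmost gene end back to the first gene
        first_name, first_start, _ = extents[0]
        start, end = right_end, first_start
        if start < n and end > 0:
            iv = Interval(start, end, "+", wraps_origin=True)
            out.append(RegionSeq(f"{right_name}-{first_name}", "IGS", iv, record.slice(iv), record.id))
        elif start < n:  # first gene starts at 0: spacer is the linear tail
            iv = Interval(start, n, "+")
            out.append(RegionSeq(f"{right_name}-{first_name}", "IGS", iv, record.slice(iv), record.id))
        elif end > 0:  # last gene ends at n: spacer is the linear head
            iv = Interval(0, end, "+")
            out.append(RegionSeq(f"{right_name}-{first_name}", "IGS", iv, record.slice(iv), record.id))
    return out


def extract_all(record: PlastomeRecord) -> dict[str, list[RegionSeq]]:
    """All three region classes keyed by category."""
    return {
        "exon": extract_coding(record),
        "intron": extract_introns(record),
        "IGS": extract_igs(record),
    }


def regions_by_name(regions: list[RegionSeq]) -> dict[str, RegionSeq]:
    out = {}
    for r in regions:
        if r.name in out:
            log.warning("duplicate region name %s in %s; keeping first", r.name, r.source_id)
            continue
        out[r.name] = r
    return out


def manifest_rows(regions: list[RegionSeq]) -> list[dict]:
    """TSV-ready manifest rows with 1-based inclusive coordinates."""
    rows = []
    for r in regions:
        s1, e1 = r.interval.to_one_based()
        rows.append(
            {
                "region": r.name,
                "category": r.category,
                "source": r.source_id,
                "start": s1,
                "end": e1,
                "length": len(r.sequence),
            }
        )
    return rows
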