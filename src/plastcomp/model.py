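"""Domain types and I/O for annotated plastome records.

A plastome is modelled as a (usually circular) DNA sequence plus a flat list
of gene features (CDS / tRNA / rRNA), each made of one or more exons.
Coordinates are 0-based half-open internally; report writers emit 1-based
inclusive positions to match the GenBank convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")

# complement map including N
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMP)[::-1]


class ParseError(ValueError):
    """Raised on malformed GenBank/FASTA input."""


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval.

    ``wraps_origin`` marks an interval crossing the origin of a circular
    genome; then ``end`` is taken modulo the genome length and ``end < start``.
    """

    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.wraps_origin and self.end <= self.start:
            raise ValueError(f"empty or inverted interval ({self.start}, {self.end})")

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("wrapping interval needs genome_length")
            return self.end - self.start + genome_length
        return self.end - self.start

    def to_one_based(self) -> tuple[int, int]:
        """(start, end) in the 1-based inclusive convention used in reports."""
        return self.start + 1, self.end

    def contains(self, pos: int, genome_length: int | None = None) -> bool:
        if self.wraps_origin:
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end


@dataclass
class GeneFeature:
    """One gene: named, typed, and split into ordered exons on one strand."""

    name: str
    kind: str  # CDS | tRNA | rRNA
    exons: list[Interval]
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("CDS", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.exons:
            raise ValueError(f"gene {self.name} has no exons")
        strands = {e.strand for e in self.exons}
        if len(strands) != 1:
            raise ValueError(f"gene {self.name} mixes strands")

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate over all exons."""
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate over all exons."""
        return max(e.end for e in self.exons)

    def total_exon_length(self) -> int:
        return sum(e.length() for e in self.exons)


@dataclass
class PlastomeRecord:
    """An annotated plastome: sequence + features."""

    id: str
    organism: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ParseError(f"record {self.id}: non-IUPAC characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, iv: Interval) -> str:
        """Genomic slice, reverse-complemented for the minus strand."""
        if iv.wraps_origin:
            s = self.sequence[iv.start :] + self.sequence[: iv.end]
        else:
            s = self.sequence[iv.start : iv.end]
        return revcomp(s) if iv.strand == "-" else s

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Spliced feature sequence in transcript (5'->3') orientation."""
        exons = sorted(feat.exons, key=lambda e: e.start)
        if feat.strand == "-":
            return "".join(revcomp(self.sequence[e.start : e.end]) for e in reversed(exons))
        return "".join(self.sequence[e.start : e.end] for e in exons)

    def genes_by_name(self) -> dict[str, GeneFeature]:
        """Map of disambiguated gene name -> feature.

        Duplicate names (multi-copy tRNAs) get a positional index suffix
        (".2", ".3", ...) in genome order so matrices can be joined.
        """
        out: dict[str, GeneFeature] = {}
        counts: dict[str, int] = {}
        for feat in sorted(self.features, key=lambda f: f.start):
            n = counts.get(feat.name, 0) + 1
            counts[feat.name] = n
            key = feat.name if n == 1 else f"{feat.name}.{n}"
            out[key] = feat
        return out


_TRNA_RE = re.compile(r"^trn(f?[A-Z])([-_]?([ACGTU]{3}))?$", re.IGNORECASE)


def normalize_gene_name(raw: str) -> str:
    """Case-fold a gene symbol to the community convention.

    Plastid gene names are three lowercase letters followed by an uppercase
    letter or a number (``rbcL``, ``psbA``, ``rpoC1``, ``ycf1``, ``rps12``);
    tRNAs keep their uppercase anticodon suffix (``trnI-CAU``). Names that do
    not fit the pattern pass through verbatim (logged).
    """
    name = raw.strip()
    if not name:
        raise ValueError("empty gene name")
    m = _TRNA_RE.match(name)
    if m:
        aa = m.group(1)
        aa = "fM" if aa.lower() == "fm" else aa.upper()
        out = f"trn{aa}"
        if m.group(3):
            out += "-" + m.group(3).upper()
        return out
    if len(name) >= 4 and name[:3].isalpha() and (name[3].isalpha() or name[3].isdigit()):
        return name[:3].lower() + name[3].upper() + name[4:]
    log.debug("gene name %r left verbatim (unrecognized pattern)", raw)
    return name


_KIND_BY_PREFIX = (("trn", "tRNA"), ("rrn", "rRNA"))


def _kind_from_name(name: str) -> str:
    for prefix, kind in _KIND_BY_PREFIX:
        if name.lower().startswith(prefix):
            return kind
    return "CDS"


def _exons_from_location(location, name: str) -> list[Interval]:
    try:
        parts = location.parts
        strand = "-" if location.strand == -1 else "+"
        exons = [Interval(int(p.start), int(p.end), strand) for p in parts]
    except Exception as exc:  # malformed location
        raise ParseError(f"feature {name}: malformed location {location}") from exc
    return sorted(exons, key=lambda e: e.start)


def read_genbank(path) -> PlastomeRecord:
    """Read a single-record GenBank flat file into a :class:`PlastomeRecord`.

    ``gene`` features and their CDS/tRNA/rRNA children are reconciled by
    normalized name; the typed child wins (it carries the exon structure).
    A bare ``gene`` with no typed child is kept, its kind inferred from the
    name prefix (trn -> tRNA, rrn -> rRNA, else CDS).
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise ParseError(f"{path}: expected a single GenBank record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise ParseError(f"{path}: missing sequence")
    circular = rec.annotations.get("topology", "circular") == "circular"
    organism = rec.annotations.get("organism", "")

    typed: dict[str, GeneFeature] = {}
    bare_genes: dict[str, GeneFeature] = {}
    order: list[str] = []

    def _key(name: str, start: int) -> str:
        # one gene may legitimately recur (multi-copy tRNAs); key on name+locus
        return f"{name}@{start}"

    for f in rec.features:
        if f.type not in ("CDS", "tRNA", "rRNA", "gene"):
            continue
        raw = (f.qualifiers.get("gene") or f.qualifiers.get("locus_tag") or ["?"])[0]
        name = normalize_gene_name(raw)
        pseudo = "pseudo" in f.qualifiers or "pseudogene" in f.qualifiers
        exons = _exons_from_location(f.location, name)
        if f.type == "gene":
            gf = GeneFeature(name, _kind_from_name(name), exons, pseudo)
            bare_genes[_key(name, gf.start)] = gf
        else:
            gf = GeneFeature(name, f.type, exons, pseudo)
            typed[_key(name, gf.start)] = gf
        k = _key(name, gf.start)
        if k not in order:
            order.append(k)

    features: list[GeneFeature] = []
    seen: set[str] = set()
    for k in order:
        if k in seen:
            continue
        seen.add(k)
        if k in typed:
            gf = typed[k]
            bg = bare_genes.get(k)
            if bg is not None and bg.pseudo:
                gf.pseudo = True
            features.append(gf)
        else:
            # a typed child may not share the gene's start (gene spans exons +
            # introns); match leftover bare genes to any typed feature by name
            bg = bare_genes[k]
            if any(t.name == bg.name and t.start >= bg.start and t.end <= bg.end for t in typed.values()):
                continue
            features.append(bg)

    n = len(seq)
    for gf in features:
        for e in gf.exons:
            if e.end > n:
                raise ParseError(f"feature {gf.name}: interval ({e.start},{e.end}) outside genome of length {n}")

    return PlastomeRecord(rec.id or rec.name, organism, seq, circular, features)


def write_genbank(record: PlastomeRecord, path) -> None:
    """Write a record back out as a GenBank flat file (round-trip partner of
    :func:`read_genbank`)."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id.split(".")[0][:16],
        description=record.organism,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.organism,
        },
    )
    for gf in sorted(record.features, key=lambda f: f.start):
        strand = -1 if gf.strand == "-" else 1
        locs = [FeatureLocation(e.start, e.end, strand) for e in sorted(gf.exons, key=lambda e: e.start)]
        if strand == -1:
            locs = locs[::-1]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [gf.name]}
        if gf.pseudo:
            quals["pseudo"] = [""]
        seqrec.features.append(SeqFeature(location, type="gene", qualifiers=dict(quals)))
        seqrec.features.append(SeqFeature(location, type=gf.kind, qualifiers=quals))
    SeqIO.write([seqrec], str(path), "genbank")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into ``[(id, uppercased sequence), ...]``."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ParseError(f"{path}:{rec.id}: non-IUPAC characters {sorted(bad)}")
        out.append((rec.id, seq))
    if not out:
        raise ParseError(f"{path}: empty FASTA file")
    return out


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write ``(id, sequence)`` pairs as 60-column FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
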