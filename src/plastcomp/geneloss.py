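"""Gene presence/absence matrices across plastomes, per-gene loss counts,
and monophyly of the loss pattern on a reference tree.

Pseudogene-flagged features count as absent: a non-functional copy is a loss
for comparative purposes.  A gene lost in every species is trivially
monophyletic (flagged as such).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import pandas as pd

from .model import PlastomeRecord, normalize_gene_name

log = logging.getLogger(__name__)

PRESENT, ABSENT = "+", "-"


@dataclass
class PresenceMatrix:
    species: list[str]
    genes: list[str]
    cells: dict[tuple[str, str], str] = field(default_factory=dict)  # (species, gene) -> +/-

    def is_present(self, species: str, gene: str) -> bool:
        return self.cells[(species, gene)] == PRESENT

    def absent_species(self, gene: str) -> list[str]:
        if gene not in self.genes:
            raise KeyError(f"gene {gene} not in matrix")
        return [sp for sp in self.species if not self.is_present(sp, gene)]

    def to_frame(self) -> pd.DataFrame:
        data = {g: [self.cells[(sp, g)] for sp in self.species] for g in self.genes}
        return pd.DataFrame(data, index=self.species)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PresenceMatrix":
        species = [str(s) for s in df.index]
        genes = [normalize_gene_name(str(g)) for g in df.columns]
        cells = {}
        for sp, row in zip(species, df.itertuples(index=False)):
            for gene, v in zip(genes, row):
                v = str(v).strip()
                # tolerate unicode minus / en-dash in transcribed tables
                cells[(sp, gene)] = PRESENT if v == "+" else ABSENT
        return cls(species, genes, cells)


def build_presence_matrix(
    records: list[PlastomeRecord], gene_panel: list[str] | None = None
) -> PresenceMatrix:
    """Presence = a non-pseudo feature with that normalized name exists.

    ``gene_panel`` defaults to the union of genes observed anywhere.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids")
    observed: dict[str, set[str]] = {}
    all_names: set[str] = set()
    for rec in records:
        observed[rec.id] = {f.name for f in rec.features if not f.pseudo}
        all_names |= {f.name for f in rec.features}
    if gene_panel is None:
        # union of everything observed, pseudogenes included (they are
        # columns too: a pseudo copy is an absence, not a missing column)
        panel = sorted(all_names)
    else:
        panel = [normalize_gene_name(g) for g in gene_panel]
    cells = {
        (sp, g): (PRESENT if g in observed[sp] else ABSENT) for sp in ids for g in panel
    }
    return PresenceMatrix(ids, panel, cells)


def loss_counts(matrix: PresenceMatrix) -> dict[str, int]:
    """Per-gene count of species lacking the gene (column-wise absences)."""
    return {g: len(matrix.absent_species(g)) for g in matrix.genes}


@dataclass
class MonophylyResult:
    monophyletic: bool
    exceptions: list[str]
    trivial: bool = False  # absent everywhere (or nowhere)


def _clades(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf-label sets under every node of the (arbitrarily rooted) tree;
    together with their complements these enumerate all bipartition sides."""
    out = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        out.append(leaves)
    return out


def loss_monophyly(tree: dendropy.Tree, matrix: PresenceMatrix, gene: str) -> MonophylyResult:
    """Is the set of species lacking ``gene`` exactly one side of one edge
    of the (unrooted) tree?

    If not, the reported exceptions are the smallest symmetric difference
    between the absent set and any bipartition side: species that would have
    to flip state for the loss to be clade-shaped.
    """
    absent = frozenset(matrix.absent_species(gene))
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    missing = set(matrix.species) - leaves
    if missing:
        raise ValueError(f"species absent from tree: {sorted(missing)}")
    if not absent or absent == frozenset(matrix.species):
        return MonophylyResult(True, [], trivial=True)
    best: tuple[int, list[str]] | None = None
    for clade in _clades(tree):
        for side in (clade, leaves - clade):
            side = side & frozenset(matrix.species)
            if side == absent:
                return MonophylyResult(True, [])
            diff = sorted(side ^ absent)
            if diff and (best is None or (len(diff), diff) < best):
                best = (len(diff), diff)
    return MonophylyResult(False, best[1] if best else [])


def load_irlc_matrix() -> PresenceMatrix:
    """The transcribed IRLC legume gene-loss survey (34 species x 9 genes)
    shipped with the package."""
    with resources.files("plastcomp.data").joinpath("irlc_gene_loss.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return PresenceMatrix.from_frame(df)
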