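"""Divergence-hotspot screening across species.

Homologous regions (matched by name) are aligned pairwise, Kimura
2-parameter distances are computed per region per species pair, and regions
whose maximum pairwise distance reaches mean + 2*SD of all defined values
are flagged as hotspots.

The K2p distance separates transitions (A<->G, C<->T; proportion P) from
transversions (proportion Q):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

computed over columns where both symbols are unambiguous bases (pairwise
deletion: gap or N columns are excluded).  The distance is undefined at
saturation, i.e. when 1 - 2P - Q <= 0 or 1 - 2Q <= 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio import Align

from .regions import RegionSeq

log = logging.getLogger(__name__)

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


@dataclass
class PairwiseAlignment:
    id_a: str
    id_b: str
    gapped_a: str
    gapped_b: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("aligned strings differ in length")


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # a gap of length L costs |gap_open| + L*|gap_extend|: the first gap
    # column carries the opening penalty on top of its extension
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def align_pair(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -2.0,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps; deterministic first-optimum
    traceback."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    return PairwiseAlignment(id_a, id_b, ga, gb, float(aln.score))


@dataclass
class K2pResult:
    P: float
    Q: float
    d: float
    n_sites: int
    defined: bool


def k2p(alignment: PairwiseAlignment | tuple[str, str]) -> K2pResult:
    """Kimura 2-parameter distance from one pairwise alignment."""
    if isinstance(alignment, PairwiseAlignment):
        ga, gb = alignment.gapped_a, alignment.gapped_b
    else:
        ga, gb = alignment
        if len(ga) != len(gb):
            raise ValueError("aligned strings differ in length")
    n_sites = ts = tv = 0
    for x, y in zip(ga.upper(), gb.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n_sites += 1
        if x == y:
            continue
        if {x, y} <= PURINES or {x, y} <= PYRIMIDINES:
            ts += 1
        else:
            tv += 1
    if n_sites == 0:
        log.warning("k2p: no comparable sites")
        return K2pResult(float("nan"), float("nan"), float("nan"), 0, False)
    P, Q = ts / n_sites, tv / n_sites
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return K2pResult(P, Q, float("nan"), n_sites, False)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2pResult(P, Q, d, n_sites, True)


@dataclass
class DistanceTable:
    """region name -> {(species_a, species_b) -> K2pResult}; pairs stored
    with sorted ids, so lookups are symmetric."""

    categories: dict[str, str] = field(default_factory=dict)
    cells: dict[str, dict[tuple[str, str], K2pResult]] = field(default_factory=dict)

    def add(self, region: str, category: str, a: str, b: str, result: K2pResult) -> None:
        key = tuple(sorted((a, b)))
        self.categories[region] = category
        self.cells.setdefault(region, {})[key] = result

    def get(self, region: str, a: str, b: str) -> K2pResult:
        return self.cells[region][tuple(sorted((a, b)))]

    def region_max(self, region: str) -> float:
        vals = [r.d for r in self.cells[region].values() if r.defined]
        return max(vals) if vals else float("nan")

    def defined_values(self, category: str | None = None) -> list[float]:
        out = []
        for region, pairs in self.cells.items():
            if category is not None and self.categories[region] != category:
                continue
            out.extend(r.d for r in pairs.values() if r.defined)
        return out

    def pair_range(self, a: str, b: str, category: str | None = None) -> tuple[float, float]:
        """(min, max) defined distance between one species pair."""
        key = tuple(sorted((a, b)))
        vals = [
            pairs[key].d
            for region, pairs in self.cells.items()
            if key in pairs and pairs[key].defined
            and (category is None or self.categories[region] == category)
        ]
        return (min(vals), max(vals)) if vals else (float("nan"), float("nan"))

    def rows(self) -> list[dict]:
        out = []
        for region in sorted(self.cells):
            for (a, b), r in sorted(self.cells[region].items()):
                out.append(
                    {
                        "region": region,
                        "category": self.categories[region],
                        "pair": f"{a}|{b}",
                        "P": r.P,
                        "Q": r.Q,
                        "d": r.d,
                        "n_sites": r.n_sites,
                        "defined": r.defined,
                    }
                )
        return out


def region_distance_table(
    regions_by_species: dict[str, list[RegionSeq]],
    prealigned: bool = False,
    **align_kwargs,
) -> DistanceTable:
    """K2p distance for every homologous region and species pair.

    Regions are matched across species by name; a region present in fewer
    than two species is skipped (logged).  ``prealigned=True`` treats the
    stored sequences as already aligned (equal length, gaps allowed) and
    bypasses the internal aligner.
    """
    if len(regions_by_species) < 2:
        raise ValueError("need at least two species")
    by_name: dict[str, dict[str, RegionSeq]] = {}
    for sp, regions in regions_by_species.items():
        for r in regions:
            by_name.setdefault(r.name, {})[sp] = r
    table = DistanceTable()
    for name, per_sp in sorted(by_name.items()):
        if len(per_sp) < 2:
            log.info("region %s present in only %d species; skipped", name, len(per_sp))
            continue
        category = next(iter(per_sp.values())).category
        for a, b in combinations(sorted(per_sp), 2):
            sa, sb = per_sp[a].sequence, per_sp[b].sequence
            if prealigned:
                aln = PairwiseAlignment(a, b, sa, sb)
            else:
                aln = align_pair(sa, sb, id_a=a, id_b=b, **align_kwargs)
            table.add(name, category, a, b, k2p(aln))
    return table


def hotspot_threshold(values) -> float:
    """mean + 2 * sample SD (n-1 denominator) of the pooled distances."""
    vals = np.asarray(list(values), dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("need at least two defined values for a threshold")
    return float(vals.mean() + 2.0 * vals.std(ddof=1))


def identify_hotspots(table: DistanceTable, threshold: float, category: str | None = "IGS") -> list[str]:
    """Regions whose maximum pairwise distance reaches the threshold,
    sorted by that maximum, descending."""
    hits = []
    for region in table.cells:
        if category is not None and table.categories[region] != category:
            continue
        mx = table.region_max(region)
        if mx == mx and mx >= threshold and mx > 0:
            hits.append((mx, region))
    hits.sort(key=lambda t: (-t[0], t[1]))
    return [r for _, r in hits]
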