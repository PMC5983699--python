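"""Perfect microsatellite (SSR) detection and genomic-context classification.

A tract is reported when a 1-6 nt motif repeats perfectly for at least the
class threshold number of units (defaults 8/4/4/3/3/3 for mono- through
hexa-nucleotide motifs).  Tracts are maximal, reported left to right under
their primitive period only (poly-A is a mono-nucleotide tract, never a
di-nucleotide "AA" tract), and a trailing partial unit is recorded as a
remainder rather than a unit.  On circular records the origin-spanning tract
is detected.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Interval, PlastomeRecord
from .regions import extract_all

DEFAULT_THRESHOLDS: dict[int, int] = {1: 8, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass
class SSRLocus:
    motif: str
    unit_len: int
    n_units: int
    remainder: int  # trailing partial-unit length (0..unit_len-1)
    interval: Interval
    region_category: str = "other"  # CDS | IGS | intron | other
    region_name: str = ""

    @property
    def tract_length(self) -> int:
        return self.unit_len * self.n_units + self.remainder


def is_primitive(motif: str) -> bool:
    """True unless the motif is an exact repetition of a shorter motif."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[: p] * (n // p):
            return False
    return True


def find_ssrs(
    sequence: str, thresholds: dict[int, int] | None = None
) -> list[SSRLocus]:
    """All maximal perfect SSR tracts meeting the unit-count thresholds.

    The scan compares each position with the one a period ``p`` earlier; a
    maximal run of agreements of length ``r`` is a tract of length ``r + p``.
    The tract is kept when its leading unit is primitive and ``(r + p) // p``
    reaches the threshold for ``p``.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    seq = sequence.upper()
    n = len(seq)
    out: list[SSRLocus] = []
    for p, min_units in sorted(thresholds.items()):
        i = p
        while i < n:
            # N never matches anything, so tracts cannot cross ambiguity
            if seq[i] != seq[i - p] or seq[i] == "N":
                i += 1
                continue
            run_start = i
            while i < n and seq[i] == seq[i - p] and seq[i] != "N":
                i += 1
            tract_start = run_start - p
            tract_len = i - tract_start
            motif = seq[tract_start : tract_start + p]
            n_units, rem = divmod(tract_len, p)
            if n_units >= min_units and is_primitive(motif) and "N" not in motif:
                out.append(
                    SSRLocus(motif, p, n_units, rem, Interval(tract_start, tract_start + tract_len))
                )
    out.sort(key=lambda l: (l.interval.start, l.unit_len))
    return out


def find_ssrs_circular(
    sequence: str, thresholds: dict[int, int] | None = None
) -> list[SSRLocus]:
    """SSR scan on a circular sequence: the origin-spanning tract is found by
    scanning the doubled sequence and mapping coordinates back."""
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    n = len(sequence)
    # extension cap: a tract longer than the genome is the degenerate
    # whole-circle repeat; scan one full copy plus a window
    window = min(n, 6 * max(200, max(thresholds.values()) * 6))
    doubled = sequence + sequence[:window]
    loci = []
    seen = set()
    for locus in find_ssrs(doubled, thresholds):
        start = locus.interval.start
        if start >= n:
            continue
        end = start + locus.tract_length
        if end - start > n:  # whole circle is one repeat; clip to genome
            end = start + n
        if end <= n:
            iv = Interval(start, end)
        else:
            iv = Interval(start, end - n, wraps_origin=True)
        key = (locus.motif, start % n)
        if key in seen:
            continue
        seen.add(key)
        loci.append(
            SSRLocus(locus.motif, locus.unit_len, (end - start) // locus.unit_len,
                     (end - start) % locus.unit_len, iv)
        )
    # drop linear-scan fragments that are sub-tracts of a wrapping tract
    wrapping = [l for l in loci if l.interval.wraps_origin]
    if wrapping:
        def _covered(l: SSRLocus) -> bool:
            for w in wrapping:
                if (
                    l.unit_len == w.unit_len
                    and (l.interval.start >= w.interval.start or l.interval.end <= w.interval.end)
                    and _same_phase(l, w, n)
                ):
                    return True
            return False

        loci = [l for l in loci if l.interval.wraps_origin or not _covered(l)]
    loci.sort(key=lambda l: (l.interval.start, l.unit_len))
    return loci


def _same_phase(l: SSRLocus, w: SSRLocus, n: int) -> bool:
    if l.unit_len != w.unit_len:
        return False
    shift = (l.interval.start - w.interval.start) % l.unit_len
    return l.motif == (w.motif[shift:] + w.motif[:shift])


def classify_ssrs(loci: list[SSRLocus], record: PlastomeRecord) -> list[SSRLocus]:
    """Label each locus with the region class containing its midpoint.

    Midpoints exactly on a boundary belong to the upstream region (regions
    are half-open, so containment itself encodes the tie rule).
    """
    n = len(record)
    regions = extract_all(record)
    labelled: list[tuple[str, str, Interval]] = []
    for cat_key, cat_label in (("exon", "CDS"), ("intron", "intron"), ("IGS", "IGS")):
        for r in regions[cat_key]:
            labelled.append((cat_label, r.name, r.interval))
    for locus in loci:
        start = locus.interval.start
        if not (0 <= start < n):
            raise ValueError(f"SSR locus at {start} outside genome of length {n}")
        mid = (start + locus.tract_length // 2) % n
        locus.region_category = "other"
        locus.region_name = ""
        for cat, name, iv in labelled:
            if iv.contains(mid):
                locus.region_category, locus.region_name = cat, name
                break
    return loci


def ssr_tallies(loci: list[SSRLocus]) -> dict[str, dict]:
    """Summary counts per unit length and per region class."""
    by_unit: dict[int, int] = {}
    by_region: dict[str, int] = {}
    by_motif: dict[str, int] = {}
    for l in loci:
        by_unit[l.unit_len] = by_unit.get(l.unit_len, 0) + 1
        by_region[l.region_category] = by_region.get(l.region_category, 0) + 1
        by_motif[l.motif] = by_motif.get(l.motif, 0) + 1
    return {"by_unit_length": by_unit, "by_region": by_region, "by_motif": by_motif}
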