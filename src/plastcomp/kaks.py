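"""Pairwise Ka/Ks by Nei-Gojobori (1986) counting with Jukes-Cantor
correction, under the plastid (bacterial) genetic code.

Synonymous/nonsynonymous *site* counts are fractional: each codon position
contributes the fraction of its three possible single-nucleotide changes
that preserve the amino acid (changes to stop codons count as
nonsynonymous).  For codons differing at several positions, substitution
counts are averaged over all minimal mutational pathways; pathways passing
through a stop codon are excluded when any stop-free pathway exists.
Proportions are corrected with k = -3/4 * ln(1 - 4p/3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

from .composition import STOP_CODONS, translate_codon
from .model import PlastomeRecord

log = logging.getLogger(__name__)


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon, summed
    over its 9 single-nucleotide neighbours."""
    if codon in STOP_CODONS or "N" in codon:
        raise ValueError(f"not a sense codon: {codon}")
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            neighbour = codon[:pos] + alt + codon[pos + 1 :]
            if neighbour not in STOP_CODONS and translate_codon(neighbour) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over minimal pathways."""
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_positions):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((through_stop, steps))
    usable = [steps for stop, steps in paths if not stop]
    if not usable:  # every route crosses a stop: fall back to all routes
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            # classify against the pre-step codon; stop intermediates (only
            # in the fallback) count as nonsynonymous
            if b not in STOP_CODONS and translate_codon(a) == translate_codon(b):
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return sd / k, nd / k


@dataclass
class KaKsResult:
    Ka: float
    Ks: float
    ratio: float  # nan when undefined (Ks == 0 or saturation)
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    n_codons: int
    defined: bool


def _jc_correct(p: float) -> float:
    if p == 0.0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return float("nan")
    return -0.75 * math.log(arg)


def ng86(codon_alignment: tuple[str, str]) -> KaKsResult:
    """NG86 Ka/Ks for one gapless codon-aligned CDS pair.

    Codon pairs where either member contains N or is a stop codon are
    excluded pairwise; a trailing shared stop codon is simply skipped.
    """
    seq_a, seq_b = (s.upper() for s in codon_alignment)
    if len(seq_a) != len(seq_b):
        raise ValueError("codon alignment members differ in length")
    if len(seq_a) % 3 != 0:
        raise ValueError("alignment length not divisible by 3")
    if "-" in seq_a or "-" in seq_b:
        raise ValueError("ng86 expects a gapless codon alignment")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if "N" in ca or "N" in cb or ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        n_codons += 1
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds, dn = _pathway_counts(ca, cb)
        Sd += ds
        Nd += dn
    if n_codons == 0:
        return KaKsResult(*(float("nan"),) * 3, 0.0, 0.0, 0.0, 0.0, 0, False)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jc_correct(pS)
    Ka = _jc_correct(pN)
    saturated = Ks != Ks or Ka != Ka
    if saturated:
        log.warning("ng86: saturated proportions (pS=%.3f, pN=%.3f)", pS, pN)
        return KaKsResult(Ka, Ks, float("nan"), N, S, Nd, Sd, n_codons, False)
    if Ks == 0.0:
        # 0/0 and x/0 are reported as nan with the defined flag set to the
        # informative case: identical sequences are flagged undefined
        ratio = float("nan")
        return KaKsResult(Ka, Ks, ratio, N, S, Nd, Sd, n_codons, False)
    return KaKsResult(Ka, Ks, Ka / Ks, N, S, Nd, Sd, n_codons, True)


def gene_screen(
    records: list[PlastomeRecord], gene_names: list[str] | None = None
) -> list[dict]:
    """Per-gene pairwise Ka/Ks table, ranked by ratio (descending; undefined
    ratios sink to the bottom).

    CDS sequences are matched across records by gene name; genes missing or
    length-mismatched in a pair are skipped with a log note.  Sequences come
    from the annotation, so for real data they should already be codon-aligned
    (the simulator emits indel-free CDSs, which always are).
    """
    from itertools import combinations

    by_record: dict[str, dict[str, str]] = {}
    for rec in records:
        cds = {}
        for name, feat in rec.genes_by_name().items():
            if feat.kind == "CDS" and not feat.pseudo:
                cds[name] = rec.feature_sequence(feat)
        by_record[rec.id] = cds
    if gene_names is None:
        gene_names = sorted(set().union(*(set(c) for c in by_record.values())))
    rows = []
    for gene in gene_names:
        for a, b in combinations(sorted(by_record), 2):
            sa, sb = by_record[a].get(gene), by_record[b].get(gene)
            if sa is None or sb is None:
                log.info("gene %s missing in %s; skipped", gene, a if sa is None else b)
                continue
            if len(sa) != len(sb):
                log.info("gene %s length mismatch between %s and %s; skipped", gene, a, b)
                continue
            res = ng86((sa, sb))
            rows.append(
                {
                    "gene": gene,
                    "pair": f"{a}|{b}",
                    "Ka": res.Ka,
                    "Ks": res.Ks,
                    "ratio": res.ratio,
                    "Nd": res.Nd,
                    "Sd": res.Sd,
                    "N_sites": res.N_sites,
                    "S_sites": res.S_sites,
                    "defined": res.defined,
                }
            )
    rows.sort(key=lambda r: (-(r["ratio"] if r["ratio"] == r["ratio"] else -math.inf), r["gene"]))
    return rows
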