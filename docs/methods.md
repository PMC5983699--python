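# Methods

`plastcomp` re-implements, as a tested library, the standard comparative
workflow for small plastid genomes: extract homologous regions from
annotated records, account for composition, detect repeats, screen
non-coding regions for divergence hotspots, tabulate gene losses, build a
distance phylogeny, and rank protein-coding genes by a pairwise Ka/Ks
screen. This note records the models, the parameter choices, and the
numerical conventions, including where a convention had to be chosen
because the field's tools disagree.

## Coordinates and record model

Coordinates are 0-based half-open internally; every report emits 1-based
inclusive positions to match the GenBank convention. Sequences are
uppercased on ingest; `N` is tolerated but excluded from GC and distance
denominators. A record is a circular DNA sequence plus a flat list of gene
features (CDS, tRNA, rRNA), each an ordered list of exons on one strand.
`gene` features without a typed child are kept with the kind inferred from
the name prefix (`trn` → tRNA, `rrn` → rRNA, otherwise CDS), because real
GenBank submissions are inconsistent about feature nesting. Multi-copy
tRNAs are disambiguated with a positional suffix (`trnM-CAU.2`) so
presence/absence matrices can be joined by name.

## Region classes

Three homologous region classes drive the comparisons:

- **exon** — the spliced, strand-corrected coding sequence of one
  protein-coding gene (one region per gene, not per exon piece);
- **intron** — the gap between consecutive exons in genome orientation,
  numbered in transcript order (`gene.intron1` …);
- **IGS** — the spacer between adjacent *gene extents* (leftmost to
  rightmost exon coordinate, introns included), tRNA/rRNA genes included,
  named `upstream-downstream` in genome order (`rps12-clpP` style).

IGS regions are unoriented (+ strand). A sweep keeps a running rightmost
end so a gene engulfed by another cannot open a spacer inside its host;
zero-length spacers from overlapping or abutting genes are dropped. On
circular records the wrap-around spacer between the last and first gene is
emitted. On any record without overlapping features the three classes plus
the tRNA/rRNA genes tile the genome exactly — this is asserted in the
tests.

Across species, homologous regions are matched by normalized name
equality; a region present in fewer than two species is skipped with a
log note. Synteny-aware matching is deliberately out of scope.

## Composition

GC content is (G+C)/(A+C+G+T). Codon statistics use the bacterial/plastid
genetic code (NCBI table 11). Two denominator conventions matter and are
fixed as follows: amino-acid usage percentages divide by the total codon
count *including stop codons*, and gene-class size percentages divide by
total genome length. Reported percentages are rounded half-up to two
decimals, and each reported percentage recomputes exactly from its
numerator/denominator pair.

## SSR detection

Perfect microsatellites only: a tract is reported when a primitive 1–6 nt
motif repeats at least 8/4/4/3/3/3 times (mono- through hexa-nucleotide).
Tracts are maximal, a trailing partial unit is recorded as a remainder
rather than a unit, and a tract is reported only under its primitive
period (a poly-A run is never also an "AA" tract). The motif is the
tract's leading unit, not canonicalized across rotations or strands, so AT
and TA both occur — this matches common reporting. Origin-spanning tracts
on circular records are found by scanning the doubled sequence and mapping
back. Genomic context is assigned by the region containing the tract
midpoint; with half-open regions the boundary tie resolves upstream.

Compound/interrupted SSRs are not merged. The widely used microsatellite
finders can merge nearby tracts, so absolute SSR counts from those tools
are comparable only approximately; the detector here is instead exactly
reproducible and is verified against a brute-force enumeration over every
(start, period) pair on random sequences.

## Dispersed repeats

Forward and palindromic repeat pairs with length ≥ 30, Hamming distance
≤ 3 (mismatches only, no indels) and identity ≥ 90%. A pair lives on one
alignment diagonal — the genome against itself at a positive offset
(forward) or against its reverse complement (palindromic). Reported pairs
are maximal (extension in either direction would exceed the mismatch
budget or run off the sequence) and trimmed so they start and end on a
match; pairs whose both copies lie inside another pair's copies are
removed, mirroring the usual manual removal of nested/redundant hits.

The production path seeds on shared k-mers (k = ⌊(30−3)/4⌋, guaranteed by
pigeonhole to hit every qualifying pair) and enumerates the maximal
mismatch-bounded windows around each seed; an `exhaustive=True` path scans
every diagonal directly and serves as the in-package oracle for tests.

## Tandem repeats

A deterministic offset-scoring scan rather than a probabilistic model:
for each period p ≤ 500, each position scores +2 when it equals the base
one period earlier and −7 otherwise; maximal scoring segments (Ruzzo–Tompa
decomposition, after a vectorized Kadane bound discards hopeless periods)
with score ≥ 50 become tracts spanning one leading period plus the scored
segment. Overlapping calls across periods keep the highest score (ties:
smaller period, then leftmost). The 2/7/50/500 parameter set mirrors the
common tandem-finder settings (match 2, mismatch and indel penalty 7,
minimum score 50, maximum period 500); because this scan is indel-free the
indel penalty never fires, and scores are reproducible by hand (e.g. ten
exact copies of a 4-mer score 2 × 36 = 72).

## Divergence hotspots (K2p screen)

Homologous regions are aligned pairwise by global affine-gap alignment
(match +1, mismatch −1, gap of length L costs 10 + 2L, mirroring the
classic gap-open 10 / gap-extend 2 setting). Pairwise alignment replaces
progressive multiple alignment because only pairwise distances are
consumed; this is the main known source of discrepancy against numbers
produced with a multiple aligner. Pre-aligned input can bypass the
internal aligner.

The Kimura 2-parameter distance is computed with pairwise deletion
(columns with a gap or N excluded): P = transitions / sites,
Q = transversions / sites,

    d = −½ · ln((1 − 2P − Q) · √(1 − 2Q)),

undefined (flagged, excluded from pooling) when 1−2P−Q ≤ 0 or 1−2Q ≤ 0.

The hotspot threshold is mean + 2 × SD over all defined IGS distances
across all species pairs; the sample SD (n−1) is used — the population/
sample choice is not standardized in this kind of screen, and the
difference is far below the screen's resolution. Introns are screened with
the same machinery but do not enter the IGS threshold pool. A region is a
hotspot when its maximum pairwise distance reaches the threshold.

## Gene loss and monophyly

Presence means a non-pseudo feature with the normalized name exists;
pseudogene-flagged copies count as losses, since a non-functional copy is
a loss for comparative purposes. Loss counts are column sums of the
presence/absence matrix. A 34-species legume (IRLC) survey matrix for nine
frequently lost genes ships as a packaged TSV fixture, transcribed from
the published literature, and its column sums are pinned in the tests.

A loss pattern is monophyletic when the absent-species set is exactly one
side of one edge of the unrooted reference tree (so the check is invariant
to rooting). Genes absent everywhere (or nowhere) are trivially
monophyletic and flagged as such. When the pattern is not clade-shaped,
the reported exceptions are the smallest symmetric difference between the
absent set and any bipartition side — the species that would have to flip
state.

## Phylogeny

Likelihood inference is deliberately replaced by neighbor joining on
p-distances over concatenated shared loci: the downstream question is
clade recovery, not branch lengths or rates, and NJ is exact on additive
matrices (verified against randomly generated additive trees up to eight
taxa). Tie-breaking picks the lowest-index pair; negative branch lengths
are clamped to zero with the deficit moved to the sibling edge. Bootstrap
support resamples alignment columns with replacement, rebuilds the NJ tree
per replicate, and maps bipartition frequencies onto the reference tree;
it is reproducible under a fixed seed.

## Ka/Ks screen

Nei–Gojobori (1986) pathway counting with Jukes–Cantor correction, under
the plastid code. Site counts are fractional over the nine
single-nucleotide neighbours of each codon, with changes to stop codons
counted as nonsynonymous (so sites per codon always sum to 3);
multi-difference codons average over all minimal pathways, excluding
pathways through stop codons whenever a stop-free pathway exists. Codons
containing N, or a stop in either sequence, are excluded pairwise.
Identical sequences yield Ka = Ks = 0 with an undefined (0/0) ratio;
saturation (4p/3 ≥ 1) is flagged undefined. Branch-site likelihood models
are out of scope: the screen is a deterministic ranking proxy, and its
acceptance surface is that genes simulated with a nonsynonymous excess
rank above neutral and synonymous-only genes.

## Synthetic data generator

The generator emulates a desk-scale version of a four-species plastome
study: a circular genome assembled gene-by-gene with intergenic spacers,
evolved along a given tree. What it reproduces, and what it does not:

- **Genome structure.** Default 30 genes (27 CDS with valid ORFs under the
  plastid code, two tRNAs, one rRNA), three intron-containing genes (the
  first with two introns), mean CDS length 600 bp and mean spacer 250 bp —
  roughly a fifth of real plastome scale, chosen so a full pipeline run
  stays in seconds while every code path (multi-exon, minus-strand,
  wrap-around spacer) is exercised. Base composition is AT-rich (65% AT),
  as in real plastomes.
- **Substitution model.** Two-class (transition/transversion) with rate
  ratio κ = 2, single hit per site per branch, no indels — so the
  positional alignment of any region across taxa is the identity, and
  realized transition/transversion counts logged per branch per region
  are exactly recoverable by diffing. Branch lengths are in expected
  substitutions per site (base rate 1.0).
- **Hotspots.** Two spacers carry a 10× rate multiplier; with ~0.1
  substitutions/site between the most distant taxa this yields boosted
  distances in the 0.4–0.8 range, comparable to the upper end of real
  intergenic divergence, while the background stays below ~0.1.
- **Planted repeats.** Ten SSRs spanning all six motif classes at or above
  their thresholds, and three dispersed repeat pairs (two forward, one
  palindromic, 32–40 bp). Planted elements are flanked by deliberate
  mismatch breakers (four consecutive forced mismatches on the repeat-pair
  diagonals, single breaker bases for SSR tracts) and excluded from
  substitution, so truth coordinates are exact per taxon.
- **Gene losses.** Feature *and* sequence deletion (the flanking spacers
  fuse, as in real loss), applied per taxon; default two losses.
- **Selection toggle.** Per-gene modes: neutral, synonymous-only
  (nonsynonymous proposals rejected), or positive (synonymous proposals
  thinned to one third) — enough to give the Ka/Ks screen a planted
  ranking, not a calibrated ω.

What passing tests on this generator show: the detectors report exactly
what is in the sequence, the screen's statistics behave as derived, and
the pipeline wiring is correct. What they do not show: robustness to
annotation noise, rearrangements, indel-rich alignment, IR boundary
dynamics, or the conventions of specific external tools (compound SSRs,
repeat maximality variants) — absolute counts from those tools are
reproduced only approximately.

## Numerical conventions and degenerate inputs

- Percent rounding: half-up, two decimals, `decimal`-based (no binary
  drift).
- All-N or empty partitions: GC flagged NaN rather than zero.
- K2p with zero comparable sites, saturated proportions, or fewer than two
  pooled values: flagged/undefined, never silently coerced.
- Alignment tie-breaking: the first optimum of the deterministic aligner;
  scores verified against exhaustive enumeration on short inputs.
- All randomness flows from explicit integer seeds (NumPy `default_rng`);
  the simulator is byte-reproducible per seed.

## Problem sizes used in the checked runs

The test suite and the acceptance script size their simulations to keep a
single-CPU run short while leaving the statistical assertions
well-powered: detector-vs-oracle comparisons use dozens of random
sequences of 0.2–2 kb; the K2p estimator check uses 200 replicates of
10,000 sites; clade bootstrap uses 200 replicates over ~17 kb of
concatenated coding sequence from a six-taxon simulation; the full
pipeline recovery runs on the default four-taxon configuration.
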