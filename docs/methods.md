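# Methods

## The design problem

A paralogue ratio test needs a primer pair with an unusual specificity
profile: perfect annealing at exactly two genomic loci (target and
reference) and as little near-perfect annealing elsewhere as possible. In
a typical genomic interval, most primer pairs amplify either one product
(unique sequence) or many (high-copy repeats); the useful two-copy cases
are rare and concentrated in diverged duplications. `prtdesign` therefore
generates a very large candidate set and filters, rather than trying to
predict suitable loci from annotation.

## Candidate generation

**Windowing.** The target region is tiled with windows of
`window_length` (default 2000 bp) overlapping by `overlap` (default
300 bp). If the final window would overrun the region it is re-anchored
to end exactly at the region boundary; regions shorter than one window
become a single window. Windowing exists to spread candidates: a single
global optimisation would put the entire quota on the few positions with
the best thermodynamics.

**Enumeration.** Within a window, every oligo of length 15–35 nt whose
footprint avoids masked positions and Ns is a potential primer. An oligo
is *admissible* in a given round if its length, melting temperature and
GC fraction fall in the current bands and it passes a 3' self-dimer
screen (rejected if the reverse complement of its 3'-terminal 8-mer
occurs anywhere in the oligo). For each anchor position (forward primers
anchored by start, reverse primers by end) the single best admissible
oligo is kept, scored by `|Tm − Tm_opt| + 0.5·|len − len_opt|`. Pairs are
all (fwd_start, rev_end) anchor combinations with product size inside
`amplicon_size_range` (default 100–300 bp) and non-overlapping
footprints.

**Emission order.** The quota (`ppn` × window length, default 2 pairs
per nucleotide) is far below the number of admissible pairs, so the
emission order decides what the downstream search sees. Globally
penalty-sorted emission concentrates output on a handful of positions;
instead, (fwd_start, rev_end) space is stratified into 16 bp × 16 bp
cells and pairs are emitted round-robin across cells, penalty-best first
within each cell, ties broken by coordinates. This approximates uniform
sampling over amplicon placements while keeping local thermodynamic
quality, and makes recovery of any particular designable locus
insensitive to where the window's globally best primers happen to sit.

**Relaxation.** If a round cannot fill the quota, the bands widen by
fixed decrements per round (Tm ±1 °C, GC ∓5 points, length ±1 nt, with
hard limits 15/35 nt and 0/100 % GC; default 5 rounds), and the scan
repeats, emitting only pairs not seen before (keyed by both footprints).
Pairs record the round that produced them.

**Melting temperature.** Unified nearest-neighbor model with the
SantaLucia–Hicks 2004 parameter set, 50 mM monovalent salt (entropic
correction 0.368·(N−1)·ln[Na+]) and 50 nM oligo concentration,
implemented vectorized so every candidate in a window is scored at once.
Only relative ordering and band membership matter downstream; the test
suite cross-checks absolute values against an independent implementation
of the same parameter set (agreement well inside 0.5 °C).

## In-silico PCR

A genomic footprint is a priming site for an oligo iff its 3'-terminal
`min_perfect` bases match the template perfectly (extension requires an
annealed 3' end) and total substitutions are ≤ `max_mismatch` (default 6
per primer; indels are not modeled, matching how short-oligo annealing is
usually treated). Both strands are searched.

Two seeding modes trade completeness for speed:

* **default** (tile 11, stride 5, min_perfect 15): candidate footprints
  come from index tiles shared verbatim between oligo and genome. Any
  exact site of an oligo ≥ tile+stride−1 = 15 nt necessarily contains an
  indexed tile, so exact sites are always found; mismatched (mispriming)
  sites are found when a shared tile survives, i.e. a subset of the truth.
* **sensitive** (stride 1, min_perfect 5): candidates are all exact
  genomic occurrences of the oligo's 3'-terminal 5-mer. Every qualifying
  site must contain that exact 5-mer at that offset, so this search is
  *exhaustive* — the suite asserts equality with a naive every-offset
  scan. It is the mode for a complete mispriming census, at roughly
  10× the cost.

Products are all (plus-strand site, downstream minus-strand site)
combinations on one chromosome within `max_product_size` (default
4000 bp), in both pair orientations. Match quality is
`score = round(1000·(1 − mismatches/primer_bases))`, anchored so 4
mismatches over a 40-base pair scores exactly 900; the **Misprime**
column counts non-exact products scoring > 900. A single-primer check
(same oligo priming both strands at two distinct, non-overlapping,
inverted sites) is available as an optional post-filter
(`single_primer_check`), as used for pre-computed assay databases.

## Selection and filtering

Standard mode accepts a pair iff its exact products number exactly two,
with exactly one inside the queried target region (containment); the
other becomes the reference. Multi-target mode (targets present 2–4
times per haploid genome) requires one exact product per specified
target interval plus one outside all of them with a product size
different from every target product.

Filters, each with a machine-readable rejection reason: size difference
within `[min_size_diff, max_size_diff]` (default ≥ 2 bp; 0 permitted for
RFLP/probe designs), reference product size bounds, distance rule (a
same-chromosome reference must be ≥ `min_distance` = 500 kb from the
target, so the reference cannot sit inside the CNV; different
chromosomes always pass), and `misprime ≤ max_misprime` (default 2,
i.e. fewer than three >900-score products — the threshold that separated
laboratory-successful from failed assays). Annotation adds CNV/indel
overlap flags per amplicon (any-overlap semantics — conservative for the
reference-avoidance use case) and per-primer SNP counts; FSNP/RSNP
report the maximum over the two loci for each primer. Identical oligo
pairs re-designed by overlapping windows are deduplicated, keeping the
first in genomic order.

## Storage and outputs

Matches stream into a single-file SQLite store keyed by
(pair, chromosome, start, end), which bounds memory independently of
stream size and makes re-ingestion idempotent. Per pair the store serves
the first five exact matches *in genome order* (so output is independent
of search parallelism), the total exact count, and the >900 census;
two-exact pairs are extracted without a full scan. Outputs: a 12-column
TSV report (two lines per assay, target then reference, 1-based
inclusive coordinates), a BED6 browser track (0-based, `/T` and `/R`
name suffixes), a rejection audit TSV, cluster/coverage statistics, and
a manifest with a digest of the full configuration — two runs with the
same manifest are byte-identical, for any worker count.

## Statistics

Accepted assays cluster into runs of mutually overlapping target
amplicons. `cluster_targets` single-linkage-merges overlapping or
touching intervals; gap lists are per chromosome. `window_coverage`
tiles chromosomes with fixed windows anchored at 0 (final partial tile
counts) and reports the fraction containing any part of a cluster.
`feature_tagging` reports, per proximity threshold, the fraction of
features (genes, CNVs) with an assay overlapping (d = 0) or within d bp.

## Synthetic fixtures: what they emulate and what they do not

The generator plants structure in i.i.d. background sequence of
configurable GC:

* **Segment families** — a core (flank + interior + flank) copied to
  1–k loci. Flanks (default 60 bp) are copied verbatim and model the
  conserved primer sites of a *designable* paralogue locus: they are
  drawn at balanced GC (0.55) and rejection-sampled until ≥ 8 anchor
  positions carry an oligo with Tm inside the default design band — a
  locus whose flanks cannot hold primers would never yield an assay and
  is not what the plant represents. Interiors diverge at a 30 %
  substitution rate with the flank-adjacent interior bases always
  substituted, so the region identical between copies is exactly the
  engineered flank and the truth table's copy counts are what the
  in-silico PCR sees. Per-copy `interior_delta` inserts/deletes bases at
  the interior midpoint, so copies differ in length by exactly that
  amount. Setting `flank_substitution_rate` on a copy breaks its primer
  sites — the negative control.
* **Repeat families, STRs, SNPs** — dispersed diverged repeat units
  (Alu-like) and tandem runs with matching mask tracks; SNP positions as
  a length-1 track.
* **Extra copies** — tandem appends of a region on a decoy chromosome
  with recorded truth copy number (a trisomy-like ground truth).

Everything is deterministic under the spec seed, and plants may not
overlap. Not emulated: realistic repeat families and their genomic
distribution, GC heterogeneity and higher-order composition, indel
polymorphism between copies (outside the engineered midpoint delta), and
sequencing-era reference artefacts. Passing tests therefore show the
*method* is correct and self-consistent on designable loci; they do not
predict wet-lab conversion rates on a real genome.

## Problem sizes used in validation

The suite and `scripts/acceptance.py` run at sizes a laptop core handles
in seconds per case, chosen as the smallest sizes at which every
behaviour under test is non-trivial: oracle-equivalence on 20 random
genomes of 20 kb; copy-number selectivity on a 330 kb multi-chromosome
fixture (copy numbers 1, 2, 3, 5); end-to-end planted recovery on a 1 Mb
chromosome with the paralogue copies 600 kb apart (satisfying the 500 kb
distance rule on one chromosome); determinism on a 120 kb fixture.
Recovery was additionally checked across 15 generator seeds (13–65
recovering assays per seed, none failing).

## Known limitations

* Substitution-only priming model; no gapped alignment or ΔG-based
  duplex thermodynamics, no hairpin/heterodimer screening beyond the 3'
  self-dimer rule.
* Default-mode mispriming counts are a lower bound by construction; use
  sensitive mode for a complete census.
* One best oligo per anchor position per relaxation round: two distinct
  admissible oligos sharing an anchor can only both appear via later
  rounds.
* The distance rule uses the gap between amplicons as a proxy for "not
  inside the same CNV"; it cannot know true CNV boundaries.
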