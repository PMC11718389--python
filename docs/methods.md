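# Methods

## Coordinate and data conventions

All internal coordinates are 0-based half-open; BED exports keep that
convention, human-readable TSV exports are 1-based inclusive and say so in
their header. A genome is a set of named chromosome-copy sequences
(haplotype-resolved polyploid assemblies have one record per homologous
copy) plus an explicit homolog-group mapping; grouping is never parsed from
record names. Probe design runs on each group's *design copy* — the longest
assembled copy, ties broken by lexicographic copy id. N bases are allowed in
genomes; no oligo may contain one.

## Single-copy specificity screen

Candidates are l-bp windows (default 45) tiled at an s-bp step (default 5).
Composition filters (GC within [0.30, 0.70], no homopolymer run of 8+, no
N) flag candidates rather than dropping them, so tiling arithmetic stays
auditable. Screening labels each candidate:

* **REPETITIVE** — some constituent k-mer (default k = 17) occurs more than
  `max_kmer_genome_count` times genome-wide, both strands counted. The
  default cutoff is (largest homolog group size) + 1: an autotetraploid
  single-copy locus legitimately appears once per homologous copy, so four
  hits plus one spare are tolerated.
* **CROSS_HYBRIDIZING** — an ungapped, full-length alignment with identity
  at or above `homology_pct` (default 75%) exists at some offset of some
  copy outside the candidate's own homolog group, on either strand.
* **SINGLE_COPY** — neither.

The cross-hybridization test is an **exact scan**: every offset of every
disallowed copy is evaluated on both strands. Vectorization batches the
probes (one-hot encoding; match counts computed as integer-valued float32
matrix products, exact for l ≤ 45). We deliberately did not use a
seed-and-extend shortcut: with 75% identity over 45 bp an alignment may
contain up to 11 mismatches and is not guaranteed to share any exact run
longer than 3 bp, so any practical seed length loses sensitivity, and the
screen's defining property here is that it is reproducible and
independently checkable against a brute-force oracle. Gapped
cross-hybridization, melting-temperature modeling and secondary structure
are out of scope. The test suite cross-checks the scan against an
independent oracle implemented by per-channel cross-correlation.

Thinning to a per-region oligo target places ideal positions at the centers
of equal slices of the occupied span and greedily picks the nearest unused
oligo (ties leftmost), preserving order and forbidding overlap beyond
l − step. On a uniform tiling this reduces to exact regular subsampling.

## Barcode planning

Mark counts per chromosome are 2 (both terminal) or 3 (terminal + one
interstitial). The default rule gives the shortest 3/8 of chromosomes two
marks (rounded; a single-chromosome genome falls to the majority class of
3), and an explicit per-chromosome map overrides the rule entirely — the
published alfalfa short set {1, 2, 5} does not strictly follow assembled
length, so the choice is configuration, not inference.

Terminal regions are anchored exactly at positions 0 and chromosome end
and grown inward from `min_region_bp` in `grow_step` increments (default
100 kb) until they hold `n_target` single-copy oligos or reach
`max_region_bp` (a shortfall is accepted with a warning). The interstitial
region scans a placement grid constrained by a start-to-start separation
floor from both terminals and takes the placement retaining the most
single-copy oligos (ties prefer the chromosome midpoint, then the leftmost
grid point), then grows around that window. Placement therefore follows
oligo availability, not geometry — which is also why a realized layout can
have an off-center interstitial mark. The separation constraint is
interpreted start-to-start: in the published alfalfa table the end-to-start
gaps fall below 35.8 Mb while the minimum start-to-start distance is
exactly 35 831 680 bp, matching the printed "at least 35.8 Mb".

### Two-color signature assignment

A chromosome's signature is its ordered (position-class, color) tuple.
Because metaphase chromosomes of a uniform metacentric karyotype carry no
intrinsic orientation, two signatures are considered equal if one is the
reversed (terminal-left/terminal-right swapped) image of the other.
Chromosomes with different position profiles can never collide, so the
search decomposes by profile group; within a group the distinct
reversal-equivalence classes are enumerated exhaustively (2-mark layouts
have 3 classes, 3-mark layouts 6) and assigned greedily in lexicographic
order, which yields the lexicographically smallest valid assignment
deterministically. Infeasibility is certified by pigeonhole: a group with
more chromosomes than classes is reported with the colliding chromosomes
and the class count (e.g. four 2-mark chromosomes with two colors).

Painting probes are the full single-copy set of a chromosome, unthinned;
an optional density cap exists for synthesis-cost control but is off by
default.

## Karyotype and aberration calling

Arm tables (long arm L, short arm S per chromosome, units arbitrary but
consistent within a complement) yield tl = L + S, AR = L/S and
RL = tl/TL × 100 with TL the complement total, so RL sums to 100 exactly.
Rows with L < S are swapped with a warning. Arm-ratio classes follow the
Levan convention with the boundary value assigned leftward: m (≤ 1.7),
sm (≤ 3.0), st (≤ 7.0), t (> 7.0).

Aberration calling classifies each metaphase cell independently and takes
a strict per-seed majority across cells (ties → AMBIGUOUS; the aggregation
rule across a seed's cells is our choice, as screening studies rarely
state one):

* **EUPLOID** — every chromosome shows `ploidy` barcode clusters and the
  DAPI total equals complement × ploidy.
* **ANEUPLOID ± chrN** — exactly one chromosome deviates by ±1 barcode
  cluster *and* the DAPI total corroborates (e.g. 33 instead of 32 for a
  gain in a tetraploid 8-chromosome complement).
* **SEGMENT_DELETION(chrN)** — one chromosome lost a barcode cluster while
  its painting-probe count is intact at `ploidy`. Painting confirmation is
  required: a barcode loss with a full DAPI complement but no painting data
  stays AMBIGUOUS, because a single miscounted spread produces the same
  pattern. This is what makes the caller degrade gracefully under count
  noise instead of inventing confident aberrations.
* **AMBIGUOUS** otherwise, with an evidence code naming the reason.

Variant frequencies are reported as percentages (2 dp) with Wilson 95%
confidence intervals (statsmodels).

## Homolog divergence

Two homologous copies are aligned by unique-k-mer anchors (k = 21, k-mers
occurring exactly once in each sequence), chained by longest increasing
subsequence on both coordinates and merged into maximal exact-match
blocks; overlapping blocks are trimmed deterministically. This replaces a
whole-genome aligner plus rearrangement typer at desk scale: the analysis
needs only SNP/InDel/PAV length-class totals, and inversions/translocations
are deliberately not typed (unchainable diverged blocks fall into PAV via
the identity rule below).

Inter-block gaps are classified:

* equal-length gaps → positional comparison emits SNPs, except blocks
  longer than 200 bp with identity below 75%, which are PAV (replacement of
  homologous sequence, not point divergence);
* unequal-length gaps → one net-length event: 1–200 bp is an InDel,
  201+ bp a PAV (the boundary semantics are fixed: exactly 200 → InDel).

Calls carry their sequence content, so replaying a call set onto the
reference reconstructs the alternate copy exactly — the suite asserts this
round trip on planted-variant pairs. Window summaries count SNPs/InDels
and sum PAV base pairs on a 500-kb grid anchored at 0, attributing
boundary-spanning events by reference start (proportional splitting was
rejected for auditability). PAV burden ranking compares each group's first
copy against every other copy and orders pairs by total PAV base pairs,
deterministically.

Reported indel positions can shift by a few base pairs relative to where
an event was planted when flanking bases repeat — the standard placement
ambiguity of any alignment-based caller; lengths and classes are exact.

## Synthetic data generator

`simulate_genome` draws i.i.d. base sequences at a target GC (default
0.40, a plant-like value), plants optional exact repeat families
(dispersed or tandem; exact copies keep specificity truth unambiguous),
and mutates copies 2..ploidy with Bernoulli-per-base SNPs, rate-sampled
indels (geometric lengths capped at 200 bp) and explicit PAV events
(> 200 bp). Copy 1 is the unmutated base. Structural events keep a minimum
spacing (default 50 bp > 2k) from each other so every planted event maps
to its own inter-anchor gap; SNPs may be arbitrarily close to one another
but are excluded from structural footprints. Every event is recorded in a
truth ledger with coordinates on both copies; placement failure after 100
retries is fatal rather than silently densified. A single integer seed
drives one generator stream, so identical specs give byte-identical
genomes and ledgers.

What the generator does *not* emulate: mutation within repeat families,
transposon evolution, GC heterogeneity along chromosomes, assembly gaps
and sequencing error. Passing tests therefore demonstrate algorithmic
correctness against controlled truth, not performance on real assemblies,
where repeat divergence and assembly artifacts add noise the screen's
identity threshold and the caller's painting requirement are designed to
absorb.

`simulate_screen` fabricates per-cell signal-count tables for seed
populations with planted aneuploidies/deletions (a gain shows ploidy + 1
barcode clusters and a DAPI total one higher; a deletion shows a lost
barcode cluster with an intact painting count on the affected chromosome
only — painting is the confirmatory follow-up assay, so other entries are
missing). Optional per-cell noise perturbs one barcode count by ±1 without
touching DAPI or painting, modeling a miscounted spread.

## Problem sizes used in the test and acceptance runs

Synthetic genomes in the suite range from 5 kb to 1 Mb per copy; the
specificity-oracle comparisons use twenty 24-kb tetraploid genomes
(2 chromosomes × 2 copies × 6 kb); planted-variant recovery uses ten
1-Mb homolog pairs (SNP rate 1e-3, indel rate 2e-5, three PAVs of
5000/1200/300 bp); PAV ranking uses 4 × 100-kb chromosome pairs with a
double PAV load on one pair; screening simulations use the 60/59/54-seed
populations with the planted 2/3/2 aberration counts. Design runs use
proportionally scaled region parameters (regions of 3–5 kb holding 60
oligos with 30-kb separation) on 120-kb chromosomes; the published
full-scale defaults are retained as the `alfalfa-paper` preset.

## Known limitations

* The homology screen is ungapped; a gapped 75%-identity cross-hybridizer
  would be missed (out of scope by design).
* Inversions are not recognized as such: an inverted segment loses its
  anchors and is reported as PAV on both sides.
* The aberration caller handles one deviant chromosome per cell; complex
  multi-chromosome aberrations are AMBIGUOUS by construction.
* Whole-genome (100-Mb) alignment performance is a non-goal; the anchor
  chainer is intended for desk-scale (≤ ~10 Mb) pairs.
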