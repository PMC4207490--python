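# Methods

This note records the model behind `bmclocus`, the parameters that matter,
the numerical choices, and what the synthetic corpus does and does not
establish.

## Locus model

A prospective BMC locus is defined operationally, not transcriptionally:
the ±10 kb neighborhood of every accepted shell-protein gene, with
overlapping neighborhoods on one scaffold merged by interval union.
Working from windows rather than presumed operons avoids relying on
transcription data that is unavailable for most genomes, at the cost of
sweeping in flanking genes of uncertain relevance — which is exactly what
the distance weight then discounts. Merging uses closed 1-based inclusive
intervals: windows sharing at least one bp merge; abutting-but-disjoint
windows do not. The envelope runs from the minimum shell-gene start to the
maximum shell-gene end; a single shell gene is its own envelope.

Truncation is evidence-based: a locus is truncated only when a window was
actually clipped by a scaffold end. A scaffold that happens to end exactly
at the window edge implies nothing was cut off, so such loci are complete.
Truncated loci appear in the locus table for inspection but are excluded
from profiling, scoring and clustering, since their pfam sets are
unreliable.

Shell classification follows domain architecture: one PF00936-like domain
is BMC-H, two or more non-redundant domains are BMC-T (the fused
pseudohexamer), a PF03319 domain is BMC-P. Multiple domtblout rows can
re-report overlapping alignments of one domain, so domains counted toward
a BMC-T call are first de-duplicated with the same >50% overlap rule used
for pfam filtering. A protein carrying both PF00936-like and PF03319 hits
is not described in the literature we model; the package classifies it by
the lower e-value and logs a warning.

## ORF distance

The distance *d* of a pfam from the envelope is counted in genes, via
per-scaffold ordinals derived from start coordinates (strand is ignored;
an ORF is an ORF). A gene sharing any bp with the envelope is inside
(*d* = 0); this includes partial overlaps. An outside gene is *d* ORFs away
when it is the *d*-th gene beyond the nearest envelope-bounding shell gene:
the gene immediately adjacent to the envelope edge is at *d* = 1, and the
fourth gene out is at *d* = 4, where the weight floor begins. A pfam
occurring at several distances within one locus keeps the minimal (most
favorable) distance; where a pfam sits both inside and outside the
envelope, the inside occurrence wins.

## Score composition

The published description of the score fixes its ingredients (common and
private pfam sets; distance, identifying, rarity and co-occurrence
weights; the negative-component weight *k*) but not every functional form.
The package's choices, exposed in configuration:

* **Distance weight**: linear decay `1 − 0.1·min(d, 4)`, the unique linear
  interpolation between the two published endpoints (1.0 inside, 0.6 at
  ≥ 4 ORFs). Configurable as a table, constrained non-increasing.
* **Identifying boost**: 2.0 by default, applied in both the positive and
  the negative component — a shared signature enzyme is strong evidence of
  same type, an unshared one of different type. Setting it to 1 disables
  the prior.
* **Rarity**: `R(p)` is the fraction of scoring-corpus loci lacking *p*,
  so it is exactly 0 for a ubiquitous pfam and approaches (never reaches)
  1 for rare ones. On the positive side it is floored at ε = 0.05;
  without the floor, core-enzyme pfams shared by *all* loci (AldDH and
  friends in an all-metabolosome corpus) would contribute nothing to
  similarity, which inverts their meaning. The floor is disableable
  (`rare_floor: 0`).
* **Co-occurrence**: `F(p|C)` is the conditional frequency of *p* among
  corpus loci whose pfam set contains *C*; the penalty for a private *p*
  is scaled by `(1 − F)`. This implements "frequently found within loci
  that also contain the shared set" literally as a superset-conditional
  frequency. The subset condition may be relaxed to a fraction of *C*
  (`cooccurrence_subset_fraction`). When the conditioning set matches no
  corpus locus (possible only for loci scored against a foreign corpus)
  `F` falls back to 0 with a warning.
* **Composition**: weights multiply (scale-free), the two loci's distance
  weights for a shared pfam combine by arithmetic mean (`product` and
  `min` available), and the score is positive − negative with *k* = 0.5.
  Summation is over lexicographically sorted pfams and the two private
  sums are combined commutatively, so `S(I,J) = S(J,I)` holds exactly in
  floating point.

Corpus statistics (for `R` and `F`) are computed over complete,
non-satellite loci only — the scoring corpus equals the clustering corpus.

## Clustering

MCL is implemented internally on scipy sparse matrices: symmetric
adjacency with self-loops, column normalization, then alternating
expansion (matrix square) and inflation (elementwise power, column
renormalization) to a fixed point. Numerical policy: entries below 1e-6
are pruned after inflation; convergence is a max-norm change below 1e-8;
at most 200 iterations (non-convergence returns the current
interpretation with a warning flag). Clusters are read from attractor
rows (diagonal mass > 1e-9), overlapping attractor systems merged by
union-find; a node claimed by no attractor joins its strongest column
neighbor. Columns remain stochastic to 1e-9 after every iteration, and
the procedure is fully deterministic.

Edge weights are the raw similarity scores when the cut-off is positive
(the default regime); for exploratory non-positive cut-offs, scores are
shifted by `1 − cutoff` since MCL needs positive weights. The self-loop
weight is each node's maximum incident edge weight — a standard
regularization; isolated nodes get weight 1 and become singleton
clusters, which are retained and named at every level.

Hierarchical refinement follows a plan mapping dotted cluster names to
(inflation, score cut-off) pairs. The score cut-off is inclusive (≥).
Children are ordered by descending size, then by lexicographically
smallest member, and named `parent.i`. A child cut-off may never be looser
than its parent's, and refinement is refused above cut-off 40 — clusters
that tight consist of nearly identical loci. The default plan applies
(2, 3) at the top level and the published per-cluster refinement values.

## Satellite rules

A satellite locus encodes a subset of shell proteins that presumably
complements a full BMC locus elsewhere in the genome. Three conditions,
all genome-level evaluable: insufficient complement (PF00936-type genes
or PF03319-type genes, not both), all shell genes at consecutive ordinals
with no intervening gene (the strictest reading of contiguity), and at
least one other non-satellite locus in the genome. A configured list of
common BMC-associated pfams (PF00171, PF00465, PF06130, PF10662, extensible)
within 2 ORFs (configurable) of a shell gene vetoes the satellite call to
satellite-like, as does failing only the other-locus condition. Every rule
that fired is recorded in the category table so a curator can audit the
call. Satellites are excluded from corpus statistics and clustering;
satellite-like loci are retained.

Confirmed status propagates from configured anchors (experimentally
characterized loci or named clusters) to all members of the deepest
cluster containing the anchor; everything else non-satellite remains a
candidate.

## Representatives

Per cluster, at every tree level, each pfam's occurrence proportion is the
fraction of members containing it. A member's representative score adds
the proportions of pfams it has and subtracts those it lacks. Scores are
sums of rationals c/n; ranking uses values rounded to 1e-9 so float
summation order cannot turn an exact tie into a spurious strict order
(mathematically distinct scores differ by at least 1/n²). Ties prefer
characterized loci, then reference-genome loci, then the smallest
locus_id. The majority-pfam override compares only the top two ranked
members and is not applied recursively.

## Synthetic corpus

The generator plants three locus types modeled on PDU-, EUT- and
alpha-carboxysome-style neighborhoods, with 9–13 pfams per locus —
comparable to real representative loci (signature-enzyme subunits,
catalytic core, accessory, regulatory and transport genes) — five loci per
type by default, plus a genome with a bare two-gene satellite, a locus
truncated at a scaffold edge, and a protein with two >50%-overlapping
pfam alignments. Geometry is 900 bp genes at 1000 bp pitch, so a 10 kb
window spans about ten ORFs and every distance regime (d = 0…4+, including
planted d = 1, 2 and 4 pfams) is reachable. Shell and pfam e-values are
drawn log-uniformly in 1e-30…1e-6; decoy hits are planted above each
threshold (1e-4…1e-2 for shell, 0.02…1 for pfam) so both sides of the
cutoffs are exercised. All randomness flows from one seed; equal seeds
give byte-identical files, and the truth table is validated against the
emitted annotations on write.

What the generator does **not** emulate: real protein sequences (domain
evidence enters only via the domain tables), paralogy and cross-type gene
sharing beyond the planted core pfams, assembly fragmentation beyond a
single truncation, annotation errors, and uneven locus sizes. Passing the
end-to-end tests therefore shows that the machinery is correct under the
stated geometry and noise model — type recovery is exact at zero noise
and robust to 20% pfam dropout (mean adjusted Rand ≥ 0.9 over ten seeds)
— not that the default thresholds are optimal for any particular real
survey.

## Problem sizes

Tests and the acceptance script run on corpora of 15–23 loci across ~18
genomes, pairwise scoring over ≤ 120 pairs, and MCL graphs of ≤ 30 nodes;
randomized oracle checks use hundreds of small instances. These sizes
exercise every code path (merging, truncation, satellites, both noise
regimes, all weight regimes) while keeping the whole suite in seconds.
Scoring is O(n²) in loci with set operations per pair; corpora of a few
hundred loci remain comfortable on one CPU.

## Known limitations

* The exact published functional forms for the identifying, co-occurrence
  and composition choices are not recoverable from their description;
  the package's forms reproduce all published endpoint values and are
  config-separable, but other choices could reproduce them too.
* The overlap-resolution denominator uses the shorter *alignment* length,
  not the HMM model length (robust when model lengths are absent);
  configurable.
* Entrez-based genome deduplication is out of scope; deduplication by
  exact protein-sequence identity can be done upstream.
* The biological naming of types (PDU/EUT/GRM semantics) is configuration,
  not inference: anchors and identifying pfams carry the labels.
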