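# Methods

This note documents the models, conventions and design choices behind
helitronkit, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic benchmarks do and
do not demonstrate.

## The element model

The target is a family of short non-autonomous Helitrons: a conserved
core (the 134 bp family consensus) followed by a species- or
lineage-specific *acquired* region at the 3′ end.  Structural
hallmarks used throughout:

* 5′ terminus `TC`, 3′ terminus `CTRY` (R = A/G, Y = C/T);
* a `CTRR` tetramer near the 3′ end of the acquired region;
* a palindromic inverted repeat ("hairpin") of roughly 16–20 bp near
  the 3′ terminus;
* insertion precisely between a host `A` and `T` (the host reads
  `…A | element | T…`), with **no** target-site duplication — the
  signature of rolling-circle integration.

Coordinates are 0-based half-open internally; GenBank-style 1-based
inclusive pairs are converted on ingest, with reversed pairs
(`371-171`) interpreted as minus strand.

## Search

Candidate loci are found by exact 11-mer seeding on both strands,
clustering of seeds into candidate windows, and verification with an
optimal affine-gap local alignment (match +1, mismatch −1, gap of
length L scoring −2 − L; all configurable).  An 11-mer survives in a
window of ≥ 100 bp at 70% identity with probability ≈ 1 − (1 − 0.7¹¹)⁹⁰
≈ 0.87 per window position-set, and in practice sensitivity for
134 bp cores at ≤ 15% divergence is ≈ 1.  Hits are kept when identity
(matches / ungapped columns) ≥ 0.70 **and** aligned columns
(gaps included) > 100, read strictly; overlapping hits are merged,
keeping the best score.  Whether the length filter counts gapped
columns is a convention; we count them and expose the threshold.

Pairwise alignment is delegated to Biopython's `PairwiseAligner`
(exact Gotoh DP in C).  Our gap convention `gap(L) = open + L·extend`
maps onto its scoring as `open_gap_score = open + extend`.  The test
suite verifies local and global scores against an independently coded
plain-Python DP.  Co-optimal alignments are resolved by the aligner's
deterministic first-traceback rule; outputs are reproducible but the
specific tie-break differs from, e.g., "lowest subject coordinate
first".

## Boundary refinement

A consensus hit marks the core, not the element: the true 3′ terminus
lies up to an acquired-length further downstream (65 bp by default;
> 300 bp in the largest known copies).  Refinement therefore:

* **5′ end** — nearest position within ±30 bp of the hit start where
  the sequence begins `TC` immediately preceded by host `A`;
* **3′ end** — positions ending `CTRY` immediately followed by host
  `T`, searched within ±30 bp of the hit end *plus* up to
  `acquired_reach` (default 150 bp) downstream.  Because a chance
  `CTRY|T` occurs every ~256 bp, far candidates are accepted only with
  hallmark support — a `CTRR` within ~15 bp upstream, or a perfect
  inverted-repeat arm ≥ 8 bp nearby — and candidates are ranked by
  that support before proximity.

If either anchor is missing, the raw hit boundaries are returned and
the terminus flags fall out false.  An element at a contig edge gets
junction status `undetermined` and is excluded from the full-length
set; *full length* requires `TC` and `CTRY` termini, a determinate A/T
junction, and no detected TSD (k-mer duplication scan, k = 4–10 —
typical class-II TSD lengths; the family creates none).

## Identity, consensus, alignment

Identity between two sequences is computed **excluding indels**:
matches divided by alignment columns with no gap in either row.  This
is the statistic used for copy-to-consensus and cross-species
comparisons.  Note a known property: on a *gapped optimal* alignment
of deeply diverged sequences the statistic is upward-biased (the
aligner preferentially pairs matching stretches, so surviving ungapped
columns are match-enriched).  Measured against the Jukes–Cantor
expectation the bias is ≲ 0.02 up to ~0.5 substitutions/site,
~0.04 at 0.8, and ~0.09 at 1.0; the HT margin (below) absorbs the
moderate-divergence regime, and the HT benchmark is designed inside
it.

The progressive aligner builds a UPGMA guide tree from shared-6-mer
distances and merges groups by affine-gap profile–profile DP
(column-frequency profiles; same scoring defaults).  Consensus calling
drops columns gapped in > 50% of rows, takes the majority residue when
its fraction (of non-gap residues) ≥ 0.5, and writes the IUPAC code of
the tied residue set otherwise — deterministic and
information-preserving.

## Distances, trees, bootstrap

Distances use pairwise deletion of gapped columns (complete deletion
would discard most signal for elements whose acquired regions align
only within lineages; a flag switches it).  The TN93 distance corrects
purine and pyrimidine transitions separately with empirical base
frequencies and raises an explicit saturation error when a logarithm
argument goes non-positive; the implementation agrees with R/ape's
`dist.dna(model = "TN93")` to 12 decimals on a fixed example frozen in
the tests.  TN93 ≥ p-distance always (the correction inflates).

Neighbor joining is the standard Saitou–Nei agglomeration with the
Q-criterion; ties are broken by the smallest representative leaf label
of each cluster, negative branch lengths are clamped to zero with the
deficit moved to the sister edge, and the result is an unrooted
(trifurcating-root) tree.  On additive matrices recovery is exact;
the suite checks 50 random 4–8-taxon trees and the 3-taxon closed
form to 1e-12.

The bootstrap resamples alignment columns with replacement, rebuilds
the tree per replicate (default: NJ on p-distances), and reports for
each internal bipartition of the point tree the percentage of
replicates containing it.  Newick output suppresses supports below a
threshold (default 50).  Maximum-likelihood inference is deliberately
out of scope; the TN93 model enters through its distance.

## Empty sites and horizontal transfer

The empty-site query concatenates ~100 bp of upstream and downstream
host flank across an insertion (~200 bp total), taken in element
orientation.  Each query half is locally aligned to a target
(better strand kept); a target is **empty** when both halves hit
collinearly (≥ 50 ungapped columns and ≥ 70% identity each) with at
most 10 bp of intervening target sequence, **occupied** when the
halves are split by ≥ 50 bp (the gap, corrected for unaligned query
ends, is the insert-length estimate), and **absent** otherwise.  The
50-column minimum per flank is one operationalisation of what a
curator would accept as the "same locus".

HT evidence formalises the classic argument that element identity can
be too high for vertical descent.  Under Jukes–Cantor, two lineages
separated for `T` years at per-lineage rate `r` retain expected
identity `1 − ¾(1 − e^(−8rT/3))`; a pair is flagged when observed
identity (excluding indels) exceeds this by more than `margin`
(default 0.10).  Both the rate (default neutral 2×10⁻⁹
substitutions/site/year/lineage) and the margin are explicit
parameters, and conclusions should always be reported together with
them: at a 325-My host split the expectation is ≈ 0.38, so a 0.90
observation is flagged at any plausible rate, while shallow splits
need the margin.  `ht_scan` takes host divergence directly from a host
tree's path lengths (with `rate = 1`, branch lengths are
substitutions/site/lineage).  Dollo loss counts (single gain at the
MRCA of presence taxa, minimum losses below it) quantify how patchy a
taxonomic distribution is; the implementation is checked against
exhaustive enumeration of loss placements on all presence patterns of
trees up to 8 leaves.

## Synthetic data: what it emulates, and not

`random_genome` draws i.i.d. bases at 40% GC (insect-like).
`make_element` appends to the consensus a random acquired tail
carrying all hallmarks at recorded coordinates: terminal `CTRY`,
`CTRR` immediately before it, and a perfect 8 bp-arm/4 bp-loop hairpin
ending 10 bp before the terminus.  The tail must be ≥ 30 bp so these
features fit without overlapping.  `mutate` applies per-site
substitutions and geometric(mean 2) indels, with exact bookkeeping and
an optional protected-position set; recovery experiments protect the
~30 hallmark positions so copies stay hallmark-complete at the stated
divergence (unprotected 10% mutation would destroy at least one
hallmark in most copies — real full-length copies are, by definition,
the ones whose hallmarks survived).  `plant_insertions` inserts copies
between genuine host `A|T` dinucleotides with ≥ 150 bp clearance and
no TSD.

`simulate_clade` evolves an element down a host tree using the exact
JC transition kernel per branch (so multiple hits are accounted for
and pairwise p-distances match the JC transform of path lengths).  An
HT event copies the donor's tip-state element to the recipient's
terminal-branch start, after which it evolves along that branch —
i.e., a recent transfer; "the donor's state at the event time" is not
otherwise defined without an explicit time model.

What the synthetic regime does **not** emulate: nested/chimaeric
copies, low-complexity and repetitive host background, sequencing
error, copy-number dynamics within hosts, and indel-rich divergence of
acquired regions between species.  Passing benchmarks therefore
demonstrate algorithmic correctness and calibration under clean
conditions, not performance on raw assemblies — on real data the
boundary-refinement and occupancy heuristics are the components most
exposed to these complications.

## Benchmark design notes

* *Planted recovery* uses 10 genomes × 10 copies at 10% substitution
  divergence (60 kb genomes) — small enough to run in seconds, large
  enough that a 95% sensitivity bound is meaningful.
* *Congruent bootstrap* builds a homoplasy-free 10 × 200 alignment in
  which every column marks one branch (≥ 14 columns per internal
  edge), so every resampled matrix is exactly additive on the
  generating topology and all internal supports must be 100; the
  per-edge column count keeps the probability of a replicate losing an
  edge below ~e⁻¹⁴.
* *HT benchmark* uses a 6-taxon tree with a unique most-distant pair
  at 0.5 subs/site and a 445 bp element (the size of the largest known
  real copy): expected-identity margins for every non-transferred pair
  are ≥ 4 binomial standard errors from the flag threshold, and the
  transferred pair sits ~5 s.e. above it, so the 20-replicate
  experiment is stable across seeds.

## Known limitations

* The acquired-region 5′ boundary rests on an overlap alignment to the
  consensus (element overhang free, consensus end gaps penalised); when
  core homology decays gradually the split is a convention, not a fact.
* The terminal `CTRY` and the acquired-end `CTRR` may overlap in short
  tails; both are scanned independently and overlap is allowed.
* Identity-excluding-indels saturates near ~0.55 on optimal gapped
  alignments of unrelated sequences; do not interpret HT flags at host
  divergences ≫ 1 substitution/site without raising the margin.
* No E-value model, no translated search, no autonomous-partner
  (RepHel) detection, no ML tree inference, no dating of transfer
  events.
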