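# helitronkit

Toolkit for finding and analysing short **non-autonomous Helitron
transposons** of the *Lep1* type: ~130–450 bp elements consisting of a
conserved core plus a species-specific "acquired" 3′ tail, bounded by
5′-`TC` and 3′-`CTRY` termini, carrying a `CTRR` tetramer at the end of
the acquired tail and a short palindromic hairpin near the 3′ terminus,
and inserted by rolling-circle transposition precisely between a host
`A` and `T` with no target-site duplication.

It is written for molecular-evolution work on these elements:
annotating copies in assemblies, measuring inter-copy identity the way
the field reports it (excluding indel columns), testing insertion
polymorphism *in silico* with chimeric empty-site queries, and scoring
evidence of **horizontal transfer** (HT) between distantly related
hosts.

## What it computes

* **Search** — seed-and-extend local alignment of a family consensus
  against genomic sequence (both strands), keeping hits ≥ 70% identical
  over > 100 aligned columns; BLAST tabular (outfmt 6) files can be
  ingested instead.
* **Annotation** — boundary refinement to the canonical junction
  context (`…A | TC … CTRY | T…`), hallmark calls (termini, `CTRR`,
  hairpin, A/T junction, TSD absence), and core/acquired delineation
  against the consensus.
* **Identity excluding indels** — matches divided by alignment columns
  with no gap in either row; pairwise matrices and consensus building
  from an in-house progressive aligner.
* **Phylogenetics** — p and Tamura–Nei (TN93) distances with pairwise
  deletion, Saitou–Nei neighbor joining, column-resampling bootstrap
  (default 1000 replicates; supports below 50% suppressed in newick
  output), Robinson–Foulds comparison.
* **Polymorphism & HT** — chimeric ~200 bp empty-site queries classify
  orthologous loci as *occupied / empty / absent*; a taxon pair is
  flagged for HT when its element identity exceeds the Jukes–Cantor
  vertical-descent expectation
  `E[identity] = 1 − ¾(1 − e^(−8rT/3))`
  (divergence time `T`, per-lineage rate `r`, default 2×10⁻⁹
  subs/site/yr) by more than a margin (default 0.10); Dollo
  single-gain loss counts quantify patchy taxonomic distributions.
* **Simulation** — synthetic host genomes with planted,
  hallmark-complete elements and exact truth records, including clade
  simulations with vertical descent and horizontal-transfer events, so
  every stage is testable without downloads.

## Worked example

Simulate a 60 kb genome with 10 planted, 2%-diverged copies, then scan
it with the bundled synthetic consensus:

```bash
$ helitronkit simulate --seed 3 --outdir sim
10 insertions planted in sim/genome.fasta
$ helitronkit scan sim/genome.fasta sim/consensus.fasta --outdir scan
10 elements (10 full length)
$ head -4 scan/elements.tsv | cut -f1-15
subject_id         start  end   strand length full_length five_prime_tc three_prime_ctry ctrr_in_acquired hairpin junction tsd_detected core_len acquired_len identity_to_consensus
synthgenome_seed3  4795   4994  +      199    True        True          True             True             10/2/1  AT       False        134      65           0.9776
synthgenome_seed3  5948   6147  +      199    True        True          True             True             9/4/1   AT       False        134      65           1.0000
synthgenome_seed3  7626   7825  +      199    True        True          True             True             10/2/1  AT       False        134      65           0.9851
```

Each row is one element call: a 199 bp copy (134 bp core + 65 bp
acquired tail), all hallmarks present (`hairpin` is arm/loop/mismatch),
inserted at an `A|T` junction with no TSD, and 97–100% identical to the
consensus — the signature of a recent transposition burst.  The same
run writes `elements.gff3` (with core/acquired/hairpin child features)
and `elements.fasta`, plus a JSON run manifest.

Downstream, `helitronkit tree` aligns copies and builds a bootstrapped
NJ tree, `helitronkit emptysite` classifies orthologous loci with a
chimeric flank query, and `helitronkit htscan` reports, for every
taxon pair, observed element identity vs. the vertical expectation and
the resulting HT flag.

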