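# mitoarray

How well do the mitochondrial SNPs on a genotyping array support
haplogroup assignment?

Genome-wide SNP arrays type a few hundred mtDNA positions as a side
effect of their design. Whether those positions suffice to recover a
sample's mitochondrial haplogroup — especially the deeply structured
African L0–L6 clades — depends entirely on how many *clade-defining*
sites the array happens to carry. `mitoarray` is a benchmarking toolkit
for exactly that question, aimed at population and forensic geneticists
deciding whether array data can stand in for full mtDNA genomes:

- **Masking** — project full, rCRS-coordinate mitochondrial sequences
  onto an array's position manifest (plus snp-sites-style haploid VCF
  export and vcftools-style position filtering).
- **Trees** — p/K2P/TN93 pairwise distances, Saitou–Nei neighbor
  joining, and a site-resampling bootstrap with per-bipartition support.
- **Assignability** — a haplogroup `h` with subhaplogroup leaf set `S`
  is *assignable* in a tree if some branch with bootstrap support ≥ 50
  holds all, or all but one, of `S` with at most one intruding leaf.
  Arrays are scored by the share of haplogroups (at nomenclature levels
  2–4: L0, L0d, L0d1) assignable in the full-genome gold-standard tree
  that they preserve.
- **Classification** — a transparent caller that assigns
  `argmax_h K(h)` with the Kulczynski match quality
  `K(h) = ½(|O∩E(h)|/|E(h)| + |O∩E(h)|/|O|)` between the sample's
  observed variants `O` and the haplogroup's expected defining mutations
  `E(h)`, the measure behind HaploGrep2's "overall rank".
- **Statistics** — exact two-sided Fisher tests between arrays, Pearson
  correlations of SNP count versus performance, and Fisher's (1925) z
  for comparing two correlations.
- **Synthetic data** — a generator for haplogroup trees (infinite-sites
  defining mutations), cohorts (one sequence per five-character African
  terminal, two per non-African major), and manifests with a tunable
  fraction of defining sites — so the whole pipeline is testable without
  downloads.

## Worked example

`examples/07_full_benchmark.py` simulates a 38-sample cohort on a
2,000-bp genome (binary subdivisions down to five-character African
terminals), builds bootstrapped NJ trees for the full sequences and for
four synthetic arrays that carry 100%, 50%, 10% and 0% of the tree's
defining sites (plus 50 uninformative background positions each), and
prints:

```
mean assignability (levels 2-4) per array:
  array_f0   ( 50 positions):   0.0%   mean rank 1.000
  array_f0.1 ( 70 positions):  27.9%   mean rank 0.675
  array_f0.5 (148 positions):  75.2%   mean rank 0.738
  array_f1   (245 positions): 100.0%   mean rank 0.998
wrote 7 report files to benchmark_out/
```

Assignability collapses with the defining-site fraction even though the
0%-array still types 50 mtDNA positions: informativeness, not raw SNP
count, is what matters. (The 0% array's mean rank of 1.0 is the
degenerate root call — every sample falls back to macrohaplogroup L with
a vacuously perfect match; the assignability column is what exposes it.)
The same contrast appears per sample (`examples/05_classifier_ranks.py`):

```
full genome                    mean rank 0.928   prefix-correct 100.0% of African samples
array (25% of defining sites)  mean rank 0.663   prefix-correct 100.0% of African samples
```

Array calls stay prefix-compatible with the truth but land on shallower
haplogroups with visibly lower confidence. The statistics module
reproduces the published comparison of the three- versus four-digit
performance correlations (`examples/06_printed_statistics.py`):

```
Fisher z comparing the two correlations: z = -0.4525, p = 0.6509
p-value of r = 0.9698051 at n = 8:       6.727e-05
```

A thin CLI mirrors the library (`mitoarray simulate | mask | tovcf |
filter | tree | assignability | classify | stats | run |
panel-overlap`); see `mitoarray --help`.

## Layout

```
src/mitoarray/
  haplotree.py    haplogroup nomenclature + PhyloTree-style trees (TSV I/O)
  seqio.py        FASTA / manifest / haploid-VCF I/O, reference-gap rule, masking
  phylogeny.py    distances, neighbor joining, bootstrap, newick
  assignability.py  the clade criterion and per-array percentages
  classifier.py   Kulczynski-rank haplogroup caller
  stats.py        Fisher exact, Pearson r, Fisher-1925 z
  simulate.py     synthetic trees, cohorts, manifests
  pipeline.py     end-to-end benchmark + TSV/JSON reports
  cli.py          thin command-line wrapper
docs/methods.md   model, assumptions, parameter choices, limitations
examples/         one short narrative script per capability
```
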