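# Methods

## The question and the design

A mitochondrial haplogroup is a clade of mtDNA sequences sharing derived
substitutions inherited from a common ancestor, named by alternating
letters and digits (L0d1a); the character count of a label is its
nomenclature *level* (L0 = 2, L0d = 3, L0d1 = 4). Genotyping arrays
interrogate a fixed set of mtDNA positions, and a haplogroup is
recoverable from array data only to the extent that its clade-defining
substitutions fall on typed positions. `mitoarray` quantifies this two
ways: a *tree arm* (do the subhaplogroup sequences still form supported
clades when the data are masked to the array?) and a *caller arm* (does a
rule-based classifier still find the right haplogroup, and with what
confidence?). Both are scored against full-genome results as the gold
standard.

## Tree arm

**Distances.** Pairwise distances on the masked site matrix use
p-distance, Kimura two-parameter (default), or Tamura–Nei 1993 with
empirical base frequencies. Missing bases (`N`) are excluded pairwise
(per-pair deletion; complete deletion is available). mtDNA sequences are
~99% identical, so the choice of model barely perturbs topology; MEGA's
"Maximum Composite Likelihood" distance, whose joint estimation is not
documented at implementation level, is deliberately not reproduced, and
every report's provenance block says so. Saturated pairs (log argument
≤ 0) raise an error naming the pair rather than emitting NaN.

**Neighbor joining.** Saitou–Nei agglomeration with the standard Q
criterion and branch-length formulas. Ties in Q are broken toward the
lowest (row, column) pair in the current working order and new nodes are
appended at the end, so reruns are byte-identical. On an additive matrix
NJ provably recovers the generating topology and branch lengths; the
test suite and the acceptance script verify exact recovery on random
20-taxon additive matrices (100/100).

**Bootstrap.** Support for each internal bipartition of the tree built
from the full matrix is the percentage of column-resampled replicates
containing it. Replicate *r* draws from an RNG stream seeded by
`(seed, r)`, so results are independent of execution order; replicates
on which a distance model is undefined are redrawn from a fresh stream
and logged. Internal edges of length ≤ 1e-12 are collapsed to polytomies
before bipartitions are read off, in the original tree and in every
replicate: a zero-length edge is an arbitrary resolution carrying no
signal (an all-monomorphic matrix therefore yields *no* supported
clades, rather than spuriously unanimous ones). Negative NJ branch
lengths are kept internally and floored at zero when writing newick;
supports, not lengths, drive all downstream scoring.

## Assignability

A haplogroup `h` at level k is represented by the leaf set `S` of
samples whose true label has `truncate(label, k) = h` as a prefix. `h`
is **assignable** in a bootstrapped tree when some branch with support ≥
`min_support` (default 50) contains all but at most `max_missing`
(default 1) members of `S` with at most `max_intruders` (default 1)
non-members. Because the NJ tree is unrooted, a "branch" is one side of
an edge, and both sides of every edge are candidates; trivial
(single-leaf) splits exist in every replicate and count as support 100.
Two further rules make the criterion well-posed:

- a candidate branch must contain **at least two** members of `S` — a
  single stray leaf is not a cluster, and without this rule every
  two-member haplogroup would be vacuously assignable through any leaf
  edge via the all-but-one allowance;
- haplogroups with `|S| < 2` are excluded from numerator and denominator
  and reported separately (monophyly of one sequence is vacuous; with
  one sequence per five-character terminal this removes level-5
  scoring, which is also why levels are capped at 4).

Percentages condition on the gold standard: the denominator at each
level is the set of haplogroups assignable in the full-genome tree, and
an array scores the fraction it preserves (`denominator="all"` gives the
unconditioned variant for sensitivity analysis). Per-major summaries
pool levels 2–4 within each of L0–L3. A "no bootstrapping" analysis is
`min_support=0` on the same code path. The Fisher-exact comparison
between two arrays uses the (assignable, not) × (array A, array B)
table at a chosen level.

One geometric consequence of the study design deserves note: the
non-African majors M, N and R nest inside the deepest L3 lineage, so L3
itself (and its ancestors on that path) is never monophyletic by label
prefix — in *any* tree, including the gold standard. The gold-standard
conditioning absorbs this: such haplogroups drop out of both numerator
and denominator consistently.

## Caller arm

For a sample typed at covered positions `C` with observed non-reference
variants `O`, each candidate haplogroup has expected mutations `E(h)` =
the defining mutations on its root path, and

    K(h) = ½( |O∩E(h)| / |E(h)| + |O∩E(h)| / |O| ),   0/0 := 1.

The call is `argmax K`, ties broken toward the deeper (longer) label,
then lexicographically. `E(h)` is deliberately **not** restricted to `C`
by default: defining mutations the array fails to type count against the
expected term, which is precisely what drives array ranks below
full-genome ranks and shallower-than-truth calls. (Under restriction the
true haplogroup would score 1.0 on any array and the full-genome/array
contrast would invert; the restricted variant remains available as
`restrict_expected=True` for modeling a strictly range-aware caller.)
Two degenerate cases fall out correctly: a sample with no observed
variants and `E(root) = ∅` gets a unique rank-1 root call, and an array
with zero defining coverage sends every sample to the root — a
confident-looking but uninformative call that the assignability arm, not
the rank, exposes. Correctness of a call is prefix-compatibility with
the truth (assigning L0 where the truth is L0a2a is correct; resolution
is ignored), with an exact-at-level variant available.

## Statistics

Fisher's exact test is the two-sided point-probability convention:
enumerate the hypergeometric distribution over the observed margins and
sum the probabilities of tables no more likely than the observed one,
with 1e-7 relative tolerance for floating-point ties (matching
mainstream statistical software; verified against exact
rational-arithmetic enumeration to 1e-10). Pearson r carries the
two-sided t-transform p-value on n−2 degrees of freedom. Two
correlations are compared with Fisher's (1925) z on the atanh scale
using the independent-groups formula — applied to the published
three-digit (r = 0.9470996) and four-digit (r = 0.9698051) performance
correlations over eight arrays it returns z = −0.4525, p = 0.6509,
which doubles as the check that this is the right variant; a
dependent-overlapping (Steiger/Meng) alternative is provided for
completeness.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the benchmark's study design. A rooted
macrohaplogroup-L tree subdivides African majors (L0–L3 by default, up
to L6) by alternating nomenclature characters down to `levels` = 5
(five-character terminals); M, N and R attach under the deepest L3
lineage. Every branch carries max(1, Poisson(3)) defining mutations at
globally unique positions (infinite sites: no recurrent or back
mutations, so truth is unambiguous for oracle tests). Cohorts take one
sequence per terminal African haplogroup and two per non-African major;
each sequence adds Poisson(2) private mutations at positions unused by
any branch or any other sample, making them phylogenetically
uninformative noise by construction. Manifests take
⌈fraction × D⌉ of the D defining positions plus a count of non-defining
background positions — the informativeness axis the benchmark studies.
Defaults: genome length 16,569 (rCRS-sized; benchmarks and tests use
2,000 bp with binary subdivisions, ~38 samples and 100–200 bootstrap
replicates, which keeps a full run under two seconds without changing
any invariant — all properties are length-independent).

Deliberately not modeled: transition/transversion bias and mutational
hotspots, heteroplasmy, indels, recurrent mutation, genotyping error,
and PhyloTree's back-mutation ("!") notation. Passing tests therefore
demonstrate the *pipeline's* correctness and the coverage→performance
relationship under clean inheritance; they do not certify real-array
percentages, which additionally depend on homoplasy and array-specific
clustering chemistry. Real GenBank-derived runs should supply their own
haplogroup tree TSV, reference-aligned FASTA and manifest files through
the `fasta` input mode.

## Numerical and design choices

- Coordinates are 1-based and closed on the reference, matching VCF and
  published mtDNA position tables; only single-base substitutions are
  modeled, IUPAC ambiguity codes become `N` (missing) with a warning.
- The reference-gap rule deletes alignment columns that insert gaps into
  the reference, preserving reference numbering; sample gaps at kept
  columns become `N`.
- VCF output follows the snp-sites haploid convention: polymorphic
  columns only, ALT alleles in first-observation order, `.` genotypes
  for missing.
- All generators and the bootstrap are pure functions of (config, seed);
  benchmark reports embed seed, criterion, model and deviation notices
  so every number is reproducible from the JSON alone.
- Site matrices store columns in ascending position order regardless of
  input order, which is what makes bootstrap supports exactly invariant
  to column permutation of the input.

## Known limitations

Assignability is conservative for haplogroups whose members are few and
deep (the all-but-one allowance is absolute, not proportional). The
Kulczynski caller uses no hotspot weighting or phantom-mutation
filtering, so its absolute ranks are not exchangeable with HaploGrep2's
on real data even though the measure is the same family. K2P/TN93 raise
on saturated pairs instead of falling back to p-distance; for the ~99%
identical sequences this pipeline targets, saturation indicates a data
problem worth surfacing rather than smoothing over.
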