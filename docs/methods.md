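# Methods

`haplodose` implements the desk-scale analysis of allele interactions at a
polyploid locus: given the haplotype sequences recovered for a homeologous
region, the locus ploidy from cytology, and transcriptome reads (or per-SNP
read counts), it catalogues variation among haplotypes, classifies
per-haplotype expression, tests whether the genomic allele dosage explains
the transcriptome allele ratio, and dates duplications and transposon
insertions under a strict molecular clock.  The motivating system is
sugarcane (*Saccharum* spp. hybrids), where a locus may be present in 8 or
10 homeologous copies and the sequenced clone set typically misses at
least one copy.

## Variant catalogue

Haplotypes of a region enter as a multiple alignment over
`{A, C, G, T, -, N}` with one haplotype designated the coordinate
reference.  Variant calling is column-wise with run merging:

* Polarity is majority-rules per column: the most frequent state among
  non-`N` characters is the *common* state; each minority state yields one
  record listing its carrier haplotypes.  Ties break toward the
  lexicographically smaller state as common — an arbitrary but
  deterministic convention for the 50/50 case.
* Adjacent columns merge into a single record when they have the same
  carrier set and the same category: runs of gaps collapse to one
  insertion or deletion, adjacent substituted columns collapse to a
  multibase substitution (`GG -> TT` style).
* A deletion whose deleted motif is an exact copy of the immediately
  adjacent reference sequence is classed a tandem-repeat deletion
  (`(GAG)3 -> (GAG)2` style).
* `N` never creates a variant and never counts as a match.
* Positions are 1-based on the ungapped reference; for insertions
  relative to the reference, the position of the last preceding
  reference base is used.

SNP density is reported as ungapped reference length divided by the
variant count (alignment columns would be an alternative; the ungapped
reference matches how per-gene positions are quoted in the source
tables).  Region-diagnostic sites are the variants of the concatenated
two-region alignment whose carrier set is exactly one region's full
haplotype set.

Clone sequences with pairwise identity above 99% (matches over columns
not gapped in both; configurable threshold) are collapsed into one
homeolog by single linkage.  Gene haplotypes are grouped by exact spliced
CDS identity.  The frameshift screen translates from the first codon
(ambiguous codons become `X`), counts codons before the first stop, and
flags a premature stop relative to the annotated protein length and a
frameshift when the CDS length is not `3 * (expected + 1)`.

## Expression classification

Read assignment is exact substring matching of each read against every
haplotype CDS, both strands, with `N` in a read matching any base.  This
is the decision rule of a map-then-filter-at-100%-identity pipeline,
applied directly at desk scale; gapped alignment is deliberately out of
scope, so the positional tally requires the haplotype CDSs to share a
coordinate frame, and indel variants are skipped (their counts can be
supplied directly as a table).  Reads that mismatch every haplotype stay
unassigned; reads matching all haplotypes are shared evidence.

A variant allele counts as present in the transcriptome when at least
6 reads carry it (configurable); coverage at a site counts every
assigned overlapping read, so reads showing `N` or a third base at the
site count toward coverage only.  A haplotype is then:

* **expressed** when reads consistent with it cover its whole CDS, or at
  least one of its exclusive alleles passes the read threshold;
* **not_expressed** when its exclusive sites have coverage but none of
  its exclusive alleles are seen;
* **undetermined** when it has no exclusive alleles (indistinguishable
  from its neighbours) or no coverage at them.

Multi-allelic sites are handled by keying tallies on
`(position, variant state)`, not position alone; keying on position
alone silently credits one haplotype with another allele's reads.

## The missing-haplotype dosage test

For a region of ploidy `P` with `H` sequenced haplotypes (`P - H`
missing) and a SNP with variant read count `k` out of `n` covering
reads, two genomic dosages are entertained: the missing copy carries the
common allele (variant dosage `v = x`, where `x` counts carriers among
the sequenced haplotypes) or the variant allele (`v = x + 1`).  A SNP
seen only in the transcriptome pins the variant to the missing copy and
both hypotheses coincide at `v = P - H`.  Each hypothesis is tested with
the exact two-sided binomial test of `k/n` against the exact fraction
`v/P`:

```
p = sum over i of Binom(i; n, v/P)  for all i with
    pmf(i) <= pmf(k) * (1 + 1e-7)
```

the small-probability-summation convention of the classical exact test
(identical to R's `binom.test`); the relative tolerance `1e-7` guards
the inclusion comparison against floating-point noise.  No normal
approximation is used anywhere.  The null is accepted at `p >= alpha`
(default 0.05), reading acceptance as "the genomic dosage explains the
transcriptome ratio".  No multiple-testing correction is applied — each
SNP is an independent diagnostic, and the published analysis applies
none.  Sites inside a segment duplicated into a second region are
excluded from testing (their read counts mix two loci) but reported.

Rows may carry explicit `(v, total)` pairs per hypothesis, which
override the rule above; the bundled CENP-C table uses this for one site
whose published proportions (0.57 = 4/7) imply a seven-copy context the
generating rule cannot produce.  Transcriptome proportions are reported
rounded half-up to two decimals, matching table conventions; the test
itself always uses exact fractions.

## Molecular clock

Distances: p-distance, JC69 (`d = -(3/4) ln(1 - 4p/3)`), K2P
(`d = -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q)` with transition and
transversion proportions `P`, `Q`), and NG86 synonymous/nonsynonymous
coding distances with the JC correction applied to `pS` and `pN`.
Conventions for NG86: per-codon site counts come from single-base
neighbour enumeration with changes into stop codons counted
nonsynonymous; multi-difference codons average over all orderings of the
minimal mutational path with orderings through a stop codon excluded
(all orderings are used if every one hits a stop); site counts are
averaged over the two sequences.  Columns with a gap or `N` in either
sequence are deleted pairwise everywhere.  Corrections outside their log
domain return a saturated flag, never an exception; a saturated distance
propagates to an undated result.

Dating is the strict clock `T = d / (2 r)` with substitution rates in
units of substitutions/site/year: 6.5e-9 for coding grass sequence and
1.3e-8 for noncoding DNA (both standard grass calibrations).  Which
single coding distance enters `T` is a user choice; `dS` is the default
output with `dN` alongside, since synonymous sites are closer to neutral.
LTR retrotransposon insertions are dated from the divergence of the
element's two terminal repeats, which are identical at insertion; the
default LTR distance model is K2P (the common convention for LTR
dating), with JC69 selectable.

## Neighbor joining

The tree module implements classic NJ: join the pair minimising
`Q(i,j) = (n-2) d(i,j) - R_i - R_j`, branch lengths from the two-point
formulas, exact on additive matrices.  Ties in `Q` break on the
lexicographically lowest label pair, making the result independent of
input order.  Negative branch lengths are clamped to zero with the
deficit moved to the sibling edge, preserving the joined pair's path
length.  Saturated pairs abort matrix construction with the offending
pairs listed — no tree is built from an incomplete matrix.  Rooting is
at the midpoint of the outgroup's pendant edge; monophyly of a leaf set
means some clade equals it exactly.  Bootstrap support is not
implemented.

## Synthetic data

The generator produces loci, duplication scenarios, LTR pairs and read
sets with known truth, all from one integer seed through a single
`numpy` generator, so outputs are byte-reproducible.  Substitutions
follow the Jukes-Cantor process (per-site change probability
`(3/4)(1 - exp(-4 d / 3))` at branch length `d = t r`, uniform target
base); indels are limited to configurable fixed-length deletions, enough
to exercise the deletion and frameshift paths.  Reads are unspliced CDS
fragments: uniform start, multinomial source haplotype in the expression
weights, per-base error 0.1% (a generic short-read figure; the source
data's error profile is not published).

Defaults emulate the study conditions: ploidy 8 with 7 haplotypes
observed, 564-bp CDS, haplotype radiation 0.5 Myr at the coding rate
(the shallow end of the observed haplotype divergences), equal
expression over all copies, mean coverage 500, 80-bp reads.  The
ploidy-10 preset uses a 2 Myr radiation — the deeper divergence observed
between paralogous haplotypes — plus a duplication at 2.3 Myr (the age
of the oldest dated transposon insertions, a floor for the duplication
age) and an outgroup diverging before it, and silences one sequenced
haplotype.  The radiation model is a star tree: adequate for dosage and
expression truth, but it does not reproduce the nested coalescent
structure of real homeolog sets, and the generator has no recombination,
no gene fusion, no expression noise beyond multinomial sampling, and no
alignment error.  Tests passing on this material therefore validate the
decision rules and estimators, not robustness to misalignment or
assembly artefacts.

## Problem sizes in the test suite

The suite checks the binomial implementation against exact-rational and
integer-arithmetic enumeration for all `k` at `n <= 200` over the null
proportions used in the analysis; NJ against an exhaustive-topology
least-squares oracle for up to 6 leaves; clock recovery over 200
replicates of 2-kb sequences (divergence 3 Myr, LTR age 2.3 Myr); null
calibration of the dosage test over 2000 replicates at `n = 500`
(rejection rate at most 0.065, the exact test being conservative); and
the silenced-haplotype classification over 100 simulated replicates at
depth 500, ploidy 10.  These sizes were chosen as the smallest that make
the statistical assertions sharp.

## Known limitations

* Read placement trusts exact substring matches; repetitive CDS regions
  longer than a read would misplace reads (not an issue for the locus
  sizes simulated here).
* The dosage test conditions on the published coverage; it does not
  model mapping bias between alleles.
* NG86 is the only codon model; no rate heterogeneity, no ML distances.
* The homeolog collapse aligns unequal-length inputs pairwise with a
  fixed scoring scheme; for distant sequences a curated alignment should
  be supplied instead.
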