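# haplodose

Allele-dosage and haplotype analysis for polyploid loci.

Highly polyploid genomes such as sugarcane (*Saccharum* hybrids,
2n ≈ 112) carry each locus in many homeologous copies — 8 or 10 at the
loci that motivated this package — and clone-based sequencing typically
recovers one copy fewer than cytology says exist.  `haplodose` answers
the questions that situation raises:

* which distinct haplotypes exist at a region, and how do they differ
  (SNPs, multibase substitutions, indels, frameshifts, premature stops);
* which gene haplotypes are expressed, inferred from transcriptome reads
  under a 100%-identity rule over haplotype-exclusive SNPs;
* does the genomic allele dosage explain the transcriptome allele ratio,
  given that one haplotype is missing from the sequenced set;
* when did a duplication or an LTR retrotransposon insertion happen, and
  where does a duplicated segment sit on a tree.

A synthetic-data generator simulates polyploid loci, duplication
scenarios, LTR pairs and allele-specific read sets with known truth, so
the entire pipeline is testable offline.

## The dosage test

For a SNP with `k` variant reads out of `n`, in a region of ploidy `P`
with `H` haplotypes sequenced, the missing copy either carries the
common allele (genomic variant dosage `v = x`, the count among sequenced
haplotypes) or the variant allele (`v = x + 1`); a SNP seen only in the
transcriptome pins it to the missing copy (`v = P − H`, both hypotheses
coincide).  Each hypothesis is scored with the exact two-sided binomial
test of `k/n` against the exact fraction `v/P` (small-probability
summation, as in R's `binom.test`), accepting the null at `p ≥ 0.05`:
acceptance means the genomic dosage explains the transcriptome ratio.
Distances use JC69 / K2P for nucleotides and NG86 (dS, dN with JC
correction) for coding sequence; dating is the strict clock
`T = d / 2r`; trees are neighbor joining, exact on additive matrices.

## Worked example

The per-SNP count tables published for the sugarcane *HP600* and
*CENP-C* genes (Region01: ploidy 8, seven haplotypes recovered) ship
with the package:

```python
from haplodose import datasets
from haplodose.dosage import run_dosage_table

table, summary = run_dosage_table(datasets.load_cenpc_snp_counts())
print(summary.n_accepted, "of", summary.n_testable, "SNPs accept a hypothesis")
row = table.set_index("SNP").loc[1]
print(f"SNP 1: {row.VariantCoverage}/{row.Coverage} reads, "
      f"p = {row.Pvalue1:.3g} (missing copy common, v=5/8), "
      f"p = {row.Pvalue2:.3g} (missing copy variant, v=4/8)")
```

prints

```
17 of 24 SNPs accept a hypothesis
SNP 1: 13/16 reads, p = 0.195 (missing copy common, v=5/8), p = 0.0213 (missing copy variant, v=4/8)
```

— SNP 1's transcriptome ratio (13/16 ≈ 0.81) is consistent with the
missing haplotype carrying the common allele (5 variant copies of 8,
p = 0.195 ≥ 0.05) and inconsistent with it carrying the variant
(p = 0.0213), and 17 of the 24 sites outside the duplicated segment are
explained by at least one dosage hypothesis — the haplotypes of this
region are expressed in proportion to their genomic dosage.

The same machinery runs end to end on simulated data:

```sh
haplodose simulate --preset region01 --seed 42 --out sim/
haplodose catalog --alignment sim/haplotypes_truth.fasta --out catalog/
haplodose dosage --counts mycounts.tsv --ploidy 8 --observed 7 --out dosage.tsv
haplodose tree --alignment sim/haplotypes_truth.fasta --outgroup H01 --out tree.nwk
```

## Layout

| module | contents |
| --- | --- |
| `haplodose.catalog` | alignments, variant calling, SNP density, diagnostic SNPs, homeolog collapse, gene haplotypes, frameshifts |
| `haplodose.expression` | read assignment, per-SNP tallies, expression calls |
| `haplodose.dosage` | exact binomial test, dosage hypotheses, table driver |
| `haplodose.clock` | p/JC69/K2P/NG86 distances, `T = d/2r`, LTR ages |
| `haplodose.phylogeny` | distance matrices, neighbor joining, rooting, monophyly |
| `haplodose.simulate` | JC sequence evolution, locus/duplication/read/LTR simulation |
| `haplodose.datasets` | the bundled published per-SNP count tables |

See `docs/methods.md` for the model conventions and their rationale.
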