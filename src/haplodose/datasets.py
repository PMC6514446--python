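"""Published per-SNP transcriptome count tables for the study loci.

The sugarcane *HP600* / *CENP-C* study printed, for every SNP of the two
genes in Region01, the transcriptome coverage, variant read count,
whether the SNP was seen among the sequenced genomic haplotypes, and the
genomic dosage of each missing-haplotype hypothesis (ploidy 8, seven
haplotypes recovered).  Those tables are bundled here so the dosage test
can be exercised end to end without any external download.

Notes on the transcription:

* Deletion-type rows carry their printed coverage counts directly; the
  positional read tally in :mod:`haplodose.expression` does not produce
  counts for indels.
* The *CENP-C* table's SNP 35 prints genomic proportions of 0.57 for
  both hypotheses, implying a 7-copy context for that site; its
  explicit ``GenomicTotal`` columns are therefore 7.
* Rows inside the segment duplicated into Region02 are flagged
  ``InDuplication`` and carry no hypothesis columns: their transcriptome
  counts mix reads from two loci and cannot be dosage-tested.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from haplodose.dosage import PloidyContext

#: locus ploidies fixed by cytology (BAC-FISH signal counts)
REGION01 = PloidyContext("Region01", ploidy=8, observed_haplotypes=7)
REGION02 = PloidyContext("Region02", ploidy=10, observed_haplotypes=9)


def _load(name: str) -> pd.DataFrame:
    path = resources.files("haplodose.data") / name
    with resources.as_file(path) as p:
        df = pd.read_csv(
            p,
            sep="\t",
            dtype={"GenomicDetected": "boolean", "InDuplication": "boolean"},
        )
    df["GenomicDetected"] = df["GenomicDetected"].astype(bool)
    df["InDuplication"] = df["InDuplication"].fillna(False).astype(bool)
    return df


def load_hp600_snp_counts() -> pd.DataFrame:
    """SNP counts for the *HP600* gene, Region01 (12 sites, ploidy 8)."""
    return _load("hp600_region01_snp_counts.tsv")


def load_cenpc_snp_counts() -> pd.DataFrame:
    """SNP counts for *CENP-C*, Region01 frame (50 sites; 27 lie in the
    segment duplicated into Region02 and are excluded from testing)."""
    return _load("cenpc_region01_snp_counts.tsv")
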