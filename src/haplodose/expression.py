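"""Allele-specific expression evidence from transcriptome reads.

Reads are assigned to gene haplotypes under a 100%-identity rule (exact
substring match against each haplotype CDS, both strands, with ``N`` in
a read matching any base).  Per-SNP coverage and variant coverage are
tallied in reference CDS coordinates, a SNP counts as observed in the
transcriptome when at least ``min_reads`` reads carry its variant state
(default 6), and each gene haplotype is classified as expressed /
not_expressed / undetermined:

* expressed — reads cover the entire gene consistently with the
  haplotype, or at least one haplotype-exclusive SNP passes the read
  threshold;
* not_expressed — the gene shows coverage but none of the haplotype's
  exclusive SNPs are observed;
* undetermined — the haplotype has no exclusive SNPs (or no coverage at
  them) and cannot be distinguished.

The positional tally assumes the haplotype CDSs share a common
coordinate frame (no indels among them); indel variants are skipped with
a warning — for table-style inputs their counts are supplied directly.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from haplodose.catalog import VariantRecord
from haplodose.errors import InputError

DEFAULT_MIN_READS = 6


@dataclass(frozen=True)
class ReadSet:
    """Transcriptome reads from one source tissue."""

    reads: tuple[tuple[str, str], ...]
    source: str = ""

    def __post_init__(self) -> None:
        for rid, seq in self.reads:
            if not rid:
                raise InputError("empty read id")
            if set(seq) - set("ACGTN"):
                raise InputError(f"read {rid} has characters outside ACGTN")


@dataclass(frozen=True)
class ReadAssignment:
    """Placement of one read: matched haplotypes and CDS offset."""

    read_id: str
    sequence: str  # oriented to the CDS strand
    haplotypes: frozenset[str]
    start: int | None  # 0-based CDS offset; None if unassigned

    @property
    def status(self) -> str:
        if not self.haplotypes:
            return "unassigned"
        return "assigned"


@dataclass(frozen=True)
class AlleleCount:
    """Transcriptome coverage of one variant allele (1-based CDS position).

    ``variant_state`` disambiguates multi-allelic sites, where several
    records share a position but count different minority states.
    """

    position: int
    coverage: int
    variant_coverage: int
    detected_in_genome: bool = True
    variant_state: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.variant_coverage <= self.coverage:
            raise InputError(
                f"variant coverage {self.variant_coverage} outside "
                f"[0, {self.coverage}] at position {self.position}"
            )


@dataclass(frozen=True)
class ExpressionCall:
    gene_haplotype: str
    status: str  # expressed | not_expressed | undetermined
    evidence: str  # full_coverage | exclusive_snps | none
    exclusive_observed: int = 0
    exclusive_total: int = 0

    def __post_init__(self) -> None:
        if self.status == "expressed" and self.evidence == "none":
            raise InputError("an expressed call needs evidence")


# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------


def _find(read: str, cds: str) -> int:
    """Leftmost exact-match offset of ``read`` in ``cds`` (N wildcard), or -1."""
    if "N" not in read:
        return cds.find(read)
    m = re.search(read.replace("N", "."), cds)
    return m.start() if m else -1


def assign_reads(
    reads: ReadSet | Iterable[tuple[str, str]],
    haplotype_cds: Mapping[str, str],
) -> list[ReadAssignment]:
    """Assign each read to every haplotype CDS containing it exactly.

    Both strands are searched; a read matching no haplotype is
    unassigned, one matching all haplotypes is shared evidence.
    Deterministic and independent of read order.
    """
    if not haplotype_cds:
        raise InputError("empty haplotype set")
    items = reads.reads if isinstance(reads, ReadSet) else tuple(reads)
    out = []
    for rid, seq in items:
        seq = seq.upper()
        rc = str(Seq(seq).reverse_complement())
        matched: dict[str, int] = {}
        oriented = seq
        for hap in sorted(haplotype_cds):
            pos = _find(seq, haplotype_cds[hap])
            if pos < 0:
                pos = _find(rc, haplotype_cds[hap])
                if pos >= 0:
                    oriented = rc
            if pos >= 0:
                matched[hap] = pos
        start = min(matched.values()) if matched else None
        out.append(
            ReadAssignment(
                read_id=rid,
                sequence=oriented,
                haplotypes=frozenset(matched),
                start=start,
            )
        )
    return out


# ---------------------------------------------------------------------------
# per-SNP tallies
# ---------------------------------------------------------------------------


def tally_allele_counts(
    assignments: Sequence[ReadAssignment],
    variants: Sequence[VariantRecord],
    cds_length: int | None = None,
) -> list[AlleleCount]:
    """Coverage and variant coverage at each variant site.

    Coverage counts assigned reads overlapping the position; variant
    coverage counts those whose base(s) at the site equal the variant
    state.  Reads showing ``N`` at the site count toward coverage only.
    """
    counts = []
    for var in variants:
        state = var.variant_state
        if "-" in state or "-" in var.common_state:
            warnings.warn(
                f"skipping indel variant at position {var.position}: positional "
                "tallies need a gap-free coordinate frame",
                stacklevel=2,
            )
            continue
        if cds_length is not None and var.position > cds_length:
            warnings.warn(
                f"variant position {var.position} outside CDS (length {cds_length})",
                stacklevel=2,
            )
            continue
        width = len(state)
        cov = var_cov = 0
        for a in assignments:
            if a.start is None:
                continue
            lo = a.start + 1  # 1-based first covered position
            hi = a.start + len(a.sequence)
            if not (lo <= var.position and var.position + width - 1 <= hi):
                continue
            cov += 1
            offset = var.position - 1 - a.start
            observed = a.sequence[offset : offset + width]
            if observed == state:
                var_cov += 1
        counts.append(
            AlleleCount(
                position=var.position,
                coverage=cov,
                variant_coverage=var_cov,
                detected_in_genome=True,
                variant_state=state,
            )
        )
    return counts


def snp_detected(count: AlleleCount, min_reads: int = DEFAULT_MIN_READS) -> bool:
    """A SNP counts as present in the transcriptome at >= ``min_reads``."""
    return count.variant_coverage >= min_reads


# ---------------------------------------------------------------------------
# expression classification
# ---------------------------------------------------------------------------


def full_gene_coverage(
    assignments: Sequence[ReadAssignment], haplotype: str, cds_length: int
) -> bool:
    """True when every CDS position is covered by a read consistent with
    the haplotype (assigned to a set containing it)."""
    covered = np.zeros(cds_length, dtype=bool)
    for a in assignments:
        if a.start is None or haplotype not in a.haplotypes:
            continue
        covered[a.start : a.start + len(a.sequence)] = True
    return bool(covered.all())


def classify_expression(
    gene_haplotype: str,
    counts: Sequence[AlleleCount],
    exclusive_positions: Iterable[int],
    full_coverage: bool,
    min_reads: int = DEFAULT_MIN_READS,
) -> ExpressionCall:
    """Classify one gene haplotype from its exclusive-SNP evidence.

    ``exclusive_positions`` are the sites whose variant state is carried
    only by this haplotype, given either as positions or as
    ``(position, variant_state)`` pairs — the latter is required at
    multi-allelic sites where several tallies share a position.
    ``counts`` are the tallies at (at least) those sites.
    """
    exclusive = sorted(set(exclusive_positions))

    def lookup(key):
        if isinstance(key, tuple):
            pos, state = key
            for c in counts:
                if c.position == pos and c.variant_state == state:
                    return c
            return None
        for c in counts:
            if c.position == key:
                return c
        return None

    found = {key: lookup(key) for key in exclusive}
    observed = sum(
        1
        for c in found.values()
        if c is not None and snp_detected(c, min_reads)
    )
    if full_coverage:
        return ExpressionCall(
            gene_haplotype, "expressed", "full_coverage", observed, len(exclusive)
        )
    if not exclusive:
        return ExpressionCall(gene_haplotype, "undetermined", "none")
    if observed > 0:
        return ExpressionCall(
            gene_haplotype, "expressed", "exclusive_snps", observed, len(exclusive)
        )
    any_coverage = any(c.coverage > 0 for c in found.values() if c is not None)
    if any_coverage:
        return ExpressionCall(
            gene_haplotype, "not_expressed", "none", 0, len(exclusive)
        )
    return ExpressionCall(gene_haplotype, "undetermined", "none", 0, len(exclusive))


def call_expression(
    reads: ReadSet | Iterable[tuple[str, str]],
    haplotype_cds: Mapping[str, str],
    variants: Sequence[VariantRecord],
    min_reads: int = DEFAULT_MIN_READS,
) -> dict[str, ExpressionCall]:
    """End-to-end expression calls for every haplotype of one gene."""
    assignments = assign_reads(reads, haplotype_cds)
    counts = tally_allele_counts(assignments, variants)
    lengths = {len(s) for s in haplotype_cds.values()}
    cds_length = max(lengths)
    calls = {}
    for hap in sorted(haplotype_cds):
        exclusive = [
            (v.position, v.variant_state)
            for v in variants
            if v.carriers == frozenset({hap}) and "-" not in v.variant_state
        ]
        if not exclusive:
            # indistinguishable: shared reads cover it, but none are its own
            calls[hap] = ExpressionCall(hap, "undetermined", "none")
            continue
        full = full_gene_coverage(assignments, hap, cds_length)
        calls[hap] = classify_expression(hap, counts, exclusive, full, min_reads)
    return calls
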