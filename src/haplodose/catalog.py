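"""Haplotype catalogue for homeologous regions.

Loads aligned haplotype sequences of one region, calls variants among
them (SNPs, multibase substitutions, insertions, deletions and
tandem-repeat deletions), measures SNP density, finds region-diagnostic
sites, collapses near-identical homeologs, groups gene haplotypes by
identical CDS, and screens coding sequences for frameshifts and
premature stop codons.

Coordinates are 1-based and closed, reported on the ungapped sequence of
a designated reference haplotype.  Variant polarity is majority-rules:
the "common" state is the most frequent among observed haplotypes (ties
broken lexicographically) and each minority state yields one record
carrying its set of carrier haplotypes.  ``N`` bases never create
variants and never count as matches.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from haplodose.errors import (
    AlignmentError,
    AnnotationError,
    ConfigError,
    InputError,
)

ALPHABET = set("ACGTN-")
_TRANSITIONS = ({"A", "G"}, {"C", "T"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionAlignment:
    """Aligned haplotypes of one homeologous region.

    Parameters
    ----------
    region_id:
        Label of the region (e.g. ``"Region01"``).
    haplotypes:
        Ordered ``(haplotype_id, aligned sequence)`` pairs over the
        alphabet ``{A, C, G, T, -, N}``; all sequences equal length.
    reference_id:
        Haplotype whose ungapped coordinates anchor variant positions.
    duplication:
        Optional 1-based closed interval, in reference coordinates, of a
        segment shared with another region; variants inside it are
        flagged ``in_duplication``.
    """

    region_id: str
    haplotypes: tuple[tuple[str, str], ...]
    reference_id: str
    duplication: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.haplotypes) < 2:
            raise AlignmentError("an alignment needs at least 2 haplotypes")
        lengths = {len(s) for _, s in self.haplotypes}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        ids = [h for h, _ in self.haplotypes]
        dup = [h for h, c in Counter(ids).items() if c > 1]
        if dup:
            raise InputError(f"duplicate haplotype ids: {dup}")
        if self.reference_id not in ids:
            raise InputError(f"reference {self.reference_id!r} not in alignment")
        bad = set("".join(s for _, s in self.haplotypes)) - ALPHABET
        if bad:
            raise AlignmentError(f"illegal characters in alignment: {sorted(bad)}")

    @property
    def columns(self) -> int:
        return len(self.haplotypes[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(h for h, _ in self.haplotypes)

    def sequence(self, haplotype_id: str) -> str:
        for h, s in self.haplotypes:
            if h == haplotype_id:
                return s
        raise InputError(f"unknown haplotype {haplotype_id!r}")

    @property
    def reference(self) -> str:
        return self.sequence(self.reference_id)

    def ungapped(self, haplotype_id: str) -> str:
        return self.sequence(haplotype_id).replace("-", "")


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene on the reference haplotype.

    Exons are 1-based closed intervals, non-overlapping and sorted; the
    summed exon length must be a multiple of three for the annotated
    reference.  ``expected_protein_length`` counts amino acids before
    the stop codon.
    """

    gene_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    expected_protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be + or -, got {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start > end or start <= prev_end:
                raise AnnotationError(
                    f"exons of {self.gene_id} must be sorted and non-overlapping"
                )
            prev_end = end
        if self.cds_length % 3 != 0:
            raise AnnotationError(
                f"CDS length {self.cds_length} of {self.gene_id} not a multiple of 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    def extract_cds(self, sequence: str) -> str:
        """Splice the CDS out of an ungapped reference-frame sequence."""
        if self.exons[-1][1] > len(sequence):
            raise AnnotationError(
                f"exon of {self.gene_id} extends past sequence end "
                f"({self.exons[-1][1]} > {len(sequence)})"
            )
        spliced = "".join(sequence[s - 1 : e] for s, e in self.exons)
        if self.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        return spliced


@dataclass(frozen=True)
class VariantRecord:
    """One polymorphic site (or merged run of sites).

    ``position`` is the 1-based reference coordinate of the first
    aligned column of the run; ``span`` is the 0-based inclusive
    alignment-column interval it was called from (kept so haplotypes can
    be reconstructed from the common backbone).
    """

    position: int
    kind: str
    common_state: str
    variant_state: str
    carriers: frozenset[str]
    in_duplication: bool = False
    span: tuple[int, int] = (0, 0)

    KINDS = (
        "snp_transition",
        "snp_transversion",
        "substitution_multibase",
        "insertion",
        "deletion",
        "deletion_tandem_repeat",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise InputError(f"unknown variant kind {self.kind!r}")
        if self.common_state == self.variant_state:
            raise InputError("common and variant state must differ")

    @property
    def change(self) -> str:
        return f"{self.common_state} -> {self.variant_state}"


@dataclass(frozen=True)
class DiversityReport:
    """SNP density of a region: variants per aligned base."""

    n_variants: int
    reference_length: int
    diagnostic_variants: tuple[VariantRecord, ...] = ()

    @property
    def defined(self) -> bool:
        return self.n_variants > 0

    @property
    def bases_per_variant(self) -> float | None:
        if not self.defined:
            return None
        return self.reference_length / self.n_variants


@dataclass(frozen=True)
class FrameshiftReport:
    """Translation screen of one CDS against its expected protein length."""

    protein_length: int
    premature_stop: bool
    frameshift: bool
    has_stop: bool


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_region_alignment(
    fasta_path: str | Path,
    metadata: pd.DataFrame | str | Path | None = None,
    region_id: str = "region",
    reference_id: str | None = None,
    duplication: tuple[int, int] | None = None,
) -> RegionAlignment:
    """Load an aligned multi-FASTA into a :class:`RegionAlignment`.

    ``metadata``, if given, is a TSV (or DataFrame) with columns
    ``haplotype_id`` and ``region_id``; only haplotypes of ``region_id``
    are kept.  The reference defaults to the first record.
    """
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(fasta_path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {fasta_path}")
    if metadata is not None:
        if not isinstance(metadata, pd.DataFrame):
            metadata = pd.read_csv(metadata, sep="\t", dtype=str)
        keep = set(
            metadata.loc[metadata["region_id"] == region_id, "haplotype_id"]
        )
        records = [(h, s) for h, s in records if h in keep]
        if not records:
            raise InputError(f"no haplotypes assigned to region {region_id!r}")
    if reference_id is None:
        reference_id = records[0][0]
    return RegionAlignment(
        region_id=region_id,
        haplotypes=tuple(records),
        reference_id=reference_id,
        duplication=duplication,
    )


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------


def _column_events(aln: RegionAlignment):
    """Per-column minority events: (col, common, variant, carriers)."""
    ids = aln.ids
    seqs = [s for _, s in aln.haplotypes]
    for col in range(aln.columns):
        states: dict[str, list[str]] = {}
        for hap, seq in zip(ids, seqs):
            ch = seq[col]
            if ch == "N":
                continue
            states.setdefault(ch, []).append(hap)
        if len(states) < 2:
            continue
        # majority state; ties broken lexicographically (smallest = common)
        common = min(states, key=lambda s: (-len(states[s]), s))
        for state, carriers in sorted(states.items()):
            if state == common:
                continue
            yield col, common, state, frozenset(carriers)


def _ref_position(ref: str, col: int) -> int:
    """1-based ungapped reference coordinate of alignment column ``col``."""
    pos = sum(1 for ch in ref[: col + 1] if ch != "-")
    return max(pos, 1)


def _classify(common: str, variant: str, ref_context: str, ref_pos: int) -> str:
    if set(variant) == {"-"}:
        # deletion; tandem-repeat if the deleted motif repeats next to it
        motif = common
        k = len(motif)
        before = ref_context[max(ref_pos - 1 - k, 0) : ref_pos - 1]
        after = ref_context[ref_pos - 1 + k : ref_pos - 1 + 2 * k]
        if motif and (before == motif or after == motif):
            return "deletion_tandem_repeat"
        return "deletion"
    if set(common) == {"-"}:
        return "insertion"
    if len(common) == 1:
        pair = {common, variant}
        return "snp_transition" if pair in _TRANSITIONS else "snp_transversion"
    return "substitution_multibase"


def call_variants(aln: RegionAlignment) -> list[VariantRecord]:
    """Call variants among the haplotypes of an alignment.

    One record per polymorphic column run: contiguous gap runs collapse
    to a single insertion/deletion and adjacent substituted columns with
    an identical carrier set collapse to one multibase substitution
    (e.g. ``GG -> TT``).  Output is ordered by alignment column.
    """
    ref = aln.reference
    ref_ungapped = ref.replace("-", "")

    def category(common: str, variant: str) -> str:
        if variant == "-":
            return "del"
        if common == "-":
            return "ins"
        return "sub"

    runs: list[dict] = []
    open_runs: dict[tuple[frozenset, str], dict] = {}
    for col, common, variant, carriers in _column_events(aln):
        key = (carriers, category(common, variant))
        run = open_runs.get(key)
        if run is not None and run["end"] == col - 1:
            run["end"] = col
            run["common"] += common
            run["variant"] += variant
        else:
            run = {
                "start": col,
                "end": col,
                "common": common,
                "variant": variant,
                "carriers": carriers,
            }
            open_runs[key] = run
            runs.append(run)
        # close runs that did not extend into this column
        for k, r in list(open_runs.items()):
            if r["end"] < col - 1:
                del open_runs[k]

    records = []
    for run in sorted(runs, key=lambda r: (r["start"], r["variant"])):
        pos = _ref_position(ref, run["start"])
        kind = _classify(run["common"], run["variant"], ref_ungapped, pos)
        in_dup = bool(
            aln.duplication and aln.duplication[0] <= pos <= aln.duplication[1]
        )
        records.append(
            VariantRecord(
                position=pos,
                kind=kind,
                common_state=run["common"],
                variant_state=run["variant"],
                carriers=run["carriers"],
                in_duplication=in_dup,
                span=(run["start"], run["end"]),
            )
        )
    return records


def reconstruct_haplotypes(aln: RegionAlignment, variants: Sequence[VariantRecord]) -> dict[str, str]:
    """Rebuild every haplotype from the common backbone plus variants.

    Inverse of :func:`call_variants` on N-free alignments; used as a
    round-trip check.
    """
    backbone = []
    for col in range(aln.columns):
        states = Counter(
            seq[col] for _, seq in aln.haplotypes if seq[col] != "N"
        )
        if not states:
            backbone.append("N")
            continue
        top = max(states.values())
        backbone.append(min(s for s, c in states.items() if c == top))
    result = {}
    for hap in aln.ids:
        chars = list(backbone)
        for rec in variants:
            if hap in rec.carriers:
                start, end = rec.span
                chars[start : end + 1] = list(rec.variant_state)
        result[hap] = "".join(chars)
    return result


def snp_density(aln: RegionAlignment, variants: Sequence[VariantRecord]) -> DiversityReport:
    """Aligned bases per variant, on the ungapped reference length."""
    ref_len = len(aln.reference.replace("-", ""))
    return DiversityReport(n_variants=len(variants), reference_length=ref_len)


def diagnostic_variants(
    aln_region1: RegionAlignment, aln_region2: RegionAlignment
) -> list[VariantRecord]:
    """Sites fixed-different between two regions sharing a coordinate frame.

    Returns the variants of the concatenated alignment whose carrier set
    is exactly one region's full haplotype set (every haplotype of one
    region carries one state and every haplotype of the other carries
    another).
    """
    if aln_region1.columns != aln_region2.columns:
        raise InputError(
            "regions are not on a common coordinate frame "
            f"({aln_region1.columns} vs {aln_region2.columns} columns)"
        )
    ids1, ids2 = set(aln_region1.ids), set(aln_region2.ids)
    if ids1 & ids2:
        raise InputError(f"haplotype ids shared between regions: {ids1 & ids2}")
    combined = RegionAlignment(
        region_id=f"{aln_region1.region_id}+{aln_region2.region_id}",
        haplotypes=aln_region1.haplotypes + aln_region2.haplotypes,
        reference_id=aln_region1.reference_id,
        duplication=aln_region1.duplication,
    )
    return [
        rec
        for rec in call_variants(combined)
        if rec.carriers == ids1 or rec.carriers == ids2
    ]


# ---------------------------------------------------------------------------
# homeolog collapse and gene haplotypes
# ---------------------------------------------------------------------------


def pairwise_identity(a: str, b: str) -> float:
    """Identity of two aligned sequences.

    Matches over columns, excluding columns gapped in both sequences;
    ``N`` never counts as a match.  Unequal-length inputs are aligned
    globally first.
    """
    if len(a) != len(b):
        a, b = _align_pair(a, b)
    matches = compared = 0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        compared += 1
        if x == y and x not in "N-":
            matches += 1
    if compared == 0:
        raise InputError("no comparable columns between sequences")
    return matches / compared


def _align_pair(a: str, b: str) -> tuple[str, str]:
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-0.5,
    )
    best = aligner.align(a, b)[0]
    return str(best[0]), str(best[1])


def collapse_homeologs(
    sequences: Iterable[tuple[str, str]], identity_threshold: float = 0.99
) -> list[list[str]]:
    """Single-linkage grouping of sequences above an identity threshold.

    Clone sequences with pairwise identity above the threshold (default
    99%) are considered the same homeolog; groups are reported in input
    order of their first member.
    """
    if not 0 < identity_threshold <= 1:
        raise ConfigError(f"identity threshold must be in (0, 1], got {identity_threshold}")
    seqs = list(sequences)
    ids = [h for h, _ in seqs]
    parent = list(range(len(seqs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if pairwise_identity(seqs[i][1], seqs[j][1]) > identity_threshold:
                parent[find(j)] = find(i)

    groups: dict[int, list[str]] = {}
    for i, hap in enumerate(ids):
        groups.setdefault(find(i), []).append(hap)
    return [groups[r] for r in sorted(groups, key=lambda r: ids.index(groups[r][0]))]


def group_gene_haplotypes(cds_sequences: Iterable[tuple[str, str]]) -> list[list[str]]:
    """Group haplotypes whose spliced CDS strings are identical.

    Genes with the same coding sequence in different clone haplotypes
    count as one gene haplotype; group order follows input order.
    """
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for hap, cds in cds_sequences:
        if cds not in groups:
            groups[cds] = []
            order.append(cds)
        groups[cds].append(hap)
    return [groups[c] for c in order]


# ---------------------------------------------------------------------------
# frameshift / premature stop detection
# ---------------------------------------------------------------------------

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


def translate_cds(cds: str) -> str:
    """Translate from the first codon; ambiguous codons become ``X``.

    Trailing partial codons are ignored; stops are written as ``*``.
    """
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3].upper()
        if codon in _STOPS:
            protein.append("*")
        else:
            protein.append(_CODON_TABLE.get(codon, "X"))
    return "".join(protein)


def detect_frameshift(cds: str, expected_protein_length: int) -> FrameshiftReport:
    """Screen a CDS for frameshifts and premature stop codons.

    ``protein_length`` counts codons before the first stop.  A stop
    before the expected protein length flags ``premature_stop``; a CDS
    length that is not a multiple of three, or differs from
    ``3 * (expected + 1)`` (protein plus stop codon), flags
    ``frameshift``.  A CDS that never reaches a stop is reported with
    ``has_stop=False`` (truncated/incomplete reading frame).
    """
    if len(cds) < 3:
        raise InputError("CDS shorter than one codon")
    protein = translate_cds(cds)
    stop_at = protein.find("*")
    has_stop = stop_at >= 0
    protein_length = stop_at if has_stop else len(protein)
    frameshift = len(cds) % 3 != 0 or len(cds) != 3 * (expected_protein_length + 1)
    premature = has_stop and protein_length < expected_protein_length
    return FrameshiftReport(
        protein_length=protein_length,
        premature_stop=premature,
        frameshift=frameshift,
        has_stop=has_stop,
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def variants_to_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    """Variants as a table with the catalogue's standard columns."""
    return pd.DataFrame(
        {
            "Position": [v.position for v in variants],
            "Name": [v.variant_state for v in variants],
            "Change": [v.change for v in variants],
            "PolymorphismType": [v.kind for v in variants],
            "Carriers": [",".join(sorted(v.carriers)) for v in variants],
            "InDuplication": [v.in_duplication for v in variants],
        }
    )
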