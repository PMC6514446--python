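"""Variant calling, homeolog collapse, gene-haplotype grouping, frameshifts."""

import pytest
from hypothesis import given, strategies as st

from haplodose import catalog
from haplodose.catalog import (
    GeneModel,
    RegionAlignment,
    call_variants,
    collapse_homeologs,
    detect_frameshift,
    diagnostic_variants,
    group_gene_haplotypes,
    load_region_alignment,
    pairwise_identity,
    reconstruct_haplotypes,
    snp_density,
)
from haplodose.errors import (
    AlignmentError,
    AnnotationError,
    ConfigError,
    InputError,
)


class TestRegionAlignment:
    def test_loads_aligned_fasta(self, tmp_path):
        fasta = tmp_path / "aln.fasta"
        fasta.write_text(">h1\nACGTACGTACGT\n>h2\nACGTACGAACGT\n>h3\nACGTACGTACGT\n")
        aln = load_region_alignment(fasta, region_id="r1")
        assert aln.columns == 12
        assert aln.ids == ("h1", "h2", "h3")
        assert aln.reference_id == "h1"

    def test_ragged_lengths_rejected(self, tmp_path):
        fasta = tmp_path / "aln.fasta"
        fasta.write_text(">h1\nACGTACGTACGT\n>h2\nACGTACGTACG\n")
        with pytest.raises(AlignmentError):
            load_region_alignment(fasta)

    def test_empty_file_rejected(self, tmp_path):
        fasta = tmp_path / "aln.fasta"
        fasta.write_text("")
        with pytest.raises(InputError):
            load_region_alignment(fasta)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(InputError):
            RegionAlignment("r", (("h", "ACGT"), ("h", "ACGA")), "h")

    def test_metadata_filters_by_region(self, tmp_path):
        import pandas as pd

        fasta = tmp_path / "aln.fasta"
        fasta.write_text(">h1\nACGT\n>h2\nACGA\n>x1\nACGC\n")
        meta = pd.DataFrame(
            {"haplotype_id": ["h1", "h2", "x1"], "region_id": ["r1", "r1", "r2"]}
        )
        aln = load_region_alignment(fasta, metadata=meta, region_id="r1")
        assert aln.ids == ("h1", "h2")


class TestCallVariants:
    def test_single_snp_transversion(self):
        aln = RegionAlignment("r", (("a", "ACGTACGTAC"), ("b", "ACCTACGTAC")), "a")
        (rec,) = call_variants(aln)
        assert rec.kind == "snp_transversion"
        assert rec.position == 3
        # 1:1 tie in two haplotypes: the lexicographically smaller state
        # is taken as common
        assert rec.change == "C -> G"
        assert rec.carriers == {"a"}

    def test_transition_vs_transversion_kinds(self):
        aln = RegionAlignment(
            "r", (("a", "AAAA"), ("b", "GAAA"), ("c", "AACA"), ("d", "AAAA")), "a"
        )
        kinds = {(v.position, v.kind) for v in call_variants(aln)}
        assert kinds == {(1, "snp_transition"), (3, "snp_transversion")}

    def test_adjacent_substitution_merges_to_multibase(self, small_alignment):
        recs = {v.kind: v for v in call_variants(small_alignment)}
        multi = recs["substitution_multibase"]
        assert multi.change == "GG -> TT"
        assert multi.carriers == {"hapC"}
        assert multi.position == 7

    def test_gap_run_collapses_to_one_deletion(self):
        aln = RegionAlignment(
            "r",
            (
                ("a", "AACGTAA"),
                ("b", "AA---AA"),
                ("c", "AACGTAA"),
                ("d", "AACGTAA"),
            ),
            "a",
        )
        (rec,) = call_variants(aln)
        assert rec.kind == "deletion"
        assert rec.common_state == "CGT"
        assert rec.carriers == {"b"}
        assert rec.position == 3

    def test_tandem_repeat_deletion_flagged(self):
        aln = RegionAlignment(
            "r",
            (("a", "AAGAGGAGGAGTT"), ("b", "AAGAG---GAGTT"), ("c", "AAGAGGAGGAGTT")),
            "a",
        )
        (rec,) = call_variants(aln)
        assert rec.kind == "deletion_tandem_repeat"

    def test_insertion_called_on_minority_bases(self):
        aln = RegionAlignment(
            "r",
            (("a", "AA--AA"), ("b", "AACGAA"), ("c", "AA--AA"), ("d", "AA--AA")),
            "a",
        )
        (rec,) = call_variants(aln)
        assert rec.kind == "insertion"
        assert rec.variant_state == "CG"
        assert rec.carriers == {"b"}

    def test_n_bases_never_create_variants(self):
        aln = RegionAlignment("r", (("a", "ACGT"), ("b", "ACNT"), ("c", "ACGT")), "a")
        assert call_variants(aln) == []

    def test_haplotype_order_invariance(self, small_alignment):
        reversed_aln = RegionAlignment(
            small_alignment.region_id,
            tuple(reversed(small_alignment.haplotypes)),
            small_alignment.reference_id,
        )
        assert set(call_variants(small_alignment)) == set(call_variants(reversed_aln))

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=8, max_size=8), min_size=3, max_size=6
        )
    )
    def test_roundtrip_reconstructs_every_haplotype(self, seqs):
        haps = tuple((f"h{i}", s) for i, s in enumerate(seqs))
        aln = RegionAlignment("r", haps, "h0")
        rebuilt = reconstruct_haplotypes(aln, call_variants(aln))
        assert rebuilt == dict(haps)

    def test_roundtrip_with_gaps(self, small_alignment):
        rebuilt = reconstruct_haplotypes(
            small_alignment, call_variants(small_alignment)
        )
        assert rebuilt == dict(small_alignment.haplotypes)


class TestSnpDensity:
    @pytest.mark.parametrize(
        "length,n,expected", [(560, 8, 70.0), (430, 10, 43.0)]
    )
    def test_bases_per_variant(self, length, n, expected):
        report = catalog.DiversityReport(n_variants=n, reference_length=length)
        assert report.bases_per_variant == expected

    def test_zero_variants_flagged_undefined(self):
        aln = RegionAlignment("r", (("a", "ACGT"), ("b", "ACGT")), "a")
        report = snp_density(aln, [])
        assert not report.defined
        assert report.bases_per_variant is None

    def test_density_uses_ungapped_reference(self):
        aln = RegionAlignment("r", (("a", "AC--GTAT"), ("b", "ACCGGTAA")), "a")
        variants = call_variants(aln)
        report = snp_density(aln, variants)
        assert report.reference_length == 6


class TestDiagnosticVariants:
    def _regions(self):
        r1 = RegionAlignment("R1", (("R1a", "ACGTA"), ("R1b", "ACGTA")), "R1a")
        r2 = RegionAlignment("R2", (("R2a", "AGGTA"), ("R2b", "AGGTA")), "R2a")
        return r1, r2

    def test_fixed_difference_is_diagnostic(self):
        r1, r2 = self._regions()
        (rec,) = diagnostic_variants(r1, r2)
        assert rec.position == 2
        assert rec.carriers == {"R2a", "R2b"}

    def test_segregating_site_is_not_diagnostic(self):
        r1 = RegionAlignment("R1", (("R1a", "ACGTA"), ("R1b", "AGGTA")), "R1a")
        r2 = RegionAlignment("R2", (("R2a", "AGGTA"), ("R2b", "AGGTA")), "R2a")
        assert diagnostic_variants(r1, r2) == []

    def test_identical_regions_give_empty_list(self):
        r1 = RegionAlignment("R1", (("R1a", "ACGTA"), ("R1b", "ACGTA")), "R1a")
        r2 = RegionAlignment("R2", (("R2a", "ACGTA"), ("R2b", "ACGTA")), "R2a")
        assert diagnostic_variants(r1, r2) == []

    def test_mismatched_frames_rejected(self):
        r1 = RegionAlignment("R1", (("R1a", "ACGTA"), ("R1b", "ACGTA")), "R1a")
        r2 = RegionAlignment("R2", (("R2a", "ACGT"), ("R2b", "ACGT")), "R2a")
        with pytest.raises(InputError):
            diagnostic_variants(r1, r2)

    def test_diagnostics_are_subset_of_combined_variants(self):
        r1, r2 = self._regions()
        combined = RegionAlignment(
            "both", r1.haplotypes + r2.haplotypes, r1.reference_id
        )
        all_recs = set(call_variants(combined))
        assert set(diagnostic_variants(r1, r2)) <= all_recs


class TestCollapseHomeologs:
    def _seq_pair(self, n_diff, length=1000):
        a = "ACGT" * (length // 4)
        b = a[:n_diff].translate(str.maketrans("ACGT", "GTAC")) + a[n_diff:]
        return a, b

    def test_above_threshold_merges(self):
        a, b = self._seq_pair(5)  # 99.5% identical
        groups = collapse_homeologs([("x", a), ("y", b)])
        assert groups == [["x", "y"]]

    def test_below_threshold_stays_split(self):
        a, b = self._seq_pair(20)  # 98.0% identical
        groups = collapse_homeologs([("x", a), ("y", b)])
        assert groups == [["x"], ["y"]]

    def test_single_linkage_chains(self):
        # a~b and b~c above threshold, a~c below: one group regardless
        base = "ACGT" * 250
        flip = str.maketrans("ACGT", "GTAC")
        a = base
        b = base[:8].translate(flip) + base[8:]  # a~b 99.2%
        c = base[:16].translate(flip) + base[16:]  # b~c 99.2%, a~c 98.4%
        assert pairwise_identity(a, b) > 0.99
        assert pairwise_identity(b, c) > 0.99
        assert pairwise_identity(a, c) < 0.99
        groups = collapse_homeologs([("a", a), ("b", b), ("c", c)])
        assert groups == [["a", "b", "c"]]

    def test_monotone_in_threshold(self):
        base = "ACGT" * 250
        flip = str.maketrans("ACGT", "GTAC")
        seqs = [
            ("a", base),
            ("b", base[:8].translate(flip) + base[8:]),
            ("c", base[:30].translate(flip) + base[30:]),
        ]
        strict = collapse_homeologs(seqs, 0.99)
        loose = collapse_homeologs(seqs, 0.95)
        # every strict group is contained in one loose group
        loose_sets = [set(g) for g in loose]
        assert all(any(set(g) <= ls for ls in loose_sets) for g in strict)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ConfigError):
            collapse_homeologs([("a", "ACGT"), ("b", "ACGT")], identity_threshold=1.5)


class TestGeneHaplotypes:
    def test_identical_cds_grouped(self):
        groups = group_gene_haplotypes(
            [("I", "ATGAAA"), ("II", "ATGAAA"), ("III", "ATGAAC")]
        )
        assert groups == [["I", "II"], ["III"]]

    def test_seven_haplotypes_collapse_to_four_gene_haplotypes(self):
        # the pattern of the study's HP600 Region01 gene: I/II/VI, IV/V, III, VII
        cds = {
            "I": "ATGAAAGAA",
            "II": "ATGAAAGAA",
            "III": "ATGAACGAA",
            "IV": "ATGAAAGAC",
            "V": "ATGAAAGAC",
            "VI": "ATGAAAGAA",
            "VII": "ATGAAAGAG",
        }
        groups = group_gene_haplotypes(cds.items())
        assert groups == [["I", "II", "VI"], ["III"], ["IV", "V"], ["VII"]]

    def test_all_identical_is_one_group(self):
        assert group_gene_haplotypes([("a", "ATG"), ("b", "ATG")]) == [["a", "b"]]

    def test_exon_extraction_plus_strand(self):
        gene = GeneModel("g", ((1, 3), (5, 7)), strand="+")
        assert gene.extract_cds("ATGACATC") == "ATGCAT"

    def test_exon_extraction_minus_strand(self):
        # exons 2-4 = "CAA" and 6-8 = "GTT" splice to "CAAGTT";
        # the minus strand reads its reverse complement "AACTTG"
        gene = GeneModel("g", ((2, 4), (6, 8)), strand="-")
        assert gene.extract_cds("TCAATGTTA") == "AACTTG"

    def test_out_of_bounds_exon_rejected(self):
        gene = GeneModel("g", ((1, 6),))
        with pytest.raises(AnnotationError):
            gene.extract_cds("ATG")


class TestDetectFrameshift:
    def test_clean_cds(self):
        report = detect_frameshift("ATGAAAGAATAG", expected_protein_length=3)
        assert (report.protein_length, report.premature_stop, report.frameshift) == (
            3,
            False,
            False,
        )

    def test_deletion_shifts_frame_without_stop(self):
        # base 5 deleted from ATGAAAGAATAG: frame shifts, no stop reached
        report = detect_frameshift("ATGAAGAATAG", expected_protein_length=3)
        assert report.frameshift
        assert not report.premature_stop
        assert not report.has_stop

    def test_engineered_premature_stop_at_codon_121(self):
        # 1-bp deletion scenario: an in-frame TAA appears at codon 121 of a
        # CDS annotated for a 187-residue protein
        cds = "ATG" + "GGC" * 119 + "TAA" + "GGC" * 66 + "TT"
        assert len(cds) == 563  # one base short of 564
        report = detect_frameshift(cds, expected_protein_length=187)
        assert report.protein_length == 120
        assert report.premature_stop
        assert report.frameshift

    def test_ambiguous_codon_translates_as_x(self):
        assert catalog.translate_cds("ATGANA") == "MX"
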