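"""Tests for dosage quantification: codon counting, VCF VAF, CNV
adjustment, clonality, cohort profiles."""

import numpy as np
import pandas as pd
import pysam
import pytest

from conftest import CODON_START1, G12D_READ, READ_START1, SYN_READ, WT_READ
from krasdose.dosage import (
    G12_HG19,
    AlleleCounts,
    CopyNumberState,
    TargetLocus,
    adjust_for_cnv,
    build_dosage_profiles,
    classify_clonality,
    compute_dosage,
    count_alleles_at_codon,
    vaf_from_vcf,
)
from krasdose.simulate import SimulationConfig, generate_cohort


class TestTargetLocus:
    def test_default_g12_locus_is_printed_hg19_coordinates(self):
        assert G12_HG19.chrom == "chr12"
        assert G12_HG19.codon_positions == (25_398_283, 25_398_284, 25_398_285)
        assert G12_HG19.build == "hg19"
        assert G12_HG19.reference_aa == "G"  # glycine at codon 12

    def test_nonconsecutive_positions_rejected(self):
        with pytest.raises(ValueError):
            TargetLocus("chr12", (1, 3, 5), "ACC", "-", "hg19")

    def test_reverse_strand_translation(self):
        assert G12_HG19.amino_acid("ATC") == "D"  # G12D
        assert G12_HG19.amino_acid("GCC") == "G"  # synonymous


class TestCountAlleles:
    def test_known_mixture_counts(self, sam_factory):
        reads = [(f"wt{i}", 0, READ_START1, 60, "50M", WT_READ, "I") for i in range(7)]
        reads += [(f"mut{i}", 0, READ_START1, 60, "50M", G12D_READ, "I") for i in range(3)]
        path = sam_factory(reads)
        c = count_alleles_at_codon(path, G12_HG19)
        assert (c.mutant_reads, c.wildtype_reads, c.other_reads) == (3, 7, 0)

    def test_low_mapq_reads_excluded_entirely(self, sam_factory):
        reads = [(f"r{i}", 0, READ_START1, 5, "50M", WT_READ, "I") for i in range(4)]
        c = count_alleles_at_codon(sam_factory(reads), G12_HG19, min_mapq=20)
        assert c.total == 0

    def test_synonymous_counts_as_other(self, sam_factory):
        reads = [("syn", 0, READ_START1, 60, "50M", SYN_READ, "I")]
        c = count_alleles_at_codon(sam_factory(reads), G12_HG19)
        assert (c.mutant_reads, c.wildtype_reads, c.other_reads) == (0, 0, 1)

    def test_partial_span_counts_as_other(self, sam_factory):
        # read ends inside the codon (covers only its first base)
        short = WT_READ[:21]
        reads = [("partial", 0, READ_START1, 60, f"{len(short)}M", short, "I")]
        c = count_alleles_at_codon(sam_factory(reads), G12_HG19)
        assert (c.mutant_reads, c.wildtype_reads, c.other_reads) == (0, 0, 1)

    def test_deletion_over_codon_counts_as_other(self, sam_factory):
        seq = WT_READ[:20] + WT_READ[23:]  # codon deleted
        reads = [("del", 0, READ_START1, 60, "20M3D27M", seq, "I")]
        c = count_alleles_at_codon(sam_factory(reads), G12_HG19)
        assert (c.mutant_reads, c.wildtype_reads, c.other_reads) == (0, 0, 1)

    def test_n_base_counts_as_other(self, sam_factory):
        seq = WT_READ[:21] + "N" + WT_READ[22:]
        reads = [("nn", 0, READ_START1, 60, "50M", seq, "I")]
        c = count_alleles_at_codon(sam_factory(reads), G12_HG19)
        assert (c.mutant_reads, c.wildtype_reads, c.other_reads) == (0, 0, 1)

    def test_low_baseq_read_excluded(self, sam_factory):
        reads = [("lowq", 0, READ_START1, 60, "50M", WT_READ, "#")]  # Q2
        c = count_alleles_at_codon(sam_factory(reads), G12_HG19, min_baseq=20)
        assert c.total == 0

    def test_deterministic_recount(self, sam_factory):
        reads = [(f"r{i}", 0, READ_START1, 60, "50M", G12D_READ if i % 3 else WT_READ, "I")
                 for i in range(30)]
        path = sam_factory(reads)
        a = count_alleles_at_codon(path, G12_HG19)
        b = count_alleles_at_codon(path, G12_HG19)
        assert a == b

    def test_missing_contig_is_input_error(self, tmp_path):
        p = tmp_path / "other.sam"
        p.write_text("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n")
        with pytest.raises(ValueError, match="contig"):
            count_alleles_at_codon(p, G12_HG19)


class TestComputeDosage:
    def test_zero_mutant(self):
        assert compute_dosage(AlleleCounts(0, 120, 0)) == 0.0

    def test_printed_threshold_fraction(self):
        # 39/(39+161) is exactly the primary high/low threshold
        assert compute_dosage(AlleleCounts(39, 161, 0)) == pytest.approx(0.195)

    def test_zero_total_is_undefined(self):
        assert compute_dosage(AlleleCounts(0, 0, 0)) is None


class TestVcf:
    def test_allelic_depth_ratio(self, vcf_factory):
        row = f"chr12\t{CODON_START1 + 1}\t.\tC\tT\t.\tPASS\t.\tGT:AD\t0/1:80,20"
        vf = pysam.VariantFile(str(vcf_factory([row])))
        rec = next(vf.fetch()) if vf.index else next(iter(vf))
        assert vaf_from_vcf(rec, G12_HG19) == pytest.approx(0.20)

    def test_non_pass_is_undefined(self, vcf_factory):
        row = f"chr12\t{CODON_START1 + 1}\t.\tC\tT\t.\tgermline\t.\tGT:AD\t0/1:80,20"
        rec = next(iter(pysam.VariantFile(str(vcf_factory([row])))))
        assert vaf_from_vcf(rec, G12_HG19) is None

    def test_multiallelic_g12_alleles_summed(self, vcf_factory):
        # C>T (G12D) and C>G (G12A): per-allele VAFs 0.10 and 0.05 sum to 0.15
        row = f"chr12\t{CODON_START1 + 1}\t.\tC\tT,G\t.\tPASS\t.\tGT:AD\t0/1:85,10,5"
        rec = next(iter(pysam.VariantFile(str(vcf_factory([row])))))
        assert vaf_from_vcf(rec, G12_HG19) == pytest.approx(0.15)

    def test_synonymous_alt_is_undefined(self, vcf_factory):
        # first codon base A>G leaves glycine unchanged
        row = f"chr12\t{CODON_START1}\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:90,10"
        rec = next(iter(pysam.VariantFile(str(vcf_factory([row])))))
        assert vaf_from_vcf(rec, G12_HG19) is None

    def test_af_fallback_when_no_ad(self, vcf_factory):
        row = f"chr12\t{CODON_START1 + 1}\t.\tC\tT\t.\tPASS\tAF=0.31\tGT\t0/1"
        rec = next(iter(pysam.VariantFile(str(vcf_factory([row])))))
        assert vaf_from_vcf(rec, G12_HG19) == pytest.approx(0.31, abs=1e-6)


class TestCnvAndClonality:
    def test_identity_at_copy_neutral(self):
        assert adjust_for_cnv(0.3, CopyNumberState(2)) == pytest.approx(0.3)

    def test_halved_at_four_copies(self):
        assert adjust_for_cnv(0.4, CopyNumberState(4)) == pytest.approx(0.2)

    def test_clamped_at_one_copy(self):
        assert adjust_for_cnv(0.8, CopyNumberState(1)) == 1.0

    def test_zero_copies_rejected(self):
        with pytest.raises(ValueError):
            adjust_for_cnv(0.3, CopyNumberState(0))

    def test_clonal_g12(self):
        label, eff = classify_clonality(0.3, None)
        assert label == "clonal_g12" and eff == pytest.approx(0.3)

    def test_q61_transition_moves_to_high(self):
        label, eff = classify_clonality(0.05, 0.25, threshold=0.195)
        assert label == "subclonal_g12_q61"
        assert eff == pytest.approx(0.25)
        assert eff > 0.195

    def test_transition_rule_off_keeps_g12(self):
        _, eff = classify_clonality(0.05, 0.25, transition_rule=False)
        assert eff == pytest.approx(0.05)

    def test_no_mutation(self):
        label, _ = classify_clonality(0.0, None)
        assert label == "none"

    def test_error_floor_not_called_as_subclone(self):
        # ultra-deep sequencing miscall background (~e/3) must not
        # produce spurious Q61 subclone calls
        label, _ = classify_clonality(0.2, 0.0004)
        assert label == "clonal_g12"

    def test_clonality_calls_recover_simulated_truth(self):
        cfg = SimulationConfig(n_patients=400, seed=7)
        b = generate_cohort(cfg)
        prof = build_dosage_profiles(b.allele_counts).set_index("patient_id")
        truth = b.truth.set_index("patient_id")
        called = prof.clonality == "subclonal_g12_q61"
        assert (called == (truth.q61_cell_fraction > 0)).all()


class TestProfiles:
    def test_partial_modalities_yield_nan(self):
        counts = pd.DataFrame([
            {"patient_id": "A", "modality": "TS", "codon": "G12",
             "mutant_reads": 10, "wildtype_reads": 90, "other_reads": 0},
        ])
        prof = build_dosage_profiles(counts)
        row = prof.iloc[0]
        assert row.dosage_ts == pytest.approx(0.1)
        assert np.isnan(row.dosage_rna) and np.isnan(row.dosage_wes)

    def test_duplicate_rows_rejected(self):
        counts = pd.DataFrame([
            {"patient_id": "A", "modality": "TS", "codon": "G12",
             "mutant_reads": 1, "wildtype_reads": 9, "other_reads": 0},
        ] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            build_dosage_profiles(counts)

    def test_cnv_adjustment_applied(self):
        counts = pd.DataFrame([
            {"patient_id": "A", "modality": "TS", "codon": "G12",
             "mutant_reads": 40, "wildtype_reads": 60, "other_reads": 0},
        ])
        cn = pd.DataFrame([{"patient_id": "A", "kras_total_copies": 4}])
        prof = build_dosage_profiles(counts, cn_table=cn)
        assert prof.iloc[0].adjusted_dosage_ts == pytest.approx(0.2)

    def test_ts_dosage_tracks_truth_at_high_depth(self):
        cfg = SimulationConfig(n_patients=500, seed=21, depth_ts=1_000_000)
        b = generate_cohort(cfg)
        prof = build_dosage_profiles(b.allele_counts).set_index("patient_id")
        truth = b.truth.set_index("patient_id")
        err = (prof.dosage_ts - truth.expected_vaf_g12).abs()
        assert err.max() < 0.01

    def test_dosage_purity_correlation(self, small_cohort):
        _, b = small_cohort
        prof = build_dosage_profiles(b.allele_counts).set_index("patient_id")
        truth = b.truth.set_index("patient_id")
        rho = pd.Series(prof.dosage_ts).corr(truth.purity, method="spearman")
        assert rho > 0.5
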