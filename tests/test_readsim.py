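"""Read simulation: coverage planning, allele-frequency recovery, truth SAM."""

import numpy as np
import pysam
import pytest

from tumorbench.caller import pileup_counts
from tumorbench.mixing import AdmixedSample, CloneMixture, MATERNAL, PATERNAL
from tumorbench.readsim import (
    GenomeSet,
    ReadSimConfig,
    TargetRegions,
    exome_config,
    panel_config,
    plan_fragment_count,
    simulate_reads,
)
from tumorbench.variants import Origin, Variant, VariantClass, implant_variants

from conftest import random_reference

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def build_genome_set(reference, maternal_variants=(), paternal_variants=(), somatic=(), n_per_lineage=1):
    """Two control haplotypes and n cancer genomes per lineage.

    ``somatic`` variants are carried clonally by every cancer genome.
    """
    control = {
        MATERNAL: implant_variants(reference, list(maternal_variants), label="control_m"),
        PATERNAL: implant_variants(reference, list(paternal_variants), label="control_p"),
    }
    tumor = {}
    for lineage, germ in ((MATERNAL, maternal_variants), (PATERNAL, paternal_variants)):
        for i in range(n_per_lineage):
            tumor[(lineage, i)] = implant_variants(
                reference, sorted(list(germ) + list(somatic), key=lambda v: v.pos),
                label=f"cancer_{lineage}_{i}",
            )
    return GenomeSet(control=control, tumor=tumor)


def uniform_sample(admixture, n_per_lineage=1, label="t"):
    w = (1.0 / n_per_lineage,) * n_per_lineage
    return AdmixedSample(CloneMixture(w, w), admixture, label)


@pytest.fixture(scope="module")
def flat_reference():
    return {"chr1": random_reference(np.random.default_rng(101), 6_000)}


class TestPlanFragmentCount:
    def test_closed_form_exome(self):
        cfg = exome_config(target_median_coverage=70)
        targets = TargetRegions.from_intervals([("chr1", 0, 10_000)])
        assert plan_fragment_count(cfg, targets) == 3_500

    def test_closed_form_panel(self):
        cfg = panel_config(target_median_coverage=520)
        targets = TargetRegions.from_intervals([("chr1", 0, 2_000)])
        assert plan_fragment_count(cfg, targets) == 5_200

    def test_empty_targets_fatal(self):
        cfg = exome_config()
        with pytest.raises(ValueError):
            TargetRegions.from_intervals([("chr1", 5, 5)])


class TestTargetRegions:
    def test_merge_and_total(self):
        t = TargetRegions.from_intervals(
            [("chr1", 0, 100), ("chr1", 50, 150), ("chr2", 0, 10)]
        )
        assert t.intervals == (("chr1", 0, 150), ("chr2", 0, 10))
        assert t.total_bases == 160

    def test_bed_round_trip(self, tmp_path):
        t = TargetRegions.from_intervals([("chr1", 10, 500), ("chr1", 800, 900)])
        t.to_bed(tmp_path / "t.bed")
        assert TargetRegions.from_bed(tmp_path / "t.bed") == t

    def test_contains_is_one_based(self):
        t = TargetRegions.from_intervals([("chr1", 10, 20)])
        assert t.contains("chr1", 11) and t.contains("chr1", 20)
        assert not t.contains("chr1", 10) and not t.contains("chr1", 21)


def alt_fraction(sam_path, contig, pos, ref_base, alt_base):
    counts = pileup_counts(sam_path)[contig]
    col = counts[:, pos - 1]
    depth = col.sum()
    return (col[BASE_INDEX[alt_base]] / depth if depth else 0.0), int(depth)


class TestAlleleFrequencyRecovery:
    def test_pure_control_has_no_somatic_allele(self, flat_reference, tmp_path):
        som = Variant("s1", "chr1", 3_000, flat_reference["chr1"][2999],
                      "ACGT".replace(flat_reference["chr1"][2999], "")[0],
                      VariantClass.SNV, Origin.SOMATIC)
        genomes = build_genome_set(flat_reference, somatic=[som])
        targets = TargetRegions.from_intervals([("chr1", 2_000, 4_000)])
        cfg = exome_config(target_median_coverage=200, seed=5, sub_rate=0.0,
                           ins_rate=0.0, del_rate=0.0)
        run = simulate_reads(genomes, targets, cfg, sample=None, out_prefix=tmp_path / "ctrl")
        frac, depth = alt_fraction(run.truth_sam, "chr1", 3_000, som.ref_allele, som.alt_allele)
        assert depth > 100
        assert frac == 0.0

    def test_het_germline_recovers_half(self, flat_reference, tmp_path):
        ref_base = flat_reference["chr1"][2_999]
        alt = "ACGT".replace(ref_base, "")[0]
        het = Variant("g1", "chr1", 3_000, ref_base, alt, VariantClass.SNV, Origin.GERMLINE)
        genomes = build_genome_set(flat_reference, maternal_variants=[het])
        targets = TargetRegions.from_intervals([("chr1", 2_000, 4_000)])
        cfg = exome_config(target_median_coverage=500, seed=6, sub_rate=0.0,
                           ins_rate=0.0, del_rate=0.0)
        run = simulate_reads(genomes, targets, cfg, sample=None, out_prefix=tmp_path / "het")
        frac, depth = alt_fraction(run.truth_sam, "chr1", 3_000, ref_base, alt)
        se = np.sqrt(0.25 / depth)
        assert depth > 200
        assert abs(frac - 0.5) < 3 * se

    def test_clonal_somatic_at_90_percent_admixture(self, flat_reference, tmp_path):
        """Clonal somatic variant (tumor AF 1.0) reads at ~10% when a = 0.9."""
        ref_base = flat_reference["chr1"][2_999]
        alt = "ACGT".replace(ref_base, "")[0]
        som = Variant("s1", "chr1", 3_000, ref_base, alt, VariantClass.SNV, Origin.SOMATIC)
        genomes = build_genome_set(flat_reference, somatic=[som])
        targets = TargetRegions.from_intervals([("chr1", 2_500, 3_500)])
        cfg = exome_config(target_median_coverage=3_500, seed=7, sub_rate=0.0,
                           ins_rate=0.0, del_rate=0.0)
        run = simulate_reads(
            genomes, targets, cfg, sample=uniform_sample(0.9), out_prefix=tmp_path / "adx"
        )
        frac, depth = alt_fraction(run.truth_sam, "chr1", 3_000, ref_base, alt)
        assert depth >= 2_000
        se = np.sqrt(0.1 * 0.9 / depth)
        assert abs(frac - 0.10) < 3 * se


class TestCoverage:
    def test_realized_median_on_target_coverage(self, flat_reference, tmp_path):
        genomes = build_genome_set(flat_reference)
        targets = TargetRegions.from_intervals([("chr1", 500, 5_500)])
        cfg = exome_config(target_median_coverage=70, seed=8)
        run = simulate_reads(genomes, targets, cfg, sample=None, out_prefix=tmp_path / "cov")
        depth = pileup_counts(run.truth_sam)["chr1"].sum(axis=0)
        on_target = depth[500:5_500]
        median = float(np.median(on_target))
        assert 0.9 * 70 <= median <= 1.1 * 70


class TestErrorModel:
    def test_substitution_rate_recovered(self, flat_reference, tmp_path):
        """With no variants, the mismatch rate vs reference matches sub_rate."""
        genomes = build_genome_set(flat_reference)
        targets = TargetRegions.from_intervals([("chr1", 500, 5_500)])
        sub = 1e-3
        cfg = exome_config(target_median_coverage=100, seed=9, sub_rate=sub,
                           ins_rate=0.0, del_rate=0.0)
        run = simulate_reads(genomes, targets, cfg, sample=None, out_prefix=tmp_path / "err")
        counts = pileup_counts(run.truth_sam)["chr1"]
        ref_codes = np.frombuffer(flat_reference["chr1"].encode(), dtype=np.uint8)
        lut = np.full(256, -1, dtype=np.int8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        ref_idx = lut[ref_codes]
        total = counts.sum()
        matches = counts[ref_idx, np.arange(len(ref_idx))].sum()
        mismatch_rate = 1 - matches / total
        assert mismatch_rate == pytest.approx(sub, rel=0.10)

    def test_zero_error_reads_match_haplotype_exactly(self, flat_reference, tmp_path):
        genomes = build_genome_set(flat_reference)
        targets = TargetRegions.from_intervals([("chr1", 1_000, 2_000)])
        cfg = exome_config(target_median_coverage=20, seed=10, sub_rate=0.0,
                           ins_rate=0.0, del_rate=0.0)
        run = simulate_reads(genomes, targets, cfg, sample=None, out_prefix=tmp_path / "clean")
        ref = flat_reference["chr1"]
        with pysam.AlignmentFile(str(run.truth_sam), "r") as sam:
            n = 0
            for read in sam:
                assert read.cigarstring == f"{cfg.read_length}M"
                assert read.query_sequence == ref[read.reference_start:read.reference_start + cfg.read_length]
                n += 1
        assert n > 50


class TestTruthAlignments:
    def test_read_spanning_insertion_has_insertion_op(self, flat_reference, tmp_path):
        ins = Variant("i1", "chr1", 3_000, "", "GGG", VariantClass.INS, Origin.GERMLINE)
        genomes = build_genome_set(
            flat_reference, maternal_variants=[ins], paternal_variants=[ins]
        )
        targets = TargetRegions.from_intervals([("chr1", 2_800, 3_200)])
        cfg = exome_config(target_median_coverage=150, seed=11, sub_rate=0.0,
                           ins_rate=0.0, del_rate=0.0)
        run = simulate_reads(genomes, targets, cfg, sample=None, out_prefix=tmp_path / "ins")
        cigars = []
        with pysam.AlignmentFile(str(run.truth_sam), "r") as sam:
            for read in sam:
                cigars.append(read.cigarstring)
        assert any("3I" in c for c in cigars)
        # homozygous insertion: every read crossing the site carries it
        spanning = [
            c for c in cigars
            if "I" in c or "S" in c
        ]
        assert spanning

    def test_mate_flags_exactly_one_reverse(self, flat_reference, tmp_path):
        genomes = build_genome_set(flat_reference)
        targets = TargetRegions.from_intervals([("chr1", 1_000, 2_000)])
        cfg = exome_config(target_median_coverage=30, seed=12)
        run = simulate_reads(genomes, targets, cfg, sample=None, out_prefix=tmp_path / "mate")
        by_name: dict[str, list] = {}
        with pysam.AlignmentFile(str(run.truth_sam), "r") as sam:
            for read in sam:
                by_name.setdefault(read.query_name, []).append(read)
        assert by_name
        for reads in by_name.values():
            assert len(reads) == 2
            assert sorted(r.is_reverse for r in reads) == [False, True]
            assert sorted(r.is_read1 for r in reads) == [False, True]

    def test_sam_is_coordinate_sorted(self, flat_reference, tmp_path):
        genomes = build_genome_set(flat_reference)
        targets = TargetRegions.from_intervals([("chr1", 1_000, 3_000)])
        cfg = exome_config(target_median_coverage=20, seed=13)
        run = simulate_reads(genomes, targets, cfg, sample=None, out_prefix=tmp_path / "sort")
        with pysam.AlignmentFile(str(run.truth_sam), "r") as sam:
            positions = [r.reference_start for r in sam]
        assert positions == sorted(positions)


class TestDeterminism:
    def test_identical_seed_byte_identical_fastq(self, flat_reference, tmp_path):
        genomes = build_genome_set(flat_reference)
        targets = TargetRegions.from_intervals([("chr1", 1_000, 3_000)])
        cfg = exome_config(target_median_coverage=25, seed=21)
        r1 = simulate_reads(genomes, targets, cfg, sample=None, out_prefix=tmp_path / "d1")
        r2 = simulate_reads(genomes, targets, cfg, sample=None, out_prefix=tmp_path / "d2")
        assert r1.fastq1.read_bytes() == r2.fastq1.read_bytes()
        assert r1.fastq2.read_bytes() == r2.fastq2.read_bytes()
        assert r1.truth_sam.read_text() == r2.truth_sam.read_text()

    def test_different_seed_differs(self, flat_reference, tmp_path):
        genomes = build_genome_set(flat_reference)
        targets = TargetRegions.from_intervals([("chr1", 1_000, 3_000)])
        r1 = simulate_reads(genomes, targets, exome_config(target_median_coverage=25, seed=1),
                            sample=None, out_prefix=tmp_path / "s1")
        r2 = simulate_reads(genomes, targets, exome_config(target_median_coverage=25, seed=2),
                            sample=None, out_prefix=tmp_path / "s2")
        assert r1.fastq1.read_bytes() != r2.fastq1.read_bytes()


class TestConfigValidation:
    def test_insert_shorter_than_read_rejected(self):
        with pytest.raises(ValueError):
            ReadSimConfig(read_length=100, insert_mean=50)

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            ReadSimConfig(sub_rate=0.5)

    def test_presets_match_study_design(self):
        exome = exome_config()
        panel = panel_config()
        assert (exome.read_length, exome.insert_mean, exome.insert_sd) == (100, 300.0, 100.0)
        assert exome.target_median_coverage == 70
        assert (panel.insert_mean, panel.insert_sd) == (200.0, 50.0)
        assert panel.target_median_coverage == 520
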