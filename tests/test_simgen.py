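"""Simulator correctness: reference repeat content, variant placement,
haplotype implantation and coordinate maps, quality profiles, fragment
sampling, read simulation and fabricated alignments."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapqcal import simgen
from mapqcal.simgen import ReadOrigin, VariantRecord


class TestGenerateReference:
    def test_deterministic(self):
        a = simgen.generate_reference(1, 2000, 0.3, seed=5)
        b = simgen.generate_reference(1, 2000, 0.3, seed=5)
        assert a == b

    def test_repeat_free_sequence_nearly_incompressible(self):
        ref = simgen.generate_reference(1, 50_000, 0.0, seed=1)["chr1"]
        compressed = len(gzip.compress(ref.encode()))
        assert compressed / len(ref) > 0.2

    def test_repeats_shrink_compressed_size(self):
        plain = simgen.generate_reference(1, 50_000, 0.0, seed=1)["chr1"]
        repetitive = simgen.generate_reference(1, 50_000, 0.5, seed=1)["chr1"]
        assert len(gzip.compress(repetitive.encode())) < \
            len(gzip.compress(plain.encode()))

    def test_acgt_only(self):
        ref = simgen.generate_reference(2, 1000, 0.2, seed=3)
        assert set("".join(ref.values())) <= set("ACGT")


class TestGenerateVariants:
    def test_count_matches_density(self):
        # tomato-like: ~1 variant / 3,000 bp over 300 kb -> ~100
        ref = simgen.generate_reference(1, 300_000, 0.0, seed=2)
        variants = simgen.generate_variants(ref, 1 / 3000, 0.0, seed=3)
        n = len(variants)
        sd = np.sqrt(300_000 * (1 / 3000))
        assert abs(n - 100) <= 3 * sd

    def test_zero_rates_empty(self):
        ref = simgen.generate_reference(1, 5000, 0.0, seed=2)
        assert simgen.generate_variants(ref, 0.0, 0.0, seed=1) == []

    def test_hom_snps_alt_differs_from_ref(self):
        ref = simgen.generate_reference(1, 20_000, 0.0, seed=2)
        variants = simgen.generate_variants(ref, 1 / 500, 0.0, seed=4,
                                            het_fraction=0.0)
        assert variants
        for v in variants:
            assert v.genotype == "hom"
            assert len(v.ref_allele) == len(v.alt_allele) == 1
            assert v.ref_allele == ref["chr1"][v.pos - 1]
            assert v.alt_allele != v.ref_allele

    def test_non_overlapping(self):
        ref = simgen.generate_reference(1, 50_000, 0.0, seed=2)
        variants = simgen.generate_variants(ref, 1 / 300, 1 / 1000, seed=5,
                                            sv_counts={"DEL": 2, "INV": 1},
                                            sv_len=500)
        spans = sorted((v.pos, v.ref_end) for v in variants)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 > e1


class TestImplantVariants:
    def test_hom_snp_applied_to_both_haplotypes(self):
        ref = {"chr1": "AAAAAAAAAA"}
        v = VariantRecord("chr1", 5, "A", "C", "SNP", "hom")
        haps, _ = simgen.implant_variants(ref, [v])
        assert haps[0]["chr1"] == "AAAACAAAAA"
        assert haps[1]["chr1"] == "AAAACAAAAA"

    def test_het_deletion_length_arithmetic(self):
        ref = {"chr1": "AAAAAAAAAA"}
        # 2 bp deletion of bases 3-4, VCF-anchored at pos 2
        v = VariantRecord("chr1", 2, "AAA", "A", "DEL", "het", het_hap=1)
        haps, _ = simgen.implant_variants(ref, [v])
        assert len(haps[0]["chr1"]) == 8
        assert len(haps[1]["chr1"]) == 10

    def test_coordinate_map_across_deletion(self):
        ref = {"chr1": "ACGTACGTAC"}
        v = VariantRecord("chr1", 2, "CGT", "C", "DEL", "het", het_hap=1)
        _, maps = simgen.implant_variants(ref, [v])
        cmap = maps[0]["chr1"]
        # hap: A C | A C G T A C  (ref bases 3-4 deleted)
        assert cmap.hap_to_ref(2) == 2
        assert cmap.hap_to_ref(3) == 5
        assert cmap.hap_to_ref(7) == 9

    def test_zero_variants_identity(self):
        ref = {"chr1": "ACGT" * 300}
        haps, maps = simgen.implant_variants(ref, [])
        assert haps[0] == ref and haps[1] == ref
        assert maps[0]["chr1"].hap_to_ref(7) == 7

    def test_snp_only_differences_exactly_at_hom_positions(self):
        ref = simgen.generate_reference(1, 10_000, 0.0, seed=9)
        variants = simgen.generate_variants(ref, 1 / 500, 0.0, seed=10,
                                            het_fraction=0.0)
        haps, _ = simgen.implant_variants(ref, variants)
        diff = [i + 1 for i, (a, b) in
                enumerate(zip(ref["chr1"], haps[0]["chr1"])) if a != b]
        assert diff == sorted(v.pos for v in variants)

    def test_overlapping_variants_rejected(self):
        ref = {"chr1": "ACGTACGTAC"}
        vs = [VariantRecord("chr1", 2, "CGT", "C", "DEL", "hom"),
              VariantRecord("chr1", 3, "G", "A", "SNP", "hom")]
        with pytest.raises(ValueError, match="overlap"):
            simgen.implant_variants(ref, vs)


class TestQualityProfile:
    def _write_fastq(self, path, quals_per_read):
        with open(path, "w") as fh:
            for i, quals in enumerate(quals_per_read):
                seq = "A" * len(quals)
                qstr = "".join(chr(q + 33) for q in quals)
                fh.write(f"@r{i}\n{seq}\n+\n{qstr}\n")

    def test_constant_input_point_mass(self, tmp_path):
        path = str(tmp_path / "a.fastq")
        self._write_fastq(path, [[30] * 10] * 5)
        prof = simgen.build_quality_profile([path])
        assert prof.n_cycles == 10
        assert np.allclose(prof.mean_per_cycle(), 30)
        assert prof.scores.tolist() == [30]

    def test_two_read_counting(self, tmp_path):
        path = str(tmp_path / "a.fastq")
        self._write_fastq(path, [[20, 25], [40, 25]])
        prof = simgen.build_quality_profile([path])
        cycle1 = dict(zip(prof.scores.tolist(), prof.probs[0].tolist()))
        assert cycle1[20] == pytest.approx(0.5)
        assert cycle1[40] == pytest.approx(0.5)

    def test_mixed_lengths_rejected(self, tmp_path):
        path = str(tmp_path / "a.fastq")
        self._write_fastq(path, [[30] * 10, [30] * 12])
        with pytest.raises(ValueError, match="mixed read lengths"):
            simgen.build_quality_profile([path])

    def test_closed_loop_recovery(self, tmp_path):
        # profile rebuilt from reads sampled under a known profile
        truth = simgen.default_quality_profile(50)
        rng = np.random.default_rng(0)
        quals = truth.sample(rng, 10_000)
        path = str(tmp_path / "sim.fastq")
        self._write_fastq(path, quals.tolist())
        rebuilt = simgen.build_quality_profile([path])
        mad = np.abs(rebuilt.mean_per_cycle() - truth.mean_per_cycle()).mean()
        assert mad < 1.0

    def test_tsv_round_trip(self, tmp_path):
        prof = simgen.default_quality_profile(20)
        path = str(tmp_path / "prof.tsv")
        prof.to_tsv(path)
        back = simgen.QualityProfile.from_tsv(path)
        assert np.allclose(back.mean_per_cycle(), prof.mean_per_cycle(),
                           atol=1e-6)


class TestFragmentSampler:
    def test_mean_within_three_se(self):
        rng = np.random.default_rng(42)
        frags = simgen.sample_fragment_lengths(50_000, 240.0, 80.0, rng)
        se = 80.0 / np.sqrt(50_000)
        assert abs(frags.mean() - 240.0) < 3 * se

    def test_truncation_respects_bounds_without_clamping_mass(self):
        rng = np.random.default_rng(1)
        frags = simgen.sample_fragment_lengths(20_000, 240.0, 80.0, rng,
                                               min_len=100, max_len=500)
        assert frags.min() >= 100 and frags.max() <= 500
        # resampling leaves no point mass at the bound
        assert (frags == 100).mean() < 0.01


class TestOriginEncoding:
    def test_round_trip_example(self):
        origin = ReadOrigin(1, "chr1", 1000, 1099, "+",
                            "chr1", 1141, 1240, "-", serial=7)
        assert simgen.parse_origin(simgen.encode_origin(origin)) == origin

    def test_foreign_name_degrades_gracefully(self):
        assert simgen.parse_origin("SRR123.456") is None
        assert simgen.parse_origin("sim:bad:name") is None

    @settings(max_examples=200, deadline=None)
    @given(hap=st.integers(1, 2), start=st.integers(1, 10**8),
           length=st.integers(1, 500), mstart=st.integers(1, 10**8),
           strand=st.sampled_from("+-"), mstrand=st.sampled_from("+-"),
           serial=st.integers(0, 10**6),
           chrom=st.from_regex(r"[A-Za-z0-9_.]{1,12}", fullmatch=True))
    def test_round_trip_property(self, hap, start, length, mstart, strand,
                                 mstrand, serial, chrom):
        origin = ReadOrigin(hap, chrom, start, start + length, strand,
                            chrom, mstart, mstart + length, mstrand, serial)
        assert simgen.parse_origin(simgen.encode_origin(origin)) == origin


class TestSimulateReads:
    def test_pair_count_and_read_length(self, tmp_path):
        ref = simgen.generate_reference(1, 100_000, 0.0, seed=21)
        haps, maps = simgen.implant_variants(ref, [])
        cfg = simgen.SimConfig(coverage=3.0, read_len=100, seed=22)
        f1, f2, n_pairs = simgen.simulate_reads(haps, maps, cfg,
                                                str(tmp_path / "r"))
        # coverage identity: 3 * 100,000 / (2 * 100)
        assert n_pairs == 1500
        import pysam
        with pysam.FastxFile(f1) as fq:
            entries = list(fq)
        assert len(entries) == 1500
        assert all(len(e.sequence) == 100 for e in entries)
        assert all(len(e.quality) == 100 for e in entries)

    def test_origins_parse_and_fit_reference(self, small_universe):
        import pysam
        with pysam.FastxFile(small_universe["fq1"]) as fq:
            for entry in fq:
                origin = simgen.parse_origin(entry.name.rsplit("/", 1)[0])
                assert origin is not None
                assert origin.start <= origin.end
                assert origin.chrom in small_universe["ref"]
                assert origin.end <= len(small_universe["ref"][origin.chrom])


class TestFabricateAlignments:
    def test_zero_mislocation_all_correct_at_origin(self, tmp_path):
        ref = simgen.generate_reference(1, 50_000, 0.0, seed=31)
        haps, maps = simgen.implant_variants(ref, [])
        cfg = simgen.SimConfig(coverage=1.0, seed=32)
        f1, f2, _ = simgen.simulate_reads(haps, maps, cfg, str(tmp_path / "r"))
        sam = str(tmp_path / "r.sam")
        labels = simgen.fabricate_alignments(f1, f2, ref, 0.0, 33, sam)
        assert set(labels.values()) == {0}
        from mapqcal import alignment_io
        records, _ = alignment_io.read_alignments(sam)
        for rec in records:
            origin = simgen.parse_origin(rec.read_name)
            _, start, _, _ = origin.span_for_mate(rec.mate)
            assert rec.pos == start

    def test_mislocation_fraction_binomial_bound(self, small_universe):
        labels = small_universe["labels"]
        n = len(labels)
        frac = sum(labels.values()) / n
        sd = np.sqrt(0.01 * 0.99 / n)
        assert abs(frac - 0.01) < 3 * sd

    def test_misplaced_reads_have_higher_edit_distance(
            self, small_feature_table):
        by_label = small_feature_table.groupby("LABEL")["EDIT_DISTANCE"].mean()
        assert by_label[1] > by_label[0]

    def test_coverage_identity(self, small_universe):
        # mean depth from read placements ~ configured 3x (within 10%)
        ref = small_universe["ref"]
        total = np.float64(0)
        for rec in small_universe["records"]:
            total += rec.reference_span()
        depth = total / sum(len(s) for s in ref.values())
        assert abs(depth - 3.0) / 3.0 < 0.10

    def test_labels_match_origin_derived_labels(self, small_universe,
                                                small_feature_table):
        from mapqcal import features
        derived = features.feature_table(small_universe["records"],
                                         small_universe["ref"])
        merged = small_feature_table.merge(derived, on="READ_KEY",
                                           suffixes=("_gen", "_derived"))
        assert (merged["LABEL_gen"] == merged["LABEL_derived"]).all()
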