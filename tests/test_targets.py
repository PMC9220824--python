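import math

import pytest

from isletpulse.genomic import (
    GeneModel, GenomicFormatError, Loop, Peak, TargetParams, call_targets,
    calls_to_frame, distance, read_bed, read_bedpe, read_genes_tsv,
    summarize_calls, write_bed, write_bedpe, write_genes_tsv,
)
from isletpulse.synthetic import make_genomic_fixture

from _oracles import brute_force_targets


GENE = GeneModel(gene_id="G1", chrom="chr1", strand="+", tss=100_000,
                 introns=((102_000, 104_000),))


def _call_one(peaks=(), loops=(), params=TargetParams()):
    calls = call_targets([GENE], list(peaks), list(loops), ["G1"], params)
    assert len(calls) == 1
    return calls[0]


class TestDistance:
    def test_gap_semantics(self):
        assert distance((0, 10), (10, 20)) == 0  # touching half-open
        assert distance((0, 10), (15, 20)) == 5
        assert distance(5, (0, 10)) == 0
        assert distance(12, (0, 10)) == 2
        assert distance((0, 10), (5, 6)) == 0  # containment

    def test_cross_chromosome_infinite(self):
        assert distance((0, 10), (0, 10), "chr1", "chr2") == math.inf


class TestRules:
    def test_tss_boundary_inclusive(self):
        # gap from TSS to peak start exactly 1000 bp -> included
        peak = Peak("p", "chr1", GENE.tss + 1000, GENE.tss + 1150)
        call = _call_one([peak])
        assert call.categories == {"tss"}
        assert call.evidence["tss"][0]["distance_bp"] == 1000

    def test_tss_boundary_exclusive_beyond(self):
        peak = Peak("p", "chr1", GENE.tss + 1001, GENE.tss + 1151)
        call = _call_one([peak])
        assert not call.is_target

    def test_intron_one_bp_overlap(self):
        peak = Peak("p", "chr1", 101_851, 102_001)  # 1 bp inside the intron
        call = _call_one([peak])
        assert call.categories == {"intron"}

    def test_intron_touching_is_not_overlap(self):
        peak = Peak("p", "chr1", 101_850, 102_000)  # ends where intron starts
        call = _call_one([peak])
        assert not call.is_target

    def test_loop_rule(self):
        loop = Loop("l", "chr1", (GENE.tss - 200, GENE.tss + 200),
                    "chr1", (300_000, 301_000))
        peak = Peak("p", "chr1", 301_500, 301_650)  # 500 bp from anchor B
        call = _call_one([peak], [loop])
        assert call.categories == {"loop"}
        assert call.evidence["loop"][0]["loop_id"] == "l"

    def test_loop_peak_beyond_threshold(self):
        loop = Loop("l", "chr1", (GENE.tss - 200, GENE.tss + 200),
                    "chr1", (300_000, 301_000))
        peak = Peak("p", "chr1", 301_501, 301_651)
        assert not _call_one([peak], [loop]).is_target

    def test_loop_anchor_must_reach_tss(self):
        loop = Loop("l", "chr1", (GENE.tss + 1_500, GENE.tss + 2_500),
                    "chr1", (300_000, 301_000))
        peak = Peak("p", "chr1", 300_000, 300_150)
        assert not _call_one([peak], [loop]).is_target

    def test_inter_chromosomal_loop_ignored(self):
        loop = Loop("l", "chr1", (GENE.tss - 200, GENE.tss + 200),
                    "chr2", (300_000, 301_000))
        peak = Peak("p", "chr2", 300_100, 300_250)
        assert not _call_one([peak], [loop]).is_target

    def test_cross_chromosome_peak_never_matches(self):
        peak = Peak("p", "chr2", GENE.tss, GENE.tss + 150)
        assert not _call_one([peak]).is_target

    def test_multiple_categories_accumulate(self):
        peaks = [
            Peak("p1", "chr1", GENE.tss - 100, GENE.tss + 50),
            Peak("p2", "chr1", 102_500, 102_650),
        ]
        call = _call_one(peaks)
        assert call.categories == {"tss", "intron"}

    def test_unknown_de_ids_skipped(self):
        calls = call_targets([GENE], [], [], ["G1", "NOT_A_GENE"])
        assert [c.gene_id for c in calls] == ["G1"]

    def test_order_independent_of_input_order(self):
        peaks = [Peak("p1", "chr1", GENE.tss - 100, GENE.tss + 50),
                 Peak("p2", "chr1", 102_500, 102_650)]
        a = call_targets([GENE], peaks, [], ["G1"])
        b = call_targets([GENE], peaks[::-1], [], ["G1"])
        assert calls_to_frame(a).equals(calls_to_frame(b))


class TestOracle:
    def test_fixture_matches_brute_force(self, genomic_fixture):
        fx = genomic_fixture
        calls = call_targets(fx.genes, fx.peaks, fx.loops, fx.de_genes)
        oracle = brute_force_targets(fx.genes, fx.peaks, fx.loops, fx.de_genes)
        assert {c.gene_id: c.categories for c in calls} == oracle

    def test_fixture_truth_recovered(self, genomic_fixture):
        fx = genomic_fixture
        calls = call_targets(fx.genes, fx.peaks, fx.loops, fx.de_genes)
        for c in calls:
            planted = fx.truth_labels[c.gene_id]
            if planted == "none":
                assert not c.is_target
            else:
                assert planted in c.categories

    def test_summary_counts(self, genomic_fixture):
        fx = genomic_fixture
        calls = call_targets(fx.genes, fx.peaks, fx.loops, fx.de_genes)
        summary = summarize_calls(calls)
        assert summary["n_genes"] == len(fx.genes)
        assert summary["n_targets"] + summary["none"] == summary["n_genes"]


class TestReaders:
    def test_round_trip(self, genomic_fixture, tmp_path):
        fx = genomic_fixture
        write_genes_tsv(fx.genes, tmp_path / "genes.tsv")
        write_bed(fx.peaks, tmp_path / "peaks.bed")
        write_bedpe(fx.loops, tmp_path / "loops.bedpe")
        assert read_genes_tsv(tmp_path / "genes.tsv") == list(fx.genes)
        assert read_bed(tmp_path / "peaks.bed") == list(fx.peaks)
        assert read_bedpe(tmp_path / "loops.bedpe") == list(fx.loops)

    def test_malformed_bed_reports_line(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t0\t100\npeakline\n")
        with pytest.raises(GenomicFormatError, match=r"bad\.bed:2"):
            read_bed(bad)

    def test_non_integer_coordinates(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\tzero\t100\n")
        with pytest.raises(GenomicFormatError, match="non-integer"):
            read_bed(bad)

    def test_bedpe_field_count(self, tmp_path):
        bad = tmp_path / "bad.bedpe"
        bad.write_text("chr1\t0\t100\tchr1\t200\n")
        with pytest.raises(GenomicFormatError, match=r"bad\.bedpe:1"):
            read_bedpe(bad)

    def test_genes_tsv_malformed_intron(self, tmp_path):
        bad = tmp_path / "genes.tsv"
        bad.write_text("gene_id\tchrom\tstrand\ttss\tintrons\n"
                       "G1\tchr1\t+\t100\t10--20\n")
        with pytest.raises(GenomicFormatError, match=r"genes\.tsv:2"):
            read_genes_tsv(bad)

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        bed = tmp_path / "ok.bed"
        bed.write_text("# header\n\nchr1\t0\t100\tp1\n")
        peaks = read_bed(bed)
        assert len(peaks) == 1 and peaks[0].peak_id == "p1"
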