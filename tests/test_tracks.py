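"""Transcript coordinate projection, SAM end extraction, and track I/O."""

import numpy as np
import pytest

import dseq
from dseq import tracks as tr

from conftest import write_sam


class TestProjection:
    def test_plus_strand_identity(self, plus_model):
        assert plus_model.genomic_to_transcript(1000) == 0
        assert plus_model.genomic_to_transcript(1199) == 199
        assert plus_model.transcript_to_genomic(50) == 1050

    def test_minus_strand_reflection(self, minus_model):
        # transcript position 0 is the genomically rightmost base
        assert minus_model.genomic_to_transcript(5199) == 0
        assert minus_model.genomic_to_transcript(5000) == 199
        assert minus_model.transcript_to_genomic(0) == 5199

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_project_unproject_is_identity(self, strand):
        m = dseq.TranscriptModel("t", "chrI", strand,
                                 ((100, 150), (200, 260), (300, 310)))
        assert m.length == 120
        for t in range(m.length):
            g = m.transcript_to_genomic(t)
            assert m.genomic_to_transcript(g) == t
        exonic = [g for a, b in m.exons for g in range(a, b)]
        assert len({m.genomic_to_transcript(g) for g in exonic}) == m.length

    def test_intron_base_is_not_exonic(self):
        m = dseq.TranscriptModel("t", "chrI", "+", ((100, 150), (200, 260)))
        assert m.genomic_to_transcript(175) is None

    def test_features_must_tile(self):
        with pytest.raises(ValueError):
            dseq.TranscriptModel("t", "chrI", "+", ((0, 100),),
                                 (("cds", (0, 50)),))

    def test_unspliced_model_features(self):
        m = dseq.TranscriptModel.unspliced(
            "g", "chrI", "+", [(100, 150), (200, 260)], cds=(120, 240))
        segs = [s for s, _ in m.features]
        assert segs == ["five_prime_utr", "cds", "intron", "cds",
                        "three_prime_utr"]
        assert m.feature_at(0) == "five_prime_utr"
        assert m.feature_at(60) == "intron"  # genomic 160


class TestExtraction:
    def test_plus_strand_read_increments_stop_position(self, tmp_path, plus_model):
        # forward read, 5' end (RT stop) at genomic 1040 -> transcript 40
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, "chrI", 1040, 60, 30)])
        trk, stats = dseq.extract_end_counts(sam, [plus_model])
        assert trk["tplus"].counts[40] == 1
        assert stats.accepted == 1 and stats.spill == 0

    def test_minus_strand_read_reflected(self, tmp_path, minus_model):
        # reverse read: 5' end on transcript strand = reference_end - 1
        sam = write_sam(tmp_path / "a.sam", [("r1", 16, "chrI", 5100, 60, 30)])
        trk, _ = dseq.extract_end_counts(sam, [minus_model])
        g = 5100 + 30 - 1
        assert trk["tminus"].counts[minus_model.genomic_to_transcript(g)] == 1

    def test_wrong_strand_read_tallied(self, tmp_path, plus_model):
        sam = write_sam(tmp_path / "a.sam", [("r1", 16, "chrI", 1040, 60, 30)])
        trk, stats = dseq.extract_end_counts(sam, [plus_model])
        assert trk["tplus"].total == 0
        assert stats.strand_skipped == 1

    def test_low_mapq_filtered(self, tmp_path, plus_model):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, "chrI", 1040, 3, 30)])
        _, stats = dseq.extract_end_counts(sam, [plus_model], min_mapq=10)
        assert stats.filtered == 1 and stats.accepted == 0

    def test_unsorted_input_rejected(self, tmp_path, plus_model):
        p = tmp_path / "u.sam"
        p.write_text("@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chrI\tLN:10000\n")
        with pytest.raises(ValueError, match="coordinate-sorted"):
            dseq.extract_end_counts(str(p), [plus_model])

    def test_conservation_counts_plus_spill(self, tmp_path, plus_model, rng):
        reads = [(f"r{i}", 0, "chrI", int(rng.integers(900, 1300)), 60, 25)
                 for i in range(200)]
        sam = write_sam(tmp_path / "a.sam", reads)
        trk, stats = dseq.extract_end_counts(sam, [plus_model])
        assert trk["tplus"].total + stats.spill == stats.accepted

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_simulated_stops_round_trip_through_sam(self, tmp_path, strand):
        """End counts simulated in transcript space, re-expressed as aligned
        reads, must histogram back exactly."""
        cfg = dseq.SimConfig(transcripts={"t": 400}, n_fragments=1000,
                             background_stop_prob=0.01,
                             sites=(dseq.PlantedSite("t", 200, 1.0, 0.8),),
                             n_treated=1, n_control=1, seed=11)
        libset, _ = dseq.simulate_experiment(cfg)
        counts = libset.treated[0]["t"].counts
        model = dseq.TranscriptModel("t", "chrI", strand, ((1000, 1400),))
        reads, i = [], 0
        rlen = 20
        for t in np.flatnonzero(counts):
            g = model.transcript_to_genomic(int(t))
            for _ in range(int(counts[t])):
                if strand == "+":
                    reads.append((f"r{i}", 0, "chrI", g, 60, rlen))
                else:
                    reads.append((f"r{i}", 16, "chrI", g - rlen + 1, 60, rlen))
                i += 1
        sam = write_sam(tmp_path / "sim.sam", reads)
        trk, stats = dseq.extract_end_counts(sam, [model])
        assert np.array_equal(trk["t"].counts, counts)
        assert stats.spill == 0


class TestBedGraphWig:
    def test_bedgraph_simple_line(self, tmp_path):
        m = dseq.TranscriptModel("t", "chrI", "+", ((10, 110),))
        p = tmp_path / "x.bedgraph"
        p.write_text("chrI\t10\t11\t5\n")
        trk = dseq.read_count_track(p, [m])
        assert trk["t"].counts[0] == 5

    def test_empty_file_gives_zero_tracks(self, tmp_path):
        m = dseq.TranscriptModel("t", "chrI", "+", ((10, 110),))
        p = tmp_path / "x.bedgraph"
        p.write_text("")
        assert dseq.read_count_track(p, [m])["t"].total == 0

    def test_negative_value_names_line(self, tmp_path):
        m = dseq.TranscriptModel("t", "chrI", "+", ((10, 110),))
        p = tmp_path / "x.bedgraph"
        p.write_text("chrI\t10\t11\t5\nchrI\t12\t13\t-2\n")
        with pytest.raises(ValueError, match=":2:"):
            dseq.read_count_track(p, [m])

    def test_non_numeric_value_rejected(self, tmp_path):
        m = dseq.TranscriptModel("t", "chrI", "+", ((10, 110),))
        p = tmp_path / "x.bedgraph"
        p.write_text("chrI\t10\t11\tbogus\n")
        with pytest.raises(ValueError, match="non-numeric"):
            dseq.read_count_track(p, [m])

    @pytest.mark.parametrize("ext", ["bedgraph", "wig"])
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_write_read_round_trip(self, tmp_path, rng, ext, strand):
        m = dseq.TranscriptModel("t", "chrI", strand, ((1000, 1300),))
        counts = rng.integers(0, 20, size=300)
        trk = {"t": dseq.EndCountTrack("t", counts)}
        p = tmp_path / f"x.{ext}"
        dseq.write_count_track(trk, p, models={"t": m})
        back = dseq.read_count_track(p, [m])
        assert np.array_equal(back["t"].counts, counts)

    def test_transcript_space_round_trip(self, tmp_path, rng):
        counts = rng.integers(0, 50, size=120)
        trk = {"t": dseq.EndCountTrack("t", counts)}
        p = tmp_path / "x.bedgraph"
        dseq.write_count_track(trk, p)  # chrom = transcript id
        m = dseq.TranscriptModel.single_block("t", 120)
        back = dseq.read_count_track(p, [m])
        assert np.array_equal(back["t"].counts, counts)

    def test_rpm_definition_and_linearity(self, tmp_path):
        m = dseq.TranscriptModel.single_block("t", 10)
        trk = {"t": dseq.EndCountTrack("t", [0, 5, 0, 2, 0, 0, 0, 0, 0, 0])}
        p = tmp_path / "x.bedgraph"
        dseq.write_count_track(trk, p, scale="rpm", total_mapped=1_000_000)
        vals = {int(l.split()[1]): float(l.split()[3]) for l in open(p)}
        assert vals[1] == 5.0
        dbl = {"t": dseq.EndCountTrack("t", np.array([0, 10, 0, 4, 0, 0, 0, 0, 0, 0]))}
        dseq.write_count_track(dbl, p, scale="rpm", total_mapped=1_000_000)
        vals2 = {int(l.split()[1]): float(l.split()[3]) for l in open(p)}
        assert vals2[1] == 2 * vals[1] and vals2[3] == 2 * vals[3]

    def test_rpm_without_totals_errors(self, tmp_path):
        trk = {"t": dseq.EndCountTrack("t", [1, 0])}
        with pytest.raises(ValueError, match="total mapped"):
            dseq.write_count_track(trk, tmp_path / "x.bedgraph", scale="rpm")


class TestAnnotationReaders:
    def test_bed12_spliced_model(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chrI\t100\t260\tgeneA\t0\t+\t120\t240\t0\t2\t50,60\t0,100\n")
        (m,) = tr.read_bed12_models(p)
        assert m.exons == ((100, 150), (200, 260))
        assert m.length == 110
        assert m.feature_at(0) == "five_prime_utr"
        assert m.feature_at(25) == "cds"

    def test_gff3_unspliced_with_intron(self, tmp_path):
        p = tmp_path / "x.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chrI\tx\tgene\t101\t260\t.\t+\t.\tID=g1\n"
            "chrI\tx\tmRNA\t101\t260\t.\t+\t.\tID=m1;Parent=g1\n"
            "chrI\tx\texon\t101\t150\t.\t+\t.\tParent=m1\n"
            "chrI\tx\texon\t201\t260\t.\t+\t.\tParent=m1\n"
            "chrI\tx\tCDS\t121\t240\t.\t+\t.\tParent=m1\n")
        models = tr.read_gff3_models(p)
        m = next(x for x in models if x.rna_class == "mRNA")
        assert m.length == 160
        assert "intron" in {s for s, _ in m.features}

    def test_fasta_pseudo_genome(self, tmp_path):
        p = tmp_path / "trnas.fa"
        p.write_text(">tRNA-Gly\n" + "ACGU" * 18 + "\n>tRNA-Ala\n" + "GCGC" * 19 + "\n")
        models = {m.transcript_id: m for m in tr.models_from_fasta(p)}
        assert models["tRNA-Gly"].length == 72
        assert models["tRNA-Ala"].rna_class == "tRNA"
        assert models["tRNA-Gly"].chrom == "tRNA-Gly"
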