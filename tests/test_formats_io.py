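import numpy as np
import pytest

from peakreg import formats_io as fio
from peakreg.formats_io import (
    CoverageTrack,
    DERecord,
    DoseMatrix,
    FormatError,
    GeneModel,
    GenomicInterval,
    Peak,
)


class TestGenomicTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)

    def test_summit_must_lie_inside_peak(self):
        with pytest.raises(ValueError):
            Peak(GenomicInterval("chr1", 100, 200), "p", 0.0, summit_offset=100)
        assert Peak(GenomicInterval("chr1", 100, 200), "p", 0.0, 99).summit_offset == 99

    @pytest.mark.parametrize(
        "strand,start,end,tss", [("+", 1000, 5000, 1000), ("-", 1000, 5000, 4999)]
    )
    def test_tss_strand_rule(self, strand, start, end, tss):
        gene = GeneModel("g", GenomicInterval("chr1", start, end, strand))
        assert gene.tss == tss

    def test_de_record_validation(self):
        assert DERecord("g1", 1.6, 0.01, 12.3).fold_change == 1.6
        with pytest.raises(ValueError):
            DERecord("g", 0.5, 0.01, 1.0)  # |fc| < 1 is not the signed convention
        with pytest.raises(ValueError):
            DERecord("g", 2.0, 1.5, 1.0)

    def test_dose_matrix_validation(self):
        ok = DoseMatrix((0, 1), (0, 2), np.array([[100, 80], [90, 60]]))
        assert ok.viability[0, 0] == 100
        with pytest.raises(ValueError):
            DoseMatrix((1, 2), (0, 1), np.full((2, 2), 100.0))  # first dose not 0
        with pytest.raises(ValueError):
            DoseMatrix((0, 2, 1), (0, 1), np.full((3, 2), 100.0))  # not increasing


class TestPeakIO:
    def test_narrowpeak_fields(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t50\t.\t3.2\t7.1\t5.0\t40\n")
        (peak,) = fio.read_peaks(str(path))
        assert (peak.chrom, peak.start, peak.end) == ("chr1", 100, 200)
        assert peak.summit_offset == 40 and peak.score == 50

    def test_summit_minus_one_means_absent(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t0\t10\tp\t0\t.\t0\t-1\t-1\t-1\n")
        assert fio.read_peaks(str(path))[0].summit_offset is None

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.narrowPeak"
        path.write_text("")
        assert fio.read_peaks(str(path)) == []

    def test_inverted_interval_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t10\tp1\t0\t.\nchr1\t20\t10\tp2\t0\t.\n")
        with pytest.raises(FormatError, match=":2"):
            fio.read_peaks(str(path), "BED6")

    def test_roundtrip_identity(self, tmp_path):
        peaks = [
            Peak(GenomicInterval("chr1", 0, 100, "+"), "a", 5.0, 50),
            Peak(GenomicInterval("chr2", 10, 30, "."), "b", 0.0, None),
        ]
        path = tmp_path / "rt.narrowPeak"
        fio.write_peaks(peaks, str(path))
        assert fio.read_peaks(str(path)) == peaks


class TestBedgraphIO:
    def test_read_sorted_steps(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chr1\t100\t300\t1.0\nchr1\t0\t100\t2.0\n")
        track = fio.read_bedgraph(str(path), total_reads=1e6)
        np.testing.assert_array_equal(
            track.steps("chr1"), [[0, 100, 2.0], [100, 300, 1.0]]
        )

    def test_overlapping_steps_rejected(self, tmp_path):
        path = tmp_path / "bad.bedgraph"
        path.write_text("chr1\t0\t100\t1\nchr1\t50\t150\t1\n")
        with pytest.raises(FormatError):
            fio.read_bedgraph(str(path), 1e6)

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "bad.bedgraph"
        path.write_text("chr1\t0\t100\t-1\n")
        with pytest.raises(FormatError):
            fio.read_bedgraph(str(path), 1e6)

    def test_roundtrip_identity(self, tmp_path):
        track = CoverageTrack(
            {"chr1": [(0, 100, 2.0), (150, 300, 1.5)], "chr2": [(10, 20, 0.25)]},
            total_reads=5e6,
        )
        path = tmp_path / "rt.bedgraph"
        fio.write_bedgraph(track, str(path))
        back = fio.read_bedgraph(str(path), 5e6)
        for chrom in ("chr1", "chr2"):
            np.testing.assert_array_equal(back.steps(chrom), track.steps(chrom))

    def test_gap_is_implicit_zero(self):
        track = CoverageTrack({"chr1": [(0, 10, 2.0), (20, 30, 4.0)]}, 1e6)
        assert track.integral("chr1", 10, 20) == 0.0
        assert track.integral("chr1", 0, 30) == pytest.approx(60.0)


class TestTableIO:
    def test_gene_model_roundtrip_and_tss(self, tmp_path):
        genes = [
            GeneModel("g1", GenomicInterval("chr1", 1000, 5000, "+")),
            GeneModel("g2", GenomicInterval("chr1", 1000, 5000, "-")),
        ]
        path = tmp_path / "genes.tsv"
        fio.write_gene_model(genes, str(path))
        back = fio.read_gene_model(str(path))
        assert back == genes
        assert [g.tss for g in back] == [1000, 4999]

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("gene_id\tchrom\tstart\tend\ng1\tchr1\t0\t10\n")
        with pytest.raises(FormatError, match="strand"):
            fio.read_gene_model(str(path))

    def test_de_table_roundtrip(self, tmp_path):
        records = [DERecord("g1", 1.6, 0.01, 12.3), DERecord("g2", -2.0, 0.5, 3.0)]
        path = tmp_path / "de.tsv"
        fio.write_de_table(records, str(path))
        assert fio.read_de_table(str(path)) == records

    def test_de_padj_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text("gene_id\tfold_change\tpadj\tmean_expr_cpm\ng1\t2.0\t1.2\t1\n")
        with pytest.raises(FormatError):
            fio.read_de_table(str(path))

    def test_dose_matrix_roundtrip(self, tmp_path):
        m = DoseMatrix((0, 1, 2), (0, 4, 8),
                       np.array([[100, 90, 70], [95, 80, 55], [85, 60, 30.5]]))
        path = tmp_path / "dose.csv"
        fio.write_dose_matrix(m, str(path))
        back = fio.read_dose_matrix(str(path))
        assert back.drug_a_doses == m.drug_a_doses
        assert back.drug_b_doses == m.drug_b_doses
        np.testing.assert_allclose(back.viability, m.viability)
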