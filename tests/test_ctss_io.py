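import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cagecall.ctss_io import (
    FormatError,
    GeneModels,
    GffParseError,
    derive_utrs,
    read_clusters_bed,
    read_ctss_bedgraph,
    read_gene_models_gff3,
    read_sample_sheet,
    write_clusters_bed,
    write_ctss_bedgraph,
    write_gene_models_gff3,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return str(path)


class TestBedgraph:
    def test_parses_single_bp_lines(self, tmp_path):
        plus = _write(tmp_path, "p.bg", "chr1\t100\t101\t5\nchr1\t130\t131\t2\n")
        minus = _write(tmp_path, "m.bg", "")
        track = read_ctss_bedgraph(plus, minus, "s1", 1_000_000)
        got = {(r.chrom, r.pos, r.strand): r.count for r in track.data.itertuples()}
        assert got == {("chr1", 100, "+"): 5, ("chr1", 130, "+"): 2}

    def test_expands_wide_intervals_per_bp(self, tmp_path):
        plus = _write(tmp_path, "p.bg", "chr1\t10\t13\t4\n")
        minus = _write(tmp_path, "m.bg", "")
        track = read_ctss_bedgraph(plus, minus, "s1", 1_000_000)
        assert list(track.data["pos"]) == [10, 11, 12]
        assert list(track.data["count"]) == [4, 4, 4]

    def test_minus_file_populates_minus_strand(self, tmp_path):
        plus = _write(tmp_path, "p.bg", "")
        minus = _write(tmp_path, "m.bg", "chr2\t7\t8\t3\n")
        track = read_ctss_bedgraph(plus, minus, "s1", 1000)
        assert list(track.data["strand"]) == ["-"]

    @pytest.mark.parametrize(
        "line", ["chr1\t5\t6\t-3", "chr1\t5\t6\t0", "chr1\t5\t6\t2.5", "chr1\t6\t6\t2", "chr1\t9\t6\t2"]
    )
    def test_rejects_bad_values_naming_the_line(self, tmp_path, line):
        plus = _write(tmp_path, "p.bg", line + "\n")
        minus = _write(tmp_path, "m.bg", "")
        with pytest.raises(FormatError, match=":1"):
            read_ctss_bedgraph(plus, minus, "s1", 1000)

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 500), st.integers(1, 5), st.integers(1, 9)
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_expansion_conserves_tag_mass(self, tmp_path_factory, intervals):
        # non-overlapping intervals built from sorted starts
        tmp_path = tmp_path_factory.mktemp("bg")
        lines = []
        cursor = 0
        expected = 0
        for offset, width, value in intervals:
            start = cursor + offset
            lines.append(f"chr1\t{start}\t{start + width}\t{value}")
            expected += width * value
            cursor = start + width
        plus = _write(tmp_path, "p.bg", "\n".join(lines) + "\n")
        minus = _write(tmp_path, "m.bg", "")
        track = read_ctss_bedgraph(plus, minus, "s1", 1000)
        assert track.total_tags == expected

    def test_roundtrip_through_writer(self, tmp_path):
        plus = _write(tmp_path, "p.bg", "chr1\t10\t13\t4\nchr2\t5\t6\t1\n")
        minus = _write(tmp_path, "m.bg", "chr1\t99\t100\t7\n")
        track = read_ctss_bedgraph(plus, minus, "s1", 1000)
        write_ctss_bedgraph(track, str(tmp_path / "p2.bg"), str(tmp_path / "m2.bg"))
        back = read_ctss_bedgraph(str(tmp_path / "p2.bg"), str(tmp_path / "m2.bg"), "s1", 1000)
        pd.testing.assert_frame_equal(track.data, back.data)


GFF_EXAMPLE = """##gff-version 3
chr1\t.\tgene\t1001\t2000\t.\t+\t.\tID=g1;Name=ABC
chr1\t.\tmRNA\t1001\t2000\t.\t+\t.\tID=t1;Parent=g1
chr1\t.\texon\t1001\t1200\t.\t+\t.\tParent=t1
chr1\t.\texon\t1501\t2000\t.\t+\t.\tParent=t1
chr1\t.\tCDS\t1101\t1900\t.\t+\t.\tParent=t1
"""


class TestGff3:
    def test_coordinates_become_zero_based_half_open(self, tmp_path):
        models = read_gene_models_gff3(_write(tmp_path, "a.gff3", GFF_EXAMPLE))
        gene = models.genes.iloc[0]
        assert (gene["start"], gene["end"]) == (1000, 2000)

    def test_utrs_derived_from_exon_minus_cds(self, tmp_path):
        models = read_gene_models_gff3(_write(tmp_path, "a.gff3", GFF_EXAMPLE))
        utr5 = models.features[models.features["kind"] == "five_prime_UTR"]
        assert [(r.start, r.end) for r in utr5.itertuples()] == [(1000, 1100)]
        utr3 = models.features[models.features["kind"] == "three_prime_UTR"]
        assert [(r.start, r.end) for r in utr3.itertuples()] == [(1900, 2000)]

    def test_orphan_child_raises_naming_it(self, tmp_path):
        bad = GFF_EXAMPLE + "chr1\t.\texon\t1\t10\t.\t+\t.\tID=orphanexon;Parent=missing\n"
        with pytest.raises(GffParseError, match="orphanexon"):
            read_gene_models_gff3(_write(tmp_path, "bad.gff3", bad))

    def test_noncoding_transcript_has_only_exon_features(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chr1\t.\tgene\t101\t300\t.\t-\t.\tID=g2\n"
            "chr1\t.\tmRNA\t101\t300\t.\t-\t.\tID=t2;Parent=g2\n"
            "chr1\t.\texon\t101\t300\t.\t-\t.\tParent=t2\n"
        )
        models = read_gene_models_gff3(_write(tmp_path, "nc.gff3", text))
        assert set(models.features["kind"]) == {"exon"}

    def test_reader_inverts_writer_on_generated_models(self, tmp_path, default_sim):
        path = str(tmp_path / "sim.gff3")
        write_gene_models_gff3(default_sim.models, path)
        back = read_gene_models_gff3(path)
        for attr in ("genes", "transcripts"):
            a = getattr(default_sim.models, attr).sort_values(list(getattr(default_sim.models, attr).columns)).reset_index(drop=True)
            b = getattr(back, attr).sort_values(list(a.columns)).reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)
        cols = ["tx_id", "kind", "chrom", "start", "end", "strand"]
        a = default_sim.models.features[cols].sort_values(cols).reset_index(drop=True)
        b = back.features[cols].sort_values(cols).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_derive_utrs_minus_strand_orientation(self):
        # exon left of CDS is 3' UTR on the minus strand
        utrs = derive_utrs([(0, 100), (200, 300)], [(50, 100), (200, 250)], "-")
        assert ("three_prime_UTR", 0, 50) in utrs
        assert ("five_prime_UTR", 250, 300) in utrs


class TestClusterBed:
    def _tss_frame(self):
        return pd.DataFrame(
            {
                "cluster_id": ["c1"],
                "chrom": ["chr1"],
                "start": [100],
                "end": [150],
                "strand": ["+"],
                "peak_pos": [120],
                "pooled_ctpm": [55.4],
            }
        )

    def test_tss_bed12_thick_marks_peak(self, tmp_path):
        path = str(tmp_path / "t.bed")
        write_clusters_bed(self._tss_frame(), path)
        fields = open(path).read().strip().split("\t")
        assert len(fields) == 12
        assert (fields[6], fields[7]) == ("120", "121")
        assert fields[4] == "55"

    def test_enhancer_bed6_is_strandless(self, tmp_path):
        enh = pd.DataFrame(
            {
                "cluster_id": ["e1"],
                "chrom": ["chr1"],
                "start": [300],
                "end": [900],
                "midpoint": [600],
                "pooled_ctpm": [12.0],
            }
        )
        path = str(tmp_path / "e.bed")
        write_clusters_bed(enh, path)
        fields = open(path).read().strip().split("\t")
        assert len(fields) == 6
        assert fields[5] == "."

    def test_roundtrip_preserves_coords_strand_peak(self, tmp_path):
        path = str(tmp_path / "t.bed")
        frame = self._tss_frame()
        write_clusters_bed(frame, path)
        back = read_clusters_bed(path)
        assert back.loc[0, ["chrom", "start", "end", "strand", "peak_pos"]].tolist() == [
            "chr1", 100, 150, "+", 120,
        ]

    def test_unsorted_input_is_an_error(self, tmp_path):
        frame = pd.concat([self._tss_frame().assign(start=500, end=550, peak_pos=510), self._tss_frame()])
        frame = frame.reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            write_clusters_bed(frame, str(tmp_path / "x.bed"))


class TestSampleSheet:
    def test_reads_and_validates(self, tmp_path):
        text = (
            "sample_id\ttissue\tpopulation\tpath_plus\tpath_minus\tlibrary_size\n"
            "s1\tliver\tholstein\ta.bg\tb.bg\t1000\n"
        )
        sheet = read_sample_sheet(_write(tmp_path, "s.tsv", text))
        assert sheet.loc[0, "tissue"] == "liver"

    def test_duplicate_ids_rejected(self, tmp_path):
        text = (
            "sample_id\ttissue\tpopulation\tpath_plus\tpath_minus\tlibrary_size\n"
            "s1\tliver\thol\ta\tb\t1000\ns1\tbrain\thol\tc\td\t1000\n"
        )
        with pytest.raises(FormatError, match="duplicate"):
            read_sample_sheet(_write(tmp_path, "s.tsv", text))
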