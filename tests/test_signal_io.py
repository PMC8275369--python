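"""Interval parsing, binning arithmetic and window extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from encore.signal_io import (AssayPanel, BedParseError, GenomicInterval,
                              SignalTrack, bin_signal, extract_window_matrix,
                              read_chrom_sizes, read_intervals,
                              sliding_windows, write_bed)


class TestGenomicInterval:
    def test_rejects_invalid_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 5)

    def test_midpoint_is_floor(self):
        assert GenomicInterval("chr1", 0, 3).midpoint == 1
        assert GenomicInterval("chr1", 10000, 10200).midpoint == 10100


class TestBedParsing:
    def test_valid_bed_round_trip(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\nchr1\t50\t150\nchr2\t7\t12\n")
        ivs = read_intervals(p)
        assert [(i.chrom, i.start, i.end) for i in ivs] == [
            ("chr1", 0, 100), ("chr1", 50, 150), ("chr2", 7, 12)]

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_intervals(p) == []

    @pytest.mark.parametrize("line,msg", [
        ("chr1\t100\t50\n", "line 1"),
        ("chr1\t0\n", "line 1"),
        ("chr1\tzero\t100\n", "line 1"),
    ])
    def test_malformed_line_reports_line_number(self, tmp_path, line, msg):
        p = tmp_path / "bad.bed"
        p.write_text(line)
        with pytest.raises(BedParseError, match=msg):
            read_intervals(p)

    def test_error_names_later_lines(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\t200\t100\n")
        with pytest.raises(BedParseError, match="line 2"):
            read_intervals(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_intervals(tmp_path / "nope.bed")

    def test_write_read_round_trip_with_scores(self, tmp_path):
        ivs = [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 80, 90)]
        p = tmp_path / "out.bed"
        write_bed(p, ivs, scores=[1.0, 0.0])
        back = read_intervals(p)
        assert [(i.start, i.end) for i in back] == [(0, 50), (80, 90)]

    def test_chrom_sizes(self, tmp_path):
        p = tmp_path / "sizes"
        p.write_text("chr1\t10000\nchr2\t5000\n")
        assert read_chrom_sizes(p) == {"chr1": 10000, "chr2": 5000}


class TestAssayPanel:
    def test_accessibility_must_be_middle_row(self):
        with pytest.raises(ValueError):
            AssayPanel(("accessibility", "H3K9ac", "H3K4me3", "H3K27ac",
                        "H3K4me1"))
        panel = AssayPanel()
        assert panel.assays[panel.accessibility_row] == "accessibility"

    def test_exactly_five_assays(self):
        with pytest.raises(ValueError):
            AssayPanel(("a", "b", "accessibility", "c"), "accessibility")


class TestBinSignal:
    def test_constant_track_bins_to_constant(self):
        t = SignalTrack("x", {"chr1": np.full(4000, 2.0, dtype=np.float32)})
        v = bin_signal(t, GenomicInterval("chr1", 0, 4000))
        assert v.shape == (400,)
        assert np.allclose(v, 2.0)

    def test_ramp_means_match_brute_force(self):
        t = SignalTrack("x", {"chr1": np.arange(40, dtype=np.float32)})
        v = bin_signal(t, GenomicInterval("chr1", 0, 40), bin_size=10)
        assert np.allclose(v, [4.5, 14.5, 24.5, 34.5])

    def test_uncovered_window_is_zero(self):
        t = SignalTrack("x", {"chr1": np.ones(100, dtype=np.float32)})
        v = bin_signal(t, GenomicInterval("chr2", 0, 4000))
        assert np.all(v == 0.0)
        # partially covered: beyond track end reads as zero
        v2 = bin_signal(t, GenomicInterval("chr1", 0, 4000))
        assert v2[0] == 1.0 and np.all(v2[10:] == 0.0)

    def test_indivisible_window_rejected(self):
        t = SignalTrack("x", {"chr1": np.ones(100, dtype=np.float32)})
        with pytest.raises(ValueError, match="divisible"):
            bin_signal(t, GenomicInterval("chr1", 0, 35), bin_size=10)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 3000), st.integers(1, 50).map(lambda k: k * 10))
    def test_mass_conservation(self, start, length):
        # sum(bin means) * bin_size == sum of base values over the window
        rng = np.random.default_rng(0)
        base = rng.random(8000).astype(np.float32)
        t = SignalTrack("x", {"chr1": base})
        w = GenomicInterval("chr1", start, start + length)
        v = bin_signal(t, w, bin_size=10)
        assert np.isclose(v.sum() * 10, base[start:start + length].sum(),
                          rtol=1e-4)


class TestExtractWindowMatrix:
    def test_rows_follow_panel_order(self, toy_tracks):
        m = extract_window_matrix(toy_tracks, GenomicInterval("chr1", 0, 4000))
        assert m.data.shape == (5, 400)
        for r in range(5):
            assert np.allclose(m.data[r], r + 1)

    def test_accessibility_row_independent_of_argument_order(self, toy_tracks):
        panel = AssayPanel()
        shuffled = [toy_tracks[a] for a in
                    ("H3K27ac", "accessibility", "H3K4me1", "H3K4me3",
                     "H3K9ac")]
        m = extract_window_matrix(shuffled, GenomicInterval("chr1", 0, 4000),
                                  panel)
        acc_value = panel.index("accessibility") + 1  # toy value = row idx + 1
        assert np.allclose(m.data[2], acc_value)

    def test_single_base_spike_lands_in_containing_bin(self):
        from encore.signal_io import AssayPanel
        panel = AssayPanel()
        tracks = {}
        for a in panel.assays:
            arr = np.zeros(8000, dtype=np.float32)
            tracks[a] = SignalTrack(a, {"chr1": arr})
        # spike at the window midpoint: floor((1000+5000)/2) = 3000 -> bin 200
        tracks["accessibility"].values["chr1"][3000] = 10.0
        m = extract_window_matrix(tracks, GenomicInterval("chr1", 1000, 5000))
        nz = np.flatnonzero(m.data[2])
        assert list(nz) == [200]
        assert np.isclose(m.data[2, 200], 1.0)  # 10.0 averaged over 10 bp

    def test_missing_assay_raises(self, toy_tracks):
        del toy_tracks["H3K27ac"]
        with pytest.raises(KeyError, match="H3K27ac"):
            extract_window_matrix(toy_tracks, GenomicInterval("chr1", 0, 4000))

    def test_wrong_window_length_raises(self, toy_tracks):
        with pytest.raises(ValueError, match="4000"):
            extract_window_matrix(toy_tracks, GenomicInterval("chr1", 0, 2000))


class TestSlidingWindows:
    def test_count_and_starts(self):
        ws = sliding_windows(10000)
        assert len(ws) == 13
        assert [w.start for w in ws] == list(range(0, 6001, 500))
        assert all(len(w) == 4000 for w in ws)

    def test_exact_fit_single_window(self):
        assert len(sliding_windows(4000)) == 1

    def test_partial_windows_dropped(self):
        assert sliding_windows(3999) == []

    @settings(deadline=None, max_examples=50)
    @given(st.integers(1, 100_000), st.integers(1, 5000), st.integers(1, 3000))
    def test_count_formula(self, length, window, step):
        ws = sliding_windows(length, window=window, step=step)
        expected = (length - window) // step + 1 if length >= window else 0
        assert len(ws) == expected

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sliding_windows(1000, step=0)
        with pytest.raises(ValueError):
            sliding_windows(0)


class TestTrackIO:
    def test_bedgraph_round_trip(self, tmp_path):
        arr = np.zeros(200, dtype=np.float32)
        arr[20:50] = 1.5
        arr[100:110] = 3.0
        t = SignalTrack("accessibility", {"chr1": arr})
        p = tmp_path / "t.bedgraph"
        t.to_bedgraph(p)
        back = SignalTrack.from_bedgraph(p, "accessibility",
                                         chrom_sizes={"chr1": 200})
        assert np.allclose(back.values["chr1"], arr)

    def test_bigwig_round_trip(self, tmp_path):
        pyBigWig = pytest.importorskip("pyBigWig")
        arr = np.abs(np.sin(np.arange(300, dtype=np.float32)))
        p = str(tmp_path / "t.bw")
        bw = pyBigWig.open(p, "w")
        bw.addHeader([("chr1", 300)])
        bw.addEntries("chr1", 0, values=[float(v) for v in arr], span=1,
                      step=1)
        bw.close()
        t = SignalTrack.from_bigwig(p, "accessibility")
        assert np.allclose(t.values["chr1"], arr, atol=1e-5)

    def test_negative_bedgraph_value_rejected(self, tmp_path):
        p = tmp_path / "neg.bedgraph"
        p.write_text("chr1\t0\t10\t-1.0\n")
        with pytest.raises(ValueError, match="negative"):
            SignalTrack.from_bedgraph(p, "x", chrom_sizes={"chr1": 100})
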