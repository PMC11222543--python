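import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sangerase.errors import (
    ParameterError,
    SchemaError,
    TraceParseError,
    ValidationError,
)
from sangerase.synthetic_data import ChromatogramSpec, simulate_chromatogram
from sangerase.trace_io import (
    ChromatogramRecord,
    PeakRecord,
    SiteSignal,
    extract_site_signal,
    read_chromatogram,
    read_peak_table,
    write_peak_table,
)


def make_record(channels, base_calls):
    return ChromatogramRecord(
        sample_id="s1",
        molecule="gDNA",
        tissue="liver",
        base_calls=base_calls,
        channels={k: np.asarray(v, dtype=float) for k, v in channels.items()},
    )


class TestChromatogramReading:
    def test_abif_round_trip_preserves_calls_and_channels(self, tmp_path):
        """A written fixture with 10 called bases reads back identically."""
        spec = ChromatogramSpec(
            sample_id="m1",
            sequence="ACGTACGTAC",
            site_heights={4: {"A": 1000, "G": 950}},
            molecule="cDNA",
            tissue="brain",
        )
        rec = read_chromatogram(str(simulate_chromatogram(spec, tmp_path / "m1.ab1")))
        assert rec.sequence == "ACGTACGTAC"
        assert len(rec.base_calls) == 10
        assert (rec.sample_id, rec.molecule, rec.tissue) == ("m1", "cDNA", "brain")
        assert all(len(rec.channels[n]) == 120 for n in "ACGT")
        sig = extract_site_signal(rec, 4, window=0)
        assert sig.intensities == {"A": 1000.0, "C": 0.0, "G": 950.0, "T": 0.0}

    def test_trace_indices_preserve_order(self, tmp_path):
        spec = ChromatogramSpec(sample_id="m1", sequence="ACGT")
        rec = read_chromatogram(str(simulate_chromatogram(spec, tmp_path / "x.ab1")))
        indices = [i for _, i in rec.base_calls]
        assert indices == sorted(indices)

    def test_truncated_file_raises_parse_error(self, tmp_path):
        spec = ChromatogramSpec(sample_id="m1", sequence="ACGTACGT")
        path = simulate_chromatogram(spec, tmp_path / "t.ab1")
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(TraceParseError):
            read_chromatogram(str(path))

    def test_non_abif_file_rejected(self, tmp_path):
        p = tmp_path / "x.ab1"
        p.write_bytes(b"not a trace file")
        with pytest.raises(TraceParseError):
            read_chromatogram(str(p))


class TestExtractSiteSignal:
    def test_window_zero_is_direct_lookup(self):
        rec = make_record(
            {"A": [0, 9, 0], "C": [0, 0, 0], "G": [0, 0, 0], "T": [0, 0, 0]},
            [("A", 1)],
        )
        sig = extract_site_signal(rec, 0, window=0)
        assert sig.intensities == {"A": 9.0, "C": 0.0, "G": 0.0, "T": 0.0}

    def test_windowed_max_picks_nearby_peak(self):
        rec = make_record(
            {"A": [0, 9, 0], "C": [0, 0, 0], "G": [7, 0, 0], "T": [0, 0, 0]},
            [("A", 1)],
        )
        sig = extract_site_signal(rec, 0, window=1)
        assert sig.intensities["A"] == 9.0
        assert sig.intensities["G"] == 7.0

    def test_window_clipped_at_array_bounds(self):
        rec = make_record(
            {"A": [5, 0, 0], "C": [0, 0, 0], "G": [0, 0, 0], "T": [0, 0, 3]},
            [("A", 0)],
        )
        sig = extract_site_signal(rec, 0, window=100)
        assert sig.intensities["A"] == 5.0
        assert sig.intensities["T"] == 3.0

    def test_base_index_out_of_range(self):
        rec = make_record(
            {"A": [1, 1], "C": [0, 0], "G": [0, 0], "T": [0, 0]}, [("A", 0)]
        )
        with pytest.raises(IndexError):
            extract_site_signal(rec, 5)

    @given(
        window_small=st.integers(0, 3),
        extra=st.integers(1, 5),
        values=st.lists(st.integers(0, 1000), min_size=9, max_size=9),
    )
    @settings(max_examples=50, deadline=None)
    def test_enlarging_window_never_decreases_intensity(
        self, window_small, extra, values
    ):
        rec = make_record(
            {
                "A": values,
                "C": values[::-1],
                "G": [0] * 9,
                "T": [1] * 9,
            },
            [("A", 4)],
        )
        small = extract_site_signal(rec, 0, window=window_small)
        large = extract_site_signal(rec, 0, window=window_small + extra)
        for n in "ACGT":
            assert large.intensities[n] >= small.intensities[n]


class TestPeakTable:
    def test_parse_single_row(self, tmp_path):
        p = tmp_path / "peaks.tsv"
        p.write_text(
            "sample_id\tmolecule\ttissue\tsite_id\tbase_index\tA\tC\tG\tT\n"
            "m1\tgDNA\tliver\ts1\t42\t1000\t5\t3\t7\n"
        )
        (rec,) = read_peak_table(str(p))
        assert rec.sample_id == "m1"
        assert rec.molecule == "gDNA"
        assert rec.signal.base_index == 42
        assert rec.signal.intensities == {"A": 1000.0, "C": 5.0, "G": 3.0, "T": 7.0}

    def test_empty_table_gives_empty_list(self, tmp_path):
        p = tmp_path / "peaks.tsv"
        p.write_text("sample_id\tmolecule\ttissue\tsite_id\tbase_index\tA\tC\tG\tT\n")
        assert read_peak_table(str(p)) == []

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "peaks.tsv"
        p.write_text("sample_id\tmolecule\tsite_id\tbase_index\tA\tC\tG\tT\nx\tg\ts\t0\t1\t1\t1\t1\n")
        with pytest.raises(SchemaError):
            read_peak_table(str(p))

    def test_negative_intensity_is_validation_error(self, tmp_path):
        p = tmp_path / "peaks.tsv"
        p.write_text(
            "sample_id\tmolecule\ttissue\tsite_id\tbase_index\tA\tC\tG\tT\n"
            "m1\tgDNA\tliver\ts1\t42\t-1\t5\t3\t7\n"
        )
        with pytest.raises(ValidationError):
            read_peak_table(str(p))

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1e5, allow_nan=False),
                st.floats(0, 1e5, allow_nan=False),
                st.floats(0, 1e5, allow_nan=False),
                st.floats(0, 1e5, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_write_read_round_trip_is_exact(self, rows):
        records = [
            PeakRecord(
                sample_id=f"s{i}",
                molecule="cDNA",
                tissue="liver",
                signal=SiteSignal(
                    site_id=f"site{i}",
                    base_index=i,
                    intensities=dict(zip("ACGT", vals)),
                ),
                transcript="TX1",
            )
            for i, vals in enumerate(rows)
        ]
        buf = io.StringIO()
        write_peak_table(records, buf)
        buf.seek(0)
        back = read_peak_table(buf)
        assert len(back) == len(records)
        for orig, rt in zip(records, back):
            assert rt.signal.intensities == orig.signal.intensities
            assert rt.transcript == orig.transcript


class TestSiteSignalInvariants:
    def test_requires_all_four_channels(self):
        with pytest.raises(ValidationError):
            SiteSignal("s", 0, {"A": 1.0, "C": 1.0})

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValidationError):
            SiteSignal("s", 0, {"A": -1.0, "C": 0.0, "G": 0.0, "T": 0.0})

    def test_bad_window_rejected(self):
        rec = make_record(
            {"A": [1], "C": [0], "G": [0], "T": [0]}, [("A", 0)]
        )
        with pytest.raises(ParameterError):
            extract_site_signal(rec, 0, window=-1)
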