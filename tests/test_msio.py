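import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoscreen import msio


def _run(scans):
    return msio.RawRun(run_id="r1", scans=scans, metadata={"enzyme": "E1"})


def _ms1(rt, mz, inten):
    return msio.PeakSpectrum(
        mz=mz, intensity=inten, level=1, retention_time=rt, scan_id=f"s{rt}"
    )


def _ms2(rt, precursor, mz, inten):
    return msio.PeakSpectrum(
        mz=mz, intensity=inten, level=2, precursor_mz=precursor,
        retention_time=rt, scan_id=f"s{rt}",
    )


class TestPeakSpectrum:
    def test_peaks_sorted_on_construction(self):
        s = _ms1(0.0, [300.0, 100.0, 200.0], [1.0, 2.0, 3.0])
        assert list(s.mz) == [100.0, 200.0, 300.0]
        assert list(s.intensity) == [2.0, 3.0, 1.0]

    def test_ms2_requires_precursor(self):
        with pytest.raises(ValueError, match="precursor"):
            msio.PeakSpectrum(mz=[100.0], intensity=[1.0], level=2)

    def test_run_scans_time_ordered(self):
        run = _run([_ms1(2.0, [100.0], [1.0]), _ms1(1.0, [100.0], [1.0])])
        assert [s.retention_time for s in run.scans] == [1.0, 2.0]


class TestMzml:
    def test_round_trip(self, tmp_path):
        run = _run([
            _ms1(0.5, [100.0, 200.123456], [5.0, 10.0]),
            _ms1(0.6, [150.0], [1.0]),
            _ms1(0.7, [], []),
            _ms2(0.65, 431.1342, [120.5, 268.07], [3.0, 100.0]),
            _ms2(0.75, 453.1161, [99.9], [1.0]),
        ])
        path = tmp_path / "fixture.mzML"
        msio.write_mzml(run, path)
        back = msio.read_mzml(path)
        assert len(back.scans) == 5
        assert len(back.ms2()) == 2
        for a, b in zip(run.scans, back.scans):
            np.testing.assert_allclose(a.mz, b.mz, atol=1e-6)
            np.testing.assert_allclose(a.intensity, b.intensity, atol=1e-6)
            assert a.level == b.level
            assert abs(a.retention_time - b.retention_time) < 1e-6
            if a.level == 2:
                assert abs(a.precursor_mz - b.precursor_mz) < 1e-6

    def test_empty_run(self, tmp_path):
        path = tmp_path / "empty.mzML"
        msio.write_mzml(_run([]), path)
        assert len(msio.read_mzml(path).scans) == 0

    def test_malformed_xml_raises(self, tmp_path):
        path = tmp_path / "bad.mzML"
        path.write_text("<mzML><spectrum oops")
        with pytest.raises(ValueError, match="malformed"):
            msio.read_mzml(path)


class TestMsp:
    def _records(self):
        return [
            msio.ReferenceRecord(
                name="compound a", mz=[100.0, 200.0], intensity=[1.0, 0.5],
                record_id="R1", precursor_mz=269.0809, adduct="[M+H]+",
            ),
            msio.ReferenceRecord(
                name="compound b", mz=[150.5], intensity=[2.0], record_id="R2",
            ),
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "lib.msp"
        msio.write_msp(self._records(), path)
        back = msio.read_msp(path)
        assert len(back) == 2
        assert back[0].name == "compound a"
        assert back[0].precursor_mz == pytest.approx(269.0809, abs=1e-5)
        assert len(back[0].mz) == 2
        assert back[1].precursor_mz is None

    def test_bad_record_skipped_with_log(self, tmp_path, caplog):
        path = tmp_path / "lib.msp"
        path.write_text(
            "Name: ok\nNum Peaks: 1\n100.0 1.0\n\n"
            "Name: broken\nNum Peaks: 3\n100.0 1.0\n"
        )
        with caplog.at_level("WARNING"):
            back = msio.read_msp(path)
        assert [r.name for r in back] == ["ok"]
        assert "skipping" in caplog.text

    def test_zero_peak_record_skipped(self, tmp_path):
        path = tmp_path / "lib.msp"
        path.write_text("Name: nothing\nNum Peaks: 0\n")
        assert msio.read_msp(path) == []

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=50, max_value=900),
                st.floats(min_value=0.001, max_value=1e6),
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_round_trip_fuzzed(self, peaks):
        import tempfile
        from pathlib import Path

        rec = msio.ReferenceRecord(
            name="fuzz", mz=[p[0] for p in peaks], intensity=[p[1] for p in peaks],
            record_id="F", precursor_mz=950.0,
        )
        with tempfile.TemporaryDirectory() as d:
            path = Path(d) / "f.msp"
            msio.write_msp([rec], path)
            back = msio.read_msp(path)[0]
        assert len(back.mz) == len(rec.mz)
        np.testing.assert_allclose(back.mz, rec.mz, atol=1e-5)


class TestMgf:
    def test_round_trip(self, tmp_path):
        spectra = [_ms2(1.5, 431.1342, [100.0, 268.07], [1.0, 2.0])]
        path = tmp_path / "f.mgf"
        msio.write_mgf(spectra, path)
        back = msio.read_mgf(path)
        assert len(back) == 1
        assert back[0].precursor_mz == pytest.approx(431.1342)
        assert back[0].retention_time == pytest.approx(1.5)
        np.testing.assert_allclose(back[0].mz, spectra[0].mz)

    def test_missing_pepmass_raises(self, tmp_path):
        path = tmp_path / "f.mgf"
        path.write_text("BEGIN IONS\nTITLE=x\n100.0 1.0\nEND IONS\n")
        with pytest.raises(ValueError, match="PEPMASS"):
            msio.read_mgf(path)


class TestJsonl:
    def test_round_trip_lossless(self, tmp_path):
        run = _run([
            _ms1(0.123456789, [100.000000123], [7.0]),
            _ms2(0.2, 431.1342, [120.5], [3.0]),
        ])
        path = tmp_path / "run.jsonl"
        msio.write_jsonl(run, path)
        back = msio.read_jsonl(path)
        assert back.metadata == run.metadata
        np.testing.assert_array_equal(back.scans[0].mz, run.scans[0].mz)
        assert back.scans[0].retention_time == run.scans[0].retention_time


class TestTables:
    def test_missing_required_column_raises(self, tmp_path):
        path = tmp_path / "t.tsv"
        pd.DataFrame({"a": [1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing required"):
            msio.read_table(path, required=["compound_id"])

    def test_unknown_column_warns(self, tmp_path):
        path = tmp_path / "t.tsv"
        pd.DataFrame({"compound_id": ["a"], "extra": [1]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.warns(UserWarning, match="unknown columns"):
            msio.read_table(path, required=["compound_id"], known=["compound_id"])

    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({"compound_id": ["a", "b"], "neutral_mass": [1.5, 2.5]})
        path = tmp_path / "t.tsv"
        msio.write_table(df, path)
        back = msio.read_table(path, required=["compound_id", "neutral_mass"])
        pd.testing.assert_frame_equal(df, back)
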