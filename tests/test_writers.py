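"""Marker and time-series writers: format contracts and lossless round trips."""

import numpy as np
import pytest

from gaitpipe.forceplate import GRFSeries
from gaitpipe.writers import (WriterError, grf_column_names, read_timeseries,
                              read_trc, write_emg_mot, write_grf_mot, write_trc)


def _markers(nframes=3, nmarkers=2, seed=0):
    rng = np.random.default_rng(seed)
    return {f"M{i + 1}": rng.normal(scale=500, size=(nframes, 3)).round(4)
            for i in range(nmarkers)}


class TestTrc:
    def test_header_and_column_accounting(self, tmp_path):
        path = tmp_path / "t.trc"
        write_trc(_markers(), 100.0, path, units="mm")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("PathFileType\t4\t(X/Y/Z)")
        vals = lines[2].split("\t")
        assert vals[2] == "3" and vals[3] == "2" and vals[4] == "mm"
        first = lines[5].split("\t")
        assert len(first) == 8                       # Frame#, Time, 2 x XYZ
        times = [lines[5 + i].split("\t")[1] for i in range(3)]
        assert times == ["0.000000", "0.010000", "0.020000"]

    def test_round_trip_exact_at_precision(self, tmp_path):
        markers = _markers(nframes=20, nmarkers=4, seed=3)
        path = tmp_path / "rt.trc"
        write_trc(markers, 100.0, path)
        back, rate, units = read_trc(path)
        assert rate == 100.0 and units == "mm"
        for lb, arr in markers.items():
            np.testing.assert_allclose(back[lb], arr.round(6), atol=5e-7)

    def test_missing_samples_written_empty_read_as_nan(self, tmp_path):
        markers = _markers(nframes=10)
        masks = {"M1": np.zeros(10, bool)}
        masks["M1"][4:6] = True
        path = tmp_path / "gap.trc"
        write_trc(markers, 100.0, path, masks=masks)
        raw_row = path.read_text().splitlines()[9]   # frame 5
        assert "\t\t\t" in raw_row
        back, _, _ = read_trc(path)
        assert np.isnan(back["M1"][4:6]).all()
        assert np.isfinite(back["M1"][6:]).all()
        assert np.isfinite(back["M2"]).all()

    def test_units_tag_configurable(self, tmp_path):
        path = tmp_path / "m.trc"
        write_trc(_markers(), 100.0, path, units="m")
        assert read_trc(path)[2] == "m"

    def test_inconsistent_lengths_rejected(self, tmp_path):
        markers = {"A": np.zeros((5, 3)), "B": np.zeros((6, 3))}
        with pytest.raises(WriterError):
            write_trc(markers, 100.0, tmp_path / "x.trc")


def _grf(n, plate_index, seed=0):
    rng = np.random.default_rng(seed + plate_index)
    return GRFSeries(F=rng.normal(scale=300, size=(n, 3)).round(4),
                     cop=rng.normal(scale=0.2, size=(n, 3)).round(5),
                     torque=rng.normal(scale=5, size=(n, 3)).round(5),
                     contact=np.ones(n, bool), frame="global",
                     plate_index=plate_index)


class TestGrfMot:
    def test_two_plates_61_frames_is_19_by_61(self, tmp_path):
        path = tmp_path / "grf.mot"
        write_grf_mot([_grf(61, 1), _grf(61, 2)], 1000.0, path)
        text = path.read_text().splitlines()
        assert "datacolumns 19" in text[1]
        assert "datarows 61" in text[2]
        cols, table = read_timeseries(path)
        assert len(cols) == 19 and table.shape == (61, 19)

    def test_round_trip_payload(self, tmp_path):
        g1, g2 = _grf(30, 1), _grf(30, 2)
        path = tmp_path / "grf.mot"
        write_grf_mot([g1, g2], 1000.0, path)
        cols, table = read_timeseries(path)
        np.testing.assert_allclose(table[:, 1:4], g1.F, atol=5e-7)
        np.testing.assert_allclose(table[:, 4:7], g1.cop, atol=5e-7)
        np.testing.assert_allclose(table[:, 16:19], g2.torque, atol=5e-7)

    def test_time_column_is_arithmetic_sequence(self, tmp_path):
        path = tmp_path / "grf.mot"
        write_grf_mot([_grf(50, 1)], 200.0, path)
        _, table = read_timeseries(path)
        np.testing.assert_allclose(np.diff(table[:, 0]), 1.0 / 200.0, atol=5e-7)

    def test_mismatched_plate_lengths_rejected(self, tmp_path):
        with pytest.raises(WriterError, match="same window"):
            write_grf_mot([_grf(10, 1), _grf(11, 2)], 100.0, tmp_path / "x.mot")

    def test_column_names_nine_per_plate(self):
        cols = grf_column_names([1, 2])
        assert len(cols) == 19
        assert cols[1] == "ground_force_vx" and cols[10] == "1_ground_force_vx"


class TestEmgFormats:
    def _envs(self):
        rng = np.random.default_rng(9)
        return {m: rng.random(25).round(5) for m in ("vasti", "soleus", "ta")}

    @pytest.mark.parametrize("fmt", ["mot", "sto", "txt"])
    def test_four_columns_and_round_trip(self, tmp_path, fmt):
        path = tmp_path / f"emg.{fmt}"
        envs = self._envs()
        write_emg_mot(envs, 100.0, path, fmt=fmt)
        cols, table = read_timeseries(path)
        assert cols == ["time", "vasti", "soleus", "ta"]
        assert table.shape == (25, 4)
        for j, m in enumerate(envs):
            np.testing.assert_allclose(table[:, j + 1], envs[m], atol=5e-7)

    def test_mot_and_sto_carry_identical_payload(self, tmp_path):
        envs = self._envs()
        write_emg_mot(envs, 100.0, tmp_path / "e.mot", fmt="mot")
        write_emg_mot(envs, 100.0, tmp_path / "e.sto", fmt="sto")
        _, mot = read_timeseries(tmp_path / "e.mot")
        _, sto = read_timeseries(tmp_path / "e.sto")
        np.testing.assert_array_equal(mot, sto)

    def test_sto_header_dialect(self, tmp_path):
        write_emg_mot(self._envs(), 100.0, tmp_path / "e.sto", fmt="sto")
        text = (tmp_path / "e.sto").read_text()
        assert "nRows=25" in text and "nColumns=4" in text

    def test_empty_muscle_set_rejected(self, tmp_path):
        with pytest.raises(WriterError):
            write_emg_mot({}, 100.0, tmp_path / "e.mot")
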