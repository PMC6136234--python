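"""CSV dialect round-trips, unit conversion, validity screen, gap policy."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from glucodyn.cgm_io import (
    PairedReading,
    QCReport,
    fill_gaps,
    qc_validity,
    read_cgm_csv,
    select_window,
    write_cgm_csv,
)
from glucodyn.errors import FormatError, ParameterError, QCError
from glucodyn.series import GlucoseSeries, mgdl_to_mmol, mmol_to_mgdl
from glucodyn.simulate import generate_cgm, preset


def roundtrip(series):
    buf = io.StringIO()
    write_cgm_csv(series, buf)
    buf.seek(0)
    return read_cgm_csv(buf)


class TestRoundTrip:
    def test_generated_series_survives(self, tmp_path):
        series = generate_cgm(preset("T2D"), n_points=576, seed=2)
        path = tmp_path / "s.csv"
        write_cgm_csv(series, path)
        back = read_cgm_csv(path)
        assert back.subject_id == series.subject_id
        assert len(back) == 576
        assert back.interval_min == 5
        np.testing.assert_allclose(back.values, series.values, atol=5e-5)

    def test_constant_series_formatting(self, make_series):
        buf = io.StringIO()
        write_cgm_csv(make_series([5.0] * 4), buf)
        body = [ln for ln in buf.getvalue().splitlines() if not ln.startswith("#")]
        assert all(ln.endswith(",5.0000") for ln in body[1:])

    def test_meta_flags_serialized_as_comments(self, make_series):
        series = make_series([5, 6, 7]).with_values([5, 6, 7], qc_note="ok", clip_fraction=0.0)
        buf = io.StringIO()
        write_cgm_csv(series, buf)
        text = buf.getvalue()
        assert "# meta.qc_note: ok" in text
        back = read_cgm_csv(io.StringIO(text))
        assert back.meta["qc_note"] == "ok"
        assert back.meta["clip_fraction"] == 0.0

    @given(st.lists(st.floats(min_value=2.3, max_value=22.0), min_size=2, max_size=50))
    def test_values_roundtrip_to_4dp(self, values):
        series = GlucoseSeries("h", np.asarray(values), interval_min=5.0)
        back = roundtrip(series)
        np.testing.assert_allclose(back.values, series.values, atol=5.1e-5)


class TestUnits:
    def test_mgdl_column_converted(self):
        text = "subject_id,timestamp,glucose_mgdl\nx,,100.0\nx,,90.0\n"
        series = read_cgm_csv(io.StringIO(text))
        assert series.values[0] == pytest.approx(5.55, abs=5e-3)

    def test_conversion_bijection(self):
        vals = np.linspace(2.5, 20, 37)
        np.testing.assert_allclose(mgdl_to_mmol(mmol_to_mgdl(vals)), vals, atol=1e-3)

    def test_unknown_units_rejected(self):
        text = "subject_id,glucose\nx,5.0\nx,6.0\n"
        with pytest.raises(FormatError):
            read_cgm_csv(io.StringIO(text))
        # but an explicit declaration works
        series = read_cgm_csv(io.StringIO(text), units="mmol")
        assert len(series) == 2

    def test_nonmonotone_timestamps_rejected(self):
        text = (
            "subject_id,timestamp,glucose_mmol_l\n"
            "x,2000-01-01T00:05:00,5.0\nx,2000-01-01T00:00:00,6.0\n"
        )
        with pytest.raises(FormatError):
            read_cgm_csv(io.StringIO(text))


class TestValidityScreen:
    def test_perfect_pairs_pass(self, constant_series):
        pairs = [PairedReading(5.0, 5.0)] * 4
        report = qc_validity(constant_series, pairs)
        assert report == QCReport(passed=True, mad_percent=0.0, n_pairs=4)

    def test_too_few_pairs_fail_even_if_perfect(self, constant_series):
        report = qc_validity(constant_series, [PairedReading(5.0, 5.0)] * 2)
        assert not report.passed

    def test_mad_threshold(self, constant_series):
        # relative absolute errors 10%, 20%, 60% -> MAD 30% > 28% -> fail
        pairs = [
            PairedReading(5.5, 5.0),
            PairedReading(6.0, 5.0),
            PairedReading(8.0, 5.0),
        ]
        report = qc_validity(constant_series, pairs)
        assert report.mad_percent == pytest.approx(30.0)
        assert not report.passed


class TestGaps:
    def test_midpoint_interpolation(self, make_series):
        series = make_series([5.0, 6.0])
        filled = fill_gaps(series, timestamps_min=np.array([0.0, 10.0]))
        np.testing.assert_allclose(filled.values, [5.0, 5.5, 6.0])
        assert filled.meta["interpolated_indices"] == [1]

    def test_no_gaps_identity(self, make_series):
        series = make_series([5.0, 6.0, 7.0])
        filled = fill_gaps(series, timestamps_min=np.array([0.0, 5.0, 10.0]))
        np.testing.assert_array_equal(filled.values, series.values)
        assert "interpolated_indices" not in filled.meta

    def test_long_gap_raises_named_qc_error(self, make_series):
        series = make_series([5.0, 6.0])
        with pytest.raises(QCError, match="40"):
            fill_gaps(series, timestamps_min=np.array([0.0, 40.0]), max_gap_min=30.0)


class TestWindowSelection:
    @pytest.mark.parametrize(
        "position,expected_first", [("first", 0.0), ("last", 6.0), ("centered", 3.0)]
    )
    def test_positions(self, make_series, position, expected_first):
        series = make_series(np.arange(10, dtype=float) + 3.0)
        win = select_window(series, 4, position=position)
        assert win.values[0] == expected_first + 3.0
        assert len(win) == 4

    def test_oversized_window_rejected(self, make_series):
        with pytest.raises(ParameterError):
            select_window(make_series([5, 6, 7]), 10)
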