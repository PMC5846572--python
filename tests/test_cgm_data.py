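"""Trace I/O, unit conversion, gap detection and decimation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from glyvar import (
    GlucoseTrace,
    InputFormatError,
    InsufficientDataError,
    MGDL,
    MMOL,
    ValidationError,
    convert_units,
    detect_gaps,
    read_trace,
    resample,
    write_trace,
)


def _write(tmp_path, text, name="trace.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTrace:
    def test_iso_timestamps_map_to_minutes(self, tmp_path):
        p = _write(
            tmp_path,
            "timestamp,glucose\n"
            "2024-01-01T00:00:00Z,100\n"
            "2024-01-01T00:05:00Z,110\n"
            "2024-01-01T00:10:00Z,120\n",
        )
        trace = read_trace(p)
        np.testing.assert_allclose(trace.timestamps, [0, 5, 10])
        np.testing.assert_allclose(trace.glucose, [100, 110, 120])
        assert trace.unit == MGDL

    def test_epoch_seconds_accepted(self, tmp_path):
        p = _write(tmp_path, "timestamp,glucose\n0,100\n300,110\n600,120\n")
        np.testing.assert_allclose(read_trace(p).timestamps, [0, 5, 10])

    def test_missing_glucose_row_dropped(self, tmp_path):
        p = _write(
            tmp_path,
            "timestamp,glucose\n"
            "2024-01-01T00:00:00Z,100\n"
            "2024-01-01T00:05:00Z,\n"
            "2024-01-01T00:10:00Z,120\n",
        )
        np.testing.assert_allclose(read_trace(p).timestamps, [0, 10])

    def test_unsorted_rows_sorted_by_time(self, tmp_path):
        p = _write(tmp_path, "timestamp,glucose\n600,120\n0,100\n300,110\n")
        trace = read_trace(p)
        np.testing.assert_allclose(trace.timestamps, [0, 5, 10])
        np.testing.assert_allclose(trace.glucose, [100, 110, 120])

    def test_duplicate_timestamp_rejected_with_location(self, tmp_path):
        p = _write(tmp_path, "timestamp,glucose\n0,100\n300,110\n300,115\n")
        with pytest.raises(ValidationError, match="5"):
            read_trace(p)

    def test_too_few_rows(self, tmp_path):
        p = _write(tmp_path, "timestamp,glucose\n0,100\n")
        with pytest.raises(InsufficientDataError):
            read_trace(p)

    def test_missing_column(self, tmp_path):
        p = _write(tmp_path, "time,glucose\n0,100\n300,110\n")
        with pytest.raises(InputFormatError, match="timestamp"):
            read_trace(p)

    def test_round_trip_through_writer(self, tmp_path):
        trace = GlucoseTrace(timestamps=[0, 5, 10], glucose=[100.0, 110.2, 120.5])
        p = tmp_path / "out.csv"
        write_trace(trace, p)
        back = read_trace(p)
        np.testing.assert_allclose(back.timestamps, trace.timestamps)
        np.testing.assert_allclose(back.glucose, trace.glucose)


class TestConvertUnits:
    def test_mmol_to_mgdl(self):
        trace = GlucoseTrace(timestamps=[0, 5], glucose=[5.0, 5.0], unit=MMOL)
        out = convert_units(trace, MGDL)
        np.testing.assert_allclose(out.glucose, [90.08, 90.08])
        assert out.unit == MGDL

    def test_identity_when_units_match(self):
        trace = GlucoseTrace(timestamps=[0, 5], glucose=[180.0, 180.0])
        assert convert_units(trace, "mg/dl") is trace

    def test_unknown_unit_rejected(self):
        trace = GlucoseTrace(timestamps=[0, 5], glucose=[100, 100])
        with pytest.raises(ValidationError):
            convert_units(trace, "g/L")

    @given(st.lists(st.floats(40, 400), min_size=2, max_size=20))
    def test_round_trip_within_1e9_relative(self, values):
        trace = GlucoseTrace(timestamps=np.arange(len(values)) * 5.0, glucose=values)
        back = convert_units(convert_units(trace, MMOL), MGDL)
        np.testing.assert_allclose(back.glucose, trace.glucose, rtol=1e-9)


class TestDetectGaps:
    @pytest.mark.parametrize(
        "timestamps, threshold, runs, gaps, excluded",
        [
            ([0, 5, 10, 30, 35], 7.5, ((0, 3), (3, 5)), ((10.0, 30.0),), 20.0),
            ([0, 5, 10, 15], 7.5, ((0, 4),), (), 0.0),
            ([0, 5, 10, 30, 35], 25.0, ((0, 5),), (), 0.0),
        ],
    )
    def test_hand_decompositions(self, timestamps, threshold, runs, gaps, excluded):
        trace = GlucoseTrace(timestamps=timestamps, glucose=[100] * len(timestamps))
        report = detect_gaps(trace, threshold)
        assert report.runs == runs
        assert report.gap_intervals == gaps
        assert report.excluded_minutes == excluded

    def test_default_threshold_is_1p5x_interval(self):
        # 8-min step exceeds 7.5 for 5-min data but not 1.5 x 10 for 10-min data
        trace5 = GlucoseTrace([0, 5, 13], [100, 100, 100], nominal_interval=5)
        trace10 = GlucoseTrace([0, 5, 13], [100, 100, 100], nominal_interval=10)
        assert detect_gaps(trace5).n_runs == 2
        assert detect_gaps(trace10).n_runs == 1

    @given(
        st.lists(st.floats(0.1, 60), min_size=1, max_size=50),
        st.floats(0.5, 30),
    )
    def test_partition_and_gap_accounting(self, steps, threshold):
        """Runs partition the indices; excluded + within-run time = duration."""
        t = np.concatenate(([0.0], np.cumsum(steps)))
        trace = GlucoseTrace(timestamps=t, glucose=np.full(t.size, 100.0))
        report = detect_gaps(trace, threshold)
        covered = [i for a, b in report.runs for i in range(a, b)]
        assert covered == list(range(len(trace)))
        within = sum(
            trace.timestamps[b - 1] - trace.timestamps[a] for a, b in report.runs
        )
        assert within + report.excluded_minutes == pytest.approx(
            trace.duration_minutes
        )


class TestResample:
    def test_identity_factor_one(self, wave_12h):
        assert resample(wave_12h, 1) is wave_12h

    def test_decimation_count_and_interval(self, wave_12h):
        out = resample(wave_12h, 2)
        assert len(out) == 1008
        assert out.nominal_interval == 10
        np.testing.assert_allclose(np.diff(out.timestamps), 10.0)

    def test_invalid_factor(self, wave_12h):
        with pytest.raises(ValidationError):
            resample(wave_12h, 0)

    def test_too_short_trace(self):
        trace = GlucoseTrace([0, 5], [100, 110])
        with pytest.raises(InsufficientDataError):
            resample(trace, 2)


class TestTraceValidation:
    @pytest.mark.parametrize(
        "timestamps, glucose, exc",
        [
            ([0, 5, 5], [100, 100, 100], ValidationError),   # duplicate time
            ([0, 5, 3], [100, 100, 100], ValidationError),   # decreasing
            ([0, 5], [100, -1], ValidationError),            # non-positive glucose
            ([0, 5], [100, np.nan], ValidationError),        # non-finite
            ([0], [100], InsufficientDataError),             # too short
        ],
    )
    def test_invariants_rejected(self, timestamps, glucose, exc):
        with pytest.raises(exc):
            GlucoseTrace(timestamps=timestamps, glucose=glucose)
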