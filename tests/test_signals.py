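"""Core signal container, delimited I/O and filtering primitives."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scigait import (DataError, ParameterError, SchemaError, SignalChannel,
                     butterworth_lowpass, load_session, read_channels,
                     resample, savgol_filter, write_channels)


def make_channel(samples, rate=1000.0, units="deg/s^2", axis="dorso_ventral"):
    return SignalChannel(np.asarray(samples, dtype=float), rate=rate,
                         units=units, axis=axis)


class TestSignalChannel:
    def test_duration_reproducible_from_fields(self):
        ch = make_channel(np.zeros(2001), rate=1000.0)
        assert ch.duration == pytest.approx(2.0)
        assert ch.times()[-1] == pytest.approx(ch.start_time + ch.duration)

    @pytest.mark.parametrize("kwargs", [
        {"samples": [], "rate": 100.0},
        {"samples": [1.0], "rate": 0.0},
        {"samples": [1.0], "rate": -5.0},
        {"samples": [1.0], "rate": 100.0, "units": "furlongs"},
    ])
    def test_invalid_construction(self, kwargs):
        with pytest.raises(ParameterError):
            SignalChannel(**{"units": "deg", **kwargs})


class TestDelimitedIO:
    def test_rate_inferred_from_time_steps(self, tmp_path):
        p = tmp_path / "imu.csv"
        t = np.arange(100) * 0.0005
        with open(p, "w") as fh:
            fh.write("time_s,gx,gy\n")
            for ti, a, b in zip(t, np.sin(t), np.cos(t)):
                fh.write(f"{ti:.6f},{a:.6f},{b:.6f}\n")
        chans = read_channels(p, {"x": "gx", "y": "gy"})
        assert set(chans) == {"x", "y"}
        assert chans["x"].rate == pytest.approx(2000.0, rel=1e-6)

    def test_single_row_cannot_infer_rate(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("time_s,gx\n0.0,1.0\n")
        with pytest.raises(DataError, match="single row"):
            read_channels(p, {"x": "gx"})

    def test_duplicated_time_stamp_is_data_error(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("time_s,gx\n0.0,1.0\n0.001,2.0\n0.001,3.0\n0.002,4.0\n")
        with pytest.raises(DataError, match="not strictly increasing"):
            read_channels(p, {"x": "gx"})

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,gx\n0.0,1.0\n0.001,2.0\n")
        with pytest.raises(SchemaError, match="gz"):
            read_channels(p, {"z": "gz"})

    def test_gap_in_recording_rejected(self, tmp_path):
        p = tmp_path / "gap.csv"
        t = list(np.arange(50) * 0.001) + list(1.0 + np.arange(50) * 0.001)
        with open(p, "w") as fh:
            fh.write("time_s,gx\n")
            for ti in t:
                fh.write(f"{ti:.6f},0.0\n")
        with pytest.raises(DataError, match="non-uniform"):
            read_channels(p, {"x": "gx"})

    def test_writer_round_trips(self, tmp_path):
        rng = np.random.default_rng(0)
        ch = make_channel(rng.normal(size=256), rate=1000.0)
        p = tmp_path / "rt.csv"
        write_channels(p, {"dv": ch})
        back = read_channels(p, {"dv": "dv"})["dv"]
        assert back.rate == pytest.approx(1000.0)
        np.testing.assert_allclose(back.samples, ch.samples, atol=1e-6)

    def test_load_session_tab_delimited(self, tmp_path):
        t = np.arange(200) * 0.0005
        p = tmp_path / "imu.tsv"
        with open(p, "w") as fh:
            fh.write("time_s\tml\tcc\tdv\n")
            for ti in t:
                fh.write(f"{ti:.6f}\t0.1\t0.2\t0.3\n")
        rec = load_session({"thoracic": p}, animal_id="A", group="DAMAGED",
                           session="Baseline")
        assert rec.thoracic.rate == pytest.approx(2000.0)
        assert rec.lumbar is None


class TestResample:
    def test_constant_invariant(self):
        ch = make_channel(np.full(2000, 3.7), rate=2000.0)
        out = resample(ch, 1000.0)
        assert out.rate == 1000.0
        np.testing.assert_allclose(out.samples, 3.7, rtol=1e-6)

    def test_sinusoid_matches_analytic_on_new_grid(self):
        t = np.arange(4000) / 2000.0
        ch = make_channel(np.sin(2 * np.pi * 1.0 * t), rate=2000.0)
        out = resample(ch, 1000.0)
        expected = np.sin(2 * np.pi * 1.0 * out.times())
        # interior comparison: polyphase edges are less accurate
        sl = slice(50, -50)
        assert np.max(np.abs(out.samples[sl] - expected[sl])) < 0.01

    def test_identity_when_rates_match(self):
        ch = make_channel(np.arange(10.0), rate=500.0)
        assert resample(ch, 500.0) is ch

    def test_round_trip_band_limited_within_1pct_rms(self, rng):
        # sum of tones below 100 Hz at 2 kHz
        t = np.arange(8000) / 2000.0
        x = sum(np.sin(2 * np.pi * f * t + p)
                for f, p in zip([3.0, 17.0, 55.0, 90.0], rng.uniform(0, 6, 4)))
        ch = make_channel(x, rate=2000.0)
        back = resample(resample(ch, 1000.0), 2000.0)
        sl = slice(200, -200)
        rms_err = np.sqrt(np.mean((back.samples[sl] - x[sl]) ** 2))
        rms = np.sqrt(np.mean(x[sl] ** 2))
        assert rms_err / rms < 0.01

    def test_units_and_axis_preserved(self):
        ch = make_channel(np.zeros(100), rate=2000.0, units="deg", axis="flexion")
        out = resample(ch, 1000.0)
        assert (out.units, out.axis) == ("deg", "flexion")

    def test_invalid_target_rate(self):
        with pytest.raises(ParameterError):
            resample(make_channel(np.zeros(10)), -1.0)


class TestSavitzkyGolay:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(coeffs=st.lists(st.floats(-5, 5), min_size=4, max_size=4))
    def test_preserves_cubics_on_interior(self, coeffs):
        t = np.linspace(0, 1, 400)
        x = np.polyval(coeffs, t)
        out = savgol_filter(make_channel(x, rate=1000.0))
        w = 51  # 0.051 s at 1 kHz
        interior = slice(w, -w)
        np.testing.assert_allclose(out.samples[interior], x[interior], atol=1e-9)

    def test_constant_unchanged(self):
        out = savgol_filter(make_channel(np.full(500, 2.5), rate=1000.0))
        np.testing.assert_allclose(out.samples, 2.5, atol=1e-12)

    def test_window_forced_odd_at_2khz(self):
        # 0.051 s at 2 kHz is 102 samples; the filter must still run (window
        # bumped to 103) and smooth noise.
        rng = np.random.default_rng(7)
        x = rng.normal(size=20_000)
        out = savgol_filter(make_channel(x, rate=2000.0))
        assert out.samples.var() < x.var()

    def test_noise_variance_reduced(self, rng):
        x = rng.normal(size=20_000)
        out = savgol_filter(make_channel(x, rate=1000.0))
        assert out.samples.var() < 0.5 * x.var()

    def test_window_not_larger_than_poly_order(self):
        with pytest.raises(ParameterError):
            savgol_filter(make_channel(np.zeros(100), rate=50.0),
                          poly_order=3, frame_seconds=0.051)  # window 3


class TestButterworth:
    def test_dc_gain_one(self):
        out = butterworth_lowpass(make_channel(np.full(2000, -4.2), rate=1000.0))
        np.testing.assert_allclose(out.samples, -4.2, atol=1e-9)

    def test_passband_2hz_attenuation_below_1pct(self):
        t = np.arange(10_000) / 1000.0
        out = butterworth_lowpass(make_channel(np.sin(2 * np.pi * 2 * t), rate=1000.0))
        amp = np.max(np.abs(out.samples[2000:-2000]))
        assert abs(amp - 1.0) < 0.01

    def test_stopband_100hz_attenuation_above_99pct(self):
        t = np.arange(10_000) / 1000.0
        out = butterworth_lowpass(make_channel(np.sin(2 * np.pi * 100 * t), rate=1000.0))
        assert np.max(np.abs(out.samples[2000:-2000])) < 0.01

    def test_zero_phase_gaussian_bump_peak_unmoved(self):
        t = np.arange(8000) / 1000.0
        x = np.exp(-0.5 * ((t - 4.0) / 0.5) ** 2)
        out = butterworth_lowpass(make_channel(x, rate=1000.0))
        assert abs(int(np.argmax(out.samples)) - int(np.argmax(x))) <= 1

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            butterworth_lowpass(make_channel(np.zeros(100), rate=1000.0),
                                cutoff_hz=500.0)
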