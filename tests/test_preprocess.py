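import numpy as np
import pytest
from scipy import signal as sps

from cyclopred import (
    BreathingSignal,
    FilterSpec,
    crop_signal,
    lowpass,
    read_signal,
    resample_uniform,
    write_signal,
)
from cyclopred.errors import InvalidFilter, InvalidSignal, ParseError
from cyclopred.preprocess import butter_sos

RATE = 20.0


class TestReadSignal:
    def test_reads_two_column_csv(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("time_s,pos_mm\n0.0,1.0\n0.05,1.5\n")
        sig = read_signal(p)
        assert len(sig) == 2
        np.testing.assert_allclose(sig.y, [1.0, 1.5])
        assert sig.rate_hz is None
        assert sig.meta["source"] == str(p)

    def test_duplicate_timestamp_rejected(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("time_s,pos_mm\n0.0,1.0\n0.05,1.5\n0.05,1.6\n")
        with pytest.raises(InvalidSignal):
            read_signal(p)

    def test_empty_data_section(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("time_s,pos_mm\n")
        with pytest.raises(ParseError):
            read_signal(p)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("time_s,pos_mm\n0.0,1.0\n0.05,oops\n")
        with pytest.raises(ParseError, match="line 3"):
            read_signal(p)

    def test_roundtrip_with_write(self, tmp_path):
        t = np.arange(10) / RATE
        y = np.sin(t)
        p = tmp_path / "rt.csv"
        write_signal(BreathingSignal(t=t, y=y), p)
        back = read_signal(p)
        np.testing.assert_allclose(back.y, y, atol=1e-12)


class TestResample:
    def test_linear_ramp_is_interpolation_invariant(self):
        sig = BreathingSignal(t=[0, 0.08, 0.14], y=[0, 0.8, 1.4])
        out = resample_uniform(sig, rate_hz=RATE)
        np.testing.assert_allclose(out.t, [0, 0.05, 0.10], atol=1e-12)
        np.testing.assert_allclose(out.y, [0, 0.5, 1.0], atol=1e-12)
        assert out.rate_hz == RATE

    def test_uniform_input_unchanged(self):
        t = np.arange(100) / RATE
        y = np.sin(2 * np.pi * 0.25 * t)
        out = resample_uniform(BreathingSignal(t=t, y=y), rate_hz=RATE)
        np.testing.assert_allclose(out.y, y, atol=1e-12)

    def test_jittered_sinusoid_recovered(self):
        # Catalyst-like irregular ~13.3 Hz sampling of a 0.25 Hz sinusoid
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.uniform(0.06, 0.09, size=800))
        y = 5 * np.sin(2 * np.pi * 0.25 * t)
        out = resample_uniform(BreathingSignal(t=t, y=y), rate_hz=RATE)
        truth = 5 * np.sin(2 * np.pi * 0.25 * out.t)
        assert np.max(np.abs(out.y - truth)) < 0.02

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 30, size=300))
        sig = BreathingSignal(t=t, y=rng.standard_normal(300))
        once = resample_uniform(sig, rate_hz=RATE)
        twice = resample_uniform(once, rate_hz=RATE)
        np.testing.assert_allclose(once.y, twice.y, atol=1e-12)

    def test_too_short(self):
        with pytest.raises(InvalidSignal):
            resample_uniform(BreathingSignal(t=[0.0], y=[1.0]))


class TestCrop:
    def _trace(self, dur=240.0):
        t = np.arange(int(dur * RATE) + 1) / RATE
        return BreathingSignal(t=t, y=np.sin(t), rate_hz=RATE)

    def test_sample_count_on_uniform_grid(self):
        out = crop_signal(self._trace(), 0.0, 60.0)
        assert len(out) == 1201

    def test_whole_span_identity(self):
        sig = self._trace()
        out = crop_signal(sig, sig.t[0], sig.t[-1])
        np.testing.assert_allclose(out.y, sig.y)

    def test_no_overlap(self):
        with pytest.raises(InvalidSignal):
            crop_signal(self._trace(10.0), 100.0, 200.0)


class TestLowpass:
    def _sig(self, y):
        t = np.arange(len(y)) / RATE
        return BreathingSignal(t=t, y=y, rate_hz=RATE)

    def test_dc_gain_unity(self):
        out = lowpass(self._sig(np.full(600, 5.0)))
        np.testing.assert_allclose(out.y, 5.0, atol=1e-9)

    def test_passband_amplitude_preserved(self):
        # designed magnitude response at 0.25 Hz is the oracle
        t = np.arange(4000) / RATE
        y = 5 * np.sin(2 * np.pi * 0.25 * t)
        out = lowpass(self._sig(y))
        sos = butter_sos(FilterSpec(), RATE)
        _, h = sps.sosfreqz(sos, worN=[0.25], fs=RATE)
        expected = 5 * np.abs(h[0]) ** 2        # forward-backward: |H|^2
        mid = slice(500, 3500)
        amp = np.max(np.abs(out.y[mid]))
        assert abs(amp - 5) / 5 < 0.01
        assert abs(amp - expected) / expected < 0.01

    def test_stopband_attenuation(self):
        t = np.arange(4000) / RATE
        y = np.sin(2 * np.pi * 5.0 * t)
        out = lowpass(self._sig(y))
        assert np.max(np.abs(out.y[500:3500])) < 0.01

    def test_zero_phase_no_lag(self):
        t = np.arange(2000) / RATE
        y = np.sin(2 * np.pi * 0.3 * t)
        out = lowpass(self._sig(y))
        xc = np.correlate(out.y[200:-200] - out.y[200:-200].mean(),
                          y[200:-200] - y[200:-200].mean(), mode="full")
        lag = int(np.argmax(xc)) - (len(y[200:-200]) - 1)
        assert lag == 0

    def test_causal_mode_lags(self):
        t = np.arange(2000) / RATE
        y = np.sin(2 * np.pi * 0.3 * t)
        out = lowpass(self._sig(y), FilterSpec(mode="causal"))
        xc = np.correlate(out.y[500:] - out.y[500:].mean(),
                          y[500:] - y[500:].mean(), mode="full")
        lag = int(np.argmax(xc)) - (len(y[500:]) - 1)
        assert lag > 0

    def test_cutoff_above_nyquist(self):
        with pytest.raises(InvalidFilter):
            lowpass(self._sig(np.zeros(100)), FilterSpec(cutoff_hz=11.0))
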