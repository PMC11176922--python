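import numpy as np
import pytest

from cyclopred import (
    BreathingSignal,
    SyntheticConfig,
    build_envelopes,
    decompose,
    detect_peaks,
    generate_trace,
    lowpass,
    reassemble,
)
from cyclopred.errors import InvalidComponents, NoPeaksDetected

RATE = 20.0


def _sig(y):
    t = np.arange(len(y)) / RATE
    return BreathingSignal(t=t, y=np.asarray(y, dtype=float), rate_hz=RATE)


class TestDetectPeaks:
    def test_cosine_anchor_times(self):
        t = np.arange(int(12 * RATE) + 1) / RATE
        sig = _sig(5 + 5 * np.cos(2 * np.pi * t / 4))
        pk = detect_peaks(sig)
        upper_t = t[pk.upper_idx]
        lower_t = t[pk.lower_idx]
        assert {4.0, 8.0} <= set(np.round(upper_t, 6))
        assert {2.0, 6.0, 10.0} <= set(np.round(lower_t, 6))
        assert pk.mean_amplitude_mm == pytest.approx(10.0, abs=1e-9)

    def test_constant_signal(self):
        with pytest.raises(NoPeaksDetected):
            detect_peaks(_sig(np.full(400, 3.0)))

    def test_ripple_rejected_by_threshold(self):
        # 10 mm peak-to-trough carrier + 2 mm-prominence ripple; the 55 %
        # rule must drop every ripple extremum.  Oracle: a brute-force scan
        # for carrier extrema at the analytic times.
        t = np.arange(int(60 * RATE) + 1) / RATE
        y = 5 * np.cos(2 * np.pi * 0.25 * t) + 1.0 * np.cos(2 * np.pi * 0.9 * t)
        sig = _sig(y)
        pk = detect_peaks(sig)
        # exactly one anchor per carrier half-cycle (no ripple doubles) ...
        assert 13 <= len(pk.upper_idx) <= 15
        assert 13 <= len(pk.lower_idx) <= 15
        assert np.all(np.diff(t[pk.upper_idx]) > 3.0)
        assert np.all(np.diff(t[pk.lower_idx]) > 3.0)
        # ... each within half a ripple period of the carrier extremum (the
        # ripple legitimately shifts the composite's true extremum)
        for i in pk.upper_idx:
            assert np.min(np.abs(t[i] - np.arange(0, 60.01, 4.0))) < 0.6
        for i in pk.lower_idx:
            assert np.min(np.abs(t[i] - np.arange(2, 60.01, 4.0))) < 0.6
        # converged mean amplitude reflects the carrier, not the ripple
        assert 9.0 < pk.mean_amplitude_mm < 12.5

    def test_anchors_alternate(self):
        sig, _ = generate_trace(SyntheticConfig(duration_s=120, seed=3))
        pk = detect_peaks(lowpass(sig))
        idx, kind = pk.merged()
        assert np.all(kind[:-1] != kind[1:])


class TestEnvelopes:
    def test_constant_envelopes_for_pure_cosine(self, cosine_signal):
        pk = detect_peaks(cosine_signal)
        upper, lower, mid = build_envelopes(cosine_signal, pk)
        v = np.isfinite(mid)
        np.testing.assert_allclose(upper[v], 10.0, atol=1e-9)
        np.testing.assert_allclose(lower[v], 0.0, atol=1e-9)
        np.testing.assert_allclose(mid[v], 5.0, atol=1e-9)

    def test_midline_is_mean_of_envelopes(self, modulated_trace):
        sig, _ = modulated_trace
        pk = detect_peaks(sig)
        upper, lower, mid = build_envelopes(sig, pk)
        v = np.isfinite(mid)
        np.testing.assert_allclose(mid[v], (upper[v] + lower[v]) / 2, atol=1e-12)

    def test_linear_between_upper_anchors(self):
        # two upper anchors with values 8 and 12: envelope is the chord
        t = np.arange(int(8 * RATE) + 1) / RATE
        amp = np.where(t < 4, 8.0, 12.0)  # second cycle taller
        y = amp / 2 * (1 + np.cos(2 * np.pi * t / 4)) - amp / 2
        sig = _sig(y + 4.0)
        pk = detect_peaks(sig)
        upper, _, _ = build_envelopes(sig, pk)
        ups = pk.upper_idx
        i0, i1 = ups[0], ups[-1]
        chord = np.interp(np.arange(i0, i1 + 1), [i0, i1],
                          [sig.y[i0], sig.y[i1]])
        np.testing.assert_allclose(upper[i0:i1 + 1], chord, atol=1e-9)


class TestDecompose:
    def test_closed_form_cosine(self, cosine_signal):
        dec = decompose(cosine_signal, detect_peaks(cosine_signal))
        v = dec.valid_mask
        np.testing.assert_allclose(dec.deflection_mm[v], 5.0, atol=1e-6)
        np.testing.assert_allclose(dec.baseline_mm[v], 0.0, atol=1e-6)
        slope = np.polyfit(cosine_signal.t[v], dec.phase_unwrapped_deg[v], 1)[0]
        assert slope == pytest.approx(90.0, rel=1e-3)

    def test_phase_at_anchors(self, cosine_signal):
        dec = decompose(cosine_signal, detect_peaks(cosine_signal))
        pk = dec.peaks
        v = dec.valid_mask
        for i in pk.upper_idx:
            if v[i]:
                assert dec.phase_deg[i] % 360 == pytest.approx(0.0, abs=1e-9)
                # y = 2d + BL exactly at the upper anchor
                assert cosine_signal.y[i] == pytest.approx(
                    2 * dec.deflection_mm[i] + dec.baseline_mm[i], abs=1e-9)
        for i in pk.lower_idx:
            if v[i]:
                assert dec.phase_deg[i] == pytest.approx(180.0, abs=1e-9)

    def test_roundtrip_on_modulated_trace(self, modulated_trace):
        sig, _ = modulated_trace
        filt = lowpass(sig)
        dec = decompose(filt, detect_peaks(filt))
        ok = dec.valid_mask & ~dec.clamp_mask
        err = np.abs(dec.reassembled()[ok] - filt.y[ok])
        assert err.max() < 1e-9

    def test_unwrapped_phase_monotone(self, modulated_trace):
        sig, _ = modulated_trace
        dec = decompose(sig, detect_peaks(sig))
        v = dec.valid_mask
        assert np.all(np.diff(dec.phase_unwrapped_deg[v]) >= -1e-9)

    def test_clamp_fraction_small_for_clean_trace(self, clean_constant_trace):
        sig, _ = clean_constant_trace
        filt = lowpass(sig)
        dec = decompose(filt, detect_peaks(filt))
        assert dec.clamp_mask[dec.valid_mask].mean() < 0.01


class TestReassemble:
    @pytest.mark.parametrize("phi,d,bl,expected", [
        (0.0, 3.0, 1.0, 7.0),
        (180.0, 3.0, 1.0, 1.0),
        (90.0, 2.5, -0.5, 2.0),
    ])
    def test_pointwise(self, phi, d, bl, expected):
        assert reassemble(phi, d, bl) == pytest.approx(expected, abs=1e-12)

    def test_negative_deflection_rejected(self):
        with pytest.raises(InvalidComponents):
            reassemble(0.0, -1.0, 0.0)
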