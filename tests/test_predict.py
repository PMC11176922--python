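import numpy as np
import pytest

from cyclopred import (
    BreathingSignal,
    CyclicLSTM,
    NO_PREDICTION,
    PredictorConfig,
    SyntheticConfig,
    TrainedPredictor,
    decompose,
    detect_peaks,
    generate_trace,
    lowpass,
    make_samples,
    persistence_baseline,
    rmse,
    split_train_val,
)
from cyclopred.errors import InvalidConfig, InvalidSplit, RateMismatch, ShapeError

RATE = 20.0


def _decomposed_trace(duration=120.0, seed=0, noise=0.0):
    cfg = SyntheticConfig(duration_s=duration, seed=seed, noise_sd_mm=noise)
    sig, _ = generate_trace(cfg)
    filt = lowpass(sig)
    dec = decompose(filt, detect_peaks(filt))
    return sig, filt, dec


@pytest.fixture(scope="module")
def small_fitted():
    """One cheap fitted predictor per output mode, shared across tests."""
    sig, filt, dec = _decomposed_trace(duration=150.0, seed=5)
    fitted = {}
    for mode in ("signal", "components"):
        cfg = PredictorConfig(window_samples=40, horizon_samples=10,
                              lstm_units=(10, 10, 10), learning_rate=0.01,
                              batch_size=128, epochs=20, seed=1,
                              output_mode=mode, stride=2)
        samples = make_samples(filt, dec, cfg, raw=sig)
        fitted[mode] = CyclicLSTM(cfg).fit(samples)
    return sig, filt, dec, fitted


class TestConfig:
    def test_window_grid_in_seconds(self):
        for w, sec in zip((20, 40, 80, 160, 240, 320), (1, 2, 4, 8, 12, 16)):
            cfg = PredictorConfig(window_samples=w)
            assert cfg.window_samples / cfg.rate_hz == sec

    def test_horizon_is_500ms_by_default(self):
        assert PredictorConfig().horizon_s == pytest.approx(0.5)

    @pytest.mark.parametrize("kw", [
        {"window_samples": 1}, {"horizon_samples": 0},
        {"output_mode": "both"}, {"lstm_units": (10, 10)},
        {"epochs": 0}, {"learning_rate": 0.0},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(InvalidConfig):
            PredictorConfig(**kw)


class TestMakeSamples:
    def test_sample_count_matches_window_arithmetic(self):
        sig, filt, dec = _decomposed_trace(duration=120.0, seed=2)
        cfg = PredictorConfig(window_samples=160, horizon_samples=10, stride=1)
        samples = make_samples(filt, dec, cfg, raw=sig)
        n_valid = int(dec.valid_mask.sum())
        first, last = np.flatnonzero(dec.valid_mask)[[0, -1]]
        expected = (last - first + 1) - 160 - 10 + 1 - samples.n_skipped_degenerate
        assert len(samples) == expected

    def test_short_trace_yields_empty(self):
        sig, filt, dec = _decomposed_trace(duration=15.0, seed=2)
        cfg = PredictorConfig(window_samples=320, horizon_samples=10)
        assert len(make_samples(filt, dec, cfg, raw=sig)) == 0

    def test_target_alignment(self):
        sig, filt, dec = _decomposed_trace(duration=60.0, seed=2)
        cfg = PredictorConfig(window_samples=80, horizon_samples=10, stride=3)
        s = make_samples(filt, dec, cfg, raw=sig)
        # target index - last input index == horizon for every sample
        starts = s.target_idx - 80 + 1 - 10
        assert np.all(s.target_idx - (starts + 80 - 1) == 10)
        np.testing.assert_allclose(s.y_true_mm, filt.y[s.target_idx])

    def test_scaled_inputs_bounded(self):
        sig, filt, dec = _decomposed_trace(duration=60.0, seed=4)
        cfg = PredictorConfig(window_samples=80, horizon_samples=10, stride=5)
        s = make_samples(filt, dec, cfg, raw=sig)
        assert np.all(np.abs(s.X) <= 1.0 + 1e-5)


class TestSplit:
    def _datasets(self, n, subjects=None):
        out = []
        for k in range(n):
            t = np.arange(50) / RATE
            subj = subjects[k] if subjects else f"S{k}"
            out.append(BreathingSignal(t=t, y=np.sin(t), rate_hz=RATE,
                                       meta={"subject": subj}))
        return out

    def test_70_datasets_split_56_14(self):
        ds = self._datasets(70)
        tr, va = split_train_val(ds, seed=0)
        assert (len(tr), len(va)) == (56, 14)

    def test_5_single_subject_datasets(self):
        tr, va = split_train_val(self._datasets(5), seed=0)
        assert (len(tr), len(va)) == (4, 1)

    def test_deterministic_under_seed(self):
        ds = self._datasets(12)
        a = split_train_val(ds, seed=7)
        b = split_train_val(ds, seed=7)
        assert [id(x) for x in a[1]] == [id(x) for x in b[1]]

    def test_subjects_not_straddling(self):
        subjects = [f"P{k // 2}" for k in range(20)]  # 2 traces per subject
        ds = self._datasets(20, subjects)
        tr, va = split_train_val(ds, seed=1)
        tr_subj = {d.meta["subject"] for d in tr}
        va_subj = {d.meta["subject"] for d in va}
        assert not (tr_subj & va_subj)

    def test_too_few_datasets(self):
        with pytest.raises(InvalidSplit):
            split_train_val(self._datasets(4), seed=0)


class TestPrediction:
    def test_window_length_checked(self, small_fitted):
        *_, fitted = small_fitted
        with pytest.raises(ShapeError):
            fitted["signal"].predict_window(np.zeros(39))

    def test_flat_window_no_prediction(self, small_fitted):
        *_, fitted = small_fitted
        assert fitted["signal"].predict_window(np.full(40, 2.0)) is NO_PREDICTION

    def test_components_obey_reassembly(self, small_fitted):
        sig, filt, dec, fitted = small_fitted
        y_hat, comps = fitted["components"].predict_window(filt.y[200:240])
        d, bl = comps["deflection_mm"], comps["baseline_mm"]
        phi = np.radians(comps["phase_deg"])
        assert y_hat == pytest.approx(d + d * np.cos(phi) + bl, abs=1e-9)
        assert d >= 0

    def test_stream_alignment_and_gap(self, small_fitted):
        sig, filt, dec, fitted = small_fitted
        trace = fitted["signal"].predict_stream(sig)
        W, h = 40, 10
        assert len(trace.y_pred) == len(sig)
        assert np.all(np.isnan(trace.y_pred[: W + h - 1]))
        assert np.isfinite(trace.y_pred[W + h - 1])
        # first prediction targets t = (W - 1 + h) / rate
        assert sig.t[W + h - 1] == pytest.approx((W - 1 + h) / RATE)

    def test_stream_rate_mismatch(self, small_fitted):
        *_, fitted = small_fitted
        t = np.arange(100) / 10.0
        with pytest.raises(RateMismatch):
            fitted["signal"].predict_stream(
                BreathingSignal(t=t, y=np.sin(t), rate_hz=10.0))

    def test_both_models_beat_persistence(self, small_fitted):
        sig, filt, dec, fitted = small_fitted
        pers = persistence_baseline(sig, fitted["signal"].config)
        mask = np.isfinite(pers.y_pred)
        pers_rmse = rmse(pers.y_pred[mask], filt.y[mask])
        for mode in ("signal", "components"):
            trace = fitted[mode].predict_stream(sig)
            m = np.isfinite(trace.y_pred)
            assert rmse(trace.y_pred[m], filt.y[m]) < pers_rmse

    def test_save_load_bit_exact(self, small_fitted, tmp_path):
        sig, filt, dec, fitted = small_fitted
        p = tmp_path / "model.npz"
        fitted["components"].save(p)
        back = TrainedPredictor.load(p)
        w = filt.y[500:540]
        assert back.predict_window(w)[0] == fitted["components"].predict_window(w)[0]
        assert back.config == fitted["components"].config
        assert back.history == fitted["components"].history


class TestPersistenceBaseline:
    def test_emits_last_observed_value(self):
        t = np.arange(100) / RATE
        sig = BreathingSignal(t=t, y=np.arange(100.0), rate_hz=RATE)
        cfg = PredictorConfig(window_samples=20, horizon_samples=10)
        trace = persistence_baseline(sig, cfg)
        assert np.all(np.isnan(trace.y_pred[:29]))
        np.testing.assert_allclose(trace.y_pred[29:], np.arange(19.0, 90.0))
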