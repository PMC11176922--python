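# cyclopred

Cyclic decomposition and recurrent prediction of respiratory surrogate
signals, for latency compensation in gated and tracked radiotherapy.

## The problem

Treating thoracic and abdominal tumours under free breathing requires the
delivery system to follow (tracking) or switch with (gating) the
respiratory motion. Every link in that chain — imaging, computation,
multi-leaf collimator mechanics — adds latency, up to ~500 ms in total.
If the breathing surrogate signal (here: the anterior–posterior
displacement of a chest or abdomen surface point, in mm, from an optical
surface scanner) can be predicted 500 ms ahead, the latency cancels.

`cyclopred` implements a prediction method whose core idea is to encode
the cyclic structure of breathing explicitly before learning. The
preprocessed signal y(t) is decomposed through a modulated cosine

    y(t) = d(t) + d(t)·cos φ(t) + BL(t)

into a baseline BL(t) (lower envelope through the expiration extrema), a
deflection d(t) (half the peak-to-trough breathing amplitude, from the
upper and lower envelopes), and a cycle phase φ(t) (0° at one extremum
class, 180° at the other, 360° per breath, recovered exactly by arccos
inversion). Two LSTM predictors share one architecture (three stacked
layers + dense head) and a 500 ms horizon:

* **Model 1 (signal mode)** — dynamically scaled signal window → scaled
  signal value at the horizon (one output channel);
* **Model 2 (components mode)** — the same window → the three component
  channels at the horizon, decoded and reassembled through the equation
  above into a millimetre prediction.

Each input window is affinely scaled so its extremes map to ±1; the
scaling commutes with the model equation, so training in scaled space and
predicting in mm is exact. Since the environment provides no deep-learning
framework, the stacked-LSTM regressor (BPTT, Adam, seeded, float32) is
implemented in NumPy inside the package and verified against numerical
gradients.

Because no surrogate recordings are distributed, the package ships a
synthetic generator (`cyclopred.synth`) that emulates the cohort
statistics of sternum (~2.4 mm mean amplitude) and abdomen (~10.7 mm)
surrogate sites, with autocorrelated breath-to-breath variation, slow
amplitude/baseline drift, an end-exhale dwell shape and scanner noise —
with exact ground-truth components for every trace.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

```python
import numpy as np
from cyclopred import (SyntheticConfig, generate_trace, lowpass, detect_peaks,
                       decompose, PredictorConfig, make_samples, CyclicLSTM,
                       persistence_baseline, rmse)

cfg = SyntheticConfig(duration_s=150.0, seed=42)      # abdomen-like defaults
sig, truth = generate_trace(cfg)
filt = lowpass(sig)                                   # order-8 Butterworth, 1 Hz
peaks = detect_peaks(filt)                            # 55 % prominence rule
dec = decompose(filt, peaks)

ok = dec.valid_mask & ~dec.clamp_mask
print(f"cycles detected      : {len(peaks.upper_idx)}")
print(f"mean amplitude       : {peaks.mean_amplitude_mm:.2f} mm")
print(f"round-trip max error : {np.abs(dec.reassembled()[ok] - filt.y[ok]).max():.2e} mm")

pcfg = PredictorConfig(window_samples=160, horizon_samples=10,
                       lstm_units=(20, 20, 20), learning_rate=0.01,
                       batch_size=256, epochs=60, seed=0,
                       output_mode="components", stride=4)
samples = make_samples(filt, dec, pcfg, raw=sig)
result = CyclicLSTM(pcfg).fit(samples)
print(result.summary())

stream = result.predict_stream(sig)                   # causal, 500 ms ahead
m = np.isfinite(stream.y_pred)
pers = persistence_baseline(sig, pcfg)
print(f"streaming RMSE       : {rmse(stream.y_pred[m], filt.y[m]):.3f} mm")
print(f"persistence RMSE     : {rmse(pers.y_pred[m], filt.y[m]):.3f} mm")
```

Output:

```
cycles detected      : 37
mean amplitude       : 11.00 mm
round-trip max error : 9.77e-14 mm
CyclicLSTM predictor
====================================================
output mode     : components (3 channels)
input window    : 160 samples (8.0 s at 20 Hz)
horizon         : 10 samples (500 ms)
LSTM units      : [20, 20, 20]
parameters      : 8383
learning rate   : 0.01  batch 256  epochs 60  seed 0
final train loss: 1.100e-02
streaming RMSE       : 1.923 mm
persistence RMSE     : 3.009 mm
```

The decomposition reproduces the filtered signal to machine precision on
valid, unclamped samples (the arccos inversion is exact by construction);
the 37 detected cycles average 11 mm peak-to-trough; and after a short
in-sample training run the causal 500 ms-ahead prediction substantially undercuts the persistence baseline (repeating the last observed
value). `result.plot_history()` and `stream.plot(truth=filt)` draw the
loss curves and the prediction overlay.

The same pipeline is scriptable from the shell:

```bash
cyclopred simulate --out cohort/ --subjects 6 --seed 1
cyclopred preprocess --in cohort/S000_abdomen_000.csv --out pre.csv
cyclopred decompose  --in pre.csv --out dec.csv
cyclopred train --config cfg.yaml --data cohort/ --out model.npz
cyclopred predict --model model.npz --in pre.csv --out pred.csv
cyclopred evaluate --pred pred.csv --truth dec.csv --out report.json
```

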