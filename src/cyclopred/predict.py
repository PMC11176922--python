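"""Recurrent breathing-motion predictors.

Two predictor variants share one architecture (stacked LSTM layers and a
dense head) and one 500 ms prediction horizon:

* **signal mode** ("Model 1"): the dynamically scaled signal window is
  mapped to the scaled signal value one horizon ahead;
* **components mode** ("Model 2"): the same input window is mapped to the
  three cyclic-decomposition channels (phase, deflection, baseline) one
  horizon ahead, which are decoded and reassembled through the
  modulated-cosine model into a millimetre prediction.

Explicitly encoding the cycle (components mode) is the substance of the
method: the three channels are individually smooth and close to periodic,
which makes them far easier to forecast from little training data than the
raw signal.

The user-facing objects follow the model/results convention:
``CyclicLSTM(config).fit(train, val)`` returns a :class:`TrainedPredictor`
carrying the weights, the loss history, ``summary()``, prediction methods
and persistence.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._network import Adam, LSTMRegressor
from .decompose import CyclicDecomposition, reassemble
from .errors import (
    InvalidConfig,
    InvalidSplit,
    NoTrainingData,
    RateMismatch,
    ShapeError,
)
from .preprocess import BreathingSignal, FilterSpec, butter_sos, filtfilt_window
from .scale import encode_phase

__all__ = [
    "PredictorConfig",
    "TrainingSamples",
    "PredictionTrace",
    "CyclicLSTM",
    "TrainedPredictor",
    "NO_PREDICTION",
    "make_samples",
    "split_train_val",
    "train",
    "persistence_baseline",
]

_WINDOW_GRID = (20, 40, 80, 160, 240, 320)      # 1..32 s at 20 Hz
_LR_GRID = (0.05, 0.01, 0.005, 0.001)
_UNIT_GRID = (40, 30, 20)


class _NoPrediction:
    """Sentinel returned when a window is degenerate (flat)."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NO_PREDICTION"


NO_PREDICTION = _NoPrediction()


@dataclass(frozen=True)
class PredictorConfig:
    """Architecture and training hyper-parameters.

    ``window_samples`` is the input window length (the hyper-parameter grid
    used for model selection is 20/40/80/160/240/320 samples, i.e. 1-32 s
    at 20 Hz); ``horizon_samples`` defaults to 10 samples = 500 ms.
    """

    window_samples: int = 160
    horizon_samples: int = 10
    lstm_units: tuple[int, int, int] = (20, 20, 20)
    learning_rate: float = 0.01
    batch_size: int = 512
    epochs: int = 300
    seed: int = 0
    output_mode: str = "signal"          # "signal" | "components"
    rate_hz: float = 20.0
    stride: int = 1
    filter_order: int = 8
    filter_cutoff_hz: float = 1.0
    filter_per_window: bool = True
    phase_encoding: str = "wrapped_linear"
    #: components mode: per-channel loss weights (phase, deflection,
    #: baseline); None = equal.  The signal error is dominated by the
    #: phase channel, so upweighting it can pay off.
    loss_weights: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.window_samples < 2:
            raise InvalidConfig("window_samples must be >= 2")
        if self.horizon_samples < 1:
            raise InvalidConfig("horizon_samples must be >= 1")
        if self.output_mode not in ("signal", "components"):
            raise InvalidConfig(f"unknown output_mode {self.output_mode!r}")
        if len(self.lstm_units) != 3 or any(u < 1 for u in self.lstm_units):
            raise InvalidConfig("lstm_units must be three positive counts")
        if min(self.batch_size, self.epochs, self.stride) < 1:
            raise InvalidConfig("batch_size, epochs and stride must be positive")
        if self.rate_hz <= 0 or self.learning_rate <= 0:
            raise InvalidConfig("rate_hz and learning_rate must be positive")
        if self.phase_encoding != "wrapped_linear":
            raise NotImplementedError(
                "only the wrapped_linear phase encoding is implemented")

    @property
    def n_outputs(self) -> int:
        return 1 if self.output_mode == "signal" else 3

    @property
    def horizon_s(self) -> float:
        return self.horizon_samples / self.rate_hz

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(order=self.filter_order,
                          cutoff_hz=self.filter_cutoff_hz, mode="zero_phase")


@dataclass
class TrainingSamples:
    """Sliding-window samples from one decomposed trace.

    ``X`` is (n, window, 1) scaled input, ``Y`` (n, 1) or (n, 3) scaled
    targets; ``y_min``/``y_half`` store each window's scaling so metrics
    can be converted back to millimetres.  ``target_idx`` indexes into the
    source trace; the target always sits ``horizon_samples`` after the last
    input sample.
    """

    X: np.ndarray
    Y: np.ndarray
    target_idx: np.ndarray
    y_min: np.ndarray
    y_half: np.ndarray
    y_true_mm: np.ndarray
    n_skipped_degenerate: int = 0
    source: str = ""

    def __len__(self) -> int:
        return len(self.X)


def _window_matrix(values: np.ndarray, cfg: PredictorConfig,
                   starts: np.ndarray) -> np.ndarray:
    wins = sliding_window_view(values, cfg.window_samples)[starts]
    if cfg.filter_per_window:
        sos = butter_sos(cfg.filter_spec(), cfg.rate_hz)
        wins = filtfilt_window(wins, sos)
    return np.asarray(wins, dtype=float)


def _scale_rows(wins: np.ndarray):
    """Per-row min/max scaling; returns (scaled, y_min, y_half, ok_mask)."""
    w_min = wins.min(axis=1)
    w_max = wins.max(axis=1)
    half = (w_max - w_min) / 2.0
    ok = half > 1e-12
    half_safe = np.where(ok, half, 1.0)
    scaled = (wins - w_min[:, None] - half_safe[:, None]) / half_safe[:, None]
    return scaled, w_min, half_safe, ok


def make_samples(sig: BreathingSignal, dec: CyclicDecomposition,
                 cfg: PredictorConfig,
                 raw: BreathingSignal | None = None) -> TrainingSamples:
    """Build sliding-window training samples from one decomposed trace.

    ``sig`` is the preprocessed (offline-filtered) trace the decomposition
    was computed from and supplies the targets; input windows are drawn
    from ``raw`` (the resampled, unfiltered trace) when given, else from
    ``sig``, and are zero-phase filtered per window when the config says so
    -- the same path inference uses.  Windows whose span or target leave
    the decomposition's valid region are dropped; flat (degenerate) windows
    are skipped and counted.
    """
    n = len(sig)
    W, h = cfg.window_samples, cfg.horizon_samples
    src = raw.y if raw is not None else sig.y
    if len(src) != n:
        raise ShapeError("raw and filtered traces differ in length")
    empty = TrainingSamples(
        X=np.zeros((0, W, 1), np.float32), Y=np.zeros((0, cfg.n_outputs), np.float32),
        target_idx=np.zeros(0, int), y_min=np.zeros(0), y_half=np.zeros(0),
        y_true_mm=np.zeros(0), source=str(sig.meta.get("source", "")))
    if n < W + h:
        return empty

    starts = np.arange(0, n - W - h + 1, cfg.stride)
    valid = dec.valid_mask
    if cfg.output_mode == "components":
        # clamped samples carry distorted phase labels; don't train on them
        valid = valid & ~dec.clamp_mask
    # window fully valid and target valid
    win_ok = dec.valid_mask
    ok_valid = np.array([win_ok[s:s + W].all() and valid[s + W - 1 + h]
                         for s in starts])
    starts = starts[ok_valid]
    if starts.size == 0:
        return empty
    wins = _window_matrix(src, cfg, starts)
    scaled, w_min, half, ok = _scale_rows(wins)
    n_skip = int((~ok).sum())
    starts, scaled, w_min, half = starts[ok], scaled[ok], w_min[ok], half[ok]
    ti = starts + W - 1 + h
    y_true = sig.y[ti]
    if cfg.output_mode == "signal":
        Y = ((y_true - w_min - half) / half)[:, None]
    else:
        phi_ch = encode_phase(dec.phase_deg[ti])
        d_ch = dec.deflection_mm[ti] / half
        bl_ch = (dec.baseline_mm[ti] - w_min - half) / half
        Y = np.stack([phi_ch, d_ch, bl_ch], axis=1)
    return TrainingSamples(
        X=scaled[:, :, None].astype(np.float32),
        Y=Y.astype(np.float32),
        target_idx=ti, y_min=w_min, y_half=half, y_true_mm=y_true,
        n_skipped_degenerate=n_skip, source=str(sig.meta.get("source", "")))


def split_train_val(datasets: Sequence, seed: int, val_frac: float = 0.2):
    """Split datasets 4:1 into train/validation at subject level.

    All traces of one subject land on the same side; the validation share
    is as close to ``val_frac`` of the dataset count as the grouping
    allows.  Deterministic under ``seed``.
    """
    if len(datasets) < 5:
        raise InvalidSplit("need at least 5 datasets for a 4:1 split")

    def subject_of(ds):
        meta = ds.meta if hasattr(ds, "meta") else ds[0].meta
        return str(meta.get("subject", id(ds)))

    subjects: dict[str, list] = {}
    for ds in datasets:
        subjects.setdefault(subject_of(ds), []).append(ds)
    names = sorted(subjects)
    rng = np.random.default_rng(seed)
    rng.shuffle(names)
    target = val_frac * len(datasets)
    val, n_val = [], 0
    for name in names:
        group = subjects[name]
        if abs(n_val + len(group) - target) < abs(n_val - target):
            val.extend(group)
            n_val += len(group)
    if not val:                      # grouping too coarse: put one subject in val
        val = subjects[names[0]]
    val_ids = {id(ds) for ds in val}
    train = [ds for ds in datasets if id(ds) not in val_ids]
    if not train:
        raise InvalidSplit("validation absorbed every dataset")
    return train, val


def _concat_samples(sets: Sequence[TrainingSamples]):
    sets = [s for s in sets if len(s)]
    if not sets:
        raise NoTrainingData("no training samples")
    X = np.concatenate([s.X for s in sets])
    Y = np.concatenate([s.Y for s in sets])
    return X, Y


@dataclass
class PredictionTrace:
    """Time-aligned streaming predictions for one trace.

    ``y_pred`` has the same length as the input with NaN in the leading
    gap (the first ``window + horizon - 1`` samples) and at degenerate
    windows.  In components mode the decoded channels are carried too.
    """

    t: np.ndarray
    y_pred: np.ndarray
    phase_pred_deg: np.ndarray | None = None
    deflection_pred_mm: np.ndarray | None = None
    baseline_pred_mm: np.ndarray | None = None

    def plot(self, truth: BreathingSignal | None = None, ax=None):
        """Plot predictions (and optionally the measured trace)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        if truth is not None:
            ax.plot(truth.t, truth.y, lw=1, label="measured")
        ax.plot(self.t, self.y_pred, "--", lw=1, label="predicted")
        ax.set_xlabel("time [s]")
        ax.set_ylabel("AP displacement [mm]")
        ax.legend(frameon=False)
        return ax


class TrainedPredictor:
    """Fit results: weights, history, and prediction entry points."""

    def __init__(self, config: PredictorConfig, network: LSTMRegressor,
                 history: dict[str, list[float]]):
        self.config = config
        self.network = network
        self.history = history

    # -- inference ---------------------------------------------------------

    def _forward_windows(self, wins_mm: np.ndarray):
        """Filter, scale and run a (n, window) matrix of mm windows.

        Returns (y_hat_mm, comps or None, ok_mask)."""
        cfg = self.config
        wins = np.asarray(wins_mm, dtype=float)
        if cfg.filter_per_window:
            sos = butter_sos(cfg.filter_spec(), cfg.rate_hz)
            wins = filtfilt_window(wins, sos)
        scaled, w_min, half, ok = _scale_rows(wins)
        out = np.empty((len(wins), cfg.n_outputs), dtype=float)
        for lo in range(0, len(wins), 4096):
            out[lo:lo + 4096] = self.network.forward(
                scaled[lo:lo + 4096, :, None])
        if cfg.output_mode == "signal":
            y_hat = out[:, 0] * half + w_min + half
            comps = None
        else:
            phi = np.mod((out[:, 0] + 1.0) * 180.0, 360.0)
            d = np.maximum(out[:, 1], 0.0) * half       # deflection is >= 0
            bl = out[:, 2] * half + w_min + half
            y_hat = reassemble(phi, d, bl)
            comps = (phi, d, bl)
        y_hat = np.where(ok, y_hat, np.nan)
        return y_hat, comps, ok

    def predict_window(self, window_mm: np.ndarray):
        """Predict one horizon step ahead of a single window.

        Returns ``(y_hat_mm, components)`` where ``components`` is a dict
        with phase/deflection/baseline in components mode and ``None`` in
        signal mode; returns :data:`NO_PREDICTION` for a flat window.
        """
        w = np.asarray(window_mm, dtype=float).ravel()
        if w.size != self.config.window_samples:
            raise ShapeError(
                f"window length {w.size} != {self.config.window_samples}")
        y_hat, comps, ok = self._forward_windows(w[None, :])
        if not ok[0]:
            return NO_PREDICTION
        if comps is None:
            return float(y_hat[0]), None
        phi, d, bl = comps
        return float(y_hat[0]), {"phase_deg": float(phi[0]),
                                 "deflection_mm": float(d[0]),
                                 "baseline_mm": float(bl[0])}

    def predict_stream(self, sig: BreathingSignal) -> PredictionTrace:
        """Causal simulation over a whole trace.

        At every index ``i >= window - 1`` the trailing window produces a
        prediction aligned to index ``i + horizon``; the output trace has
        the input's length with NaN over the leading
        ``window + horizon - 1`` samples.
        """
        cfg = self.config
        if sig.rate_hz is None or abs(sig.rate_hz - cfg.rate_hz) > 1e-6:
            raise RateMismatch(
                f"signal rate {sig.rate_hz} != predictor rate {cfg.rate_hz}")
        n = len(sig)
        W, h = cfg.window_samples, cfg.horizon_samples
        y_pred = np.full(n, np.nan)
        comps_out = None
        if cfg.output_mode == "components":
            comps_out = [np.full(n, np.nan) for _ in range(3)]
        if n >= W + h:
            wins = sliding_window_view(sig.y, W)[: n - W - h + 1]
            y_hat, comps, _ok = self._forward_windows(wins)
            j = np.arange(len(wins)) + W - 1 + h
            y_pred[j] = y_hat
            if comps is not None:
                for arr, ch in zip(comps_out, comps):
                    arr[j] = ch
        kw = {}
        if comps_out is not None:
            kw = dict(phase_pred_deg=comps_out[0],
                      deflection_pred_mm=comps_out[1],
                      baseline_pred_mm=comps_out[2])
        return PredictionTrace(t=sig.t.copy(), y_pred=y_pred, **kw)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        n_params = sum(p.size for p in self.network.params)
        lines = [
            "CyclicLSTM predictor",
            "=" * 52,
            f"output mode     : {cfg.output_mode} "
            f"({cfg.n_outputs} channel{'s' if cfg.n_outputs > 1 else ''})",
            f"input window    : {cfg.window_samples} samples "
            f"({cfg.window_samples / cfg.rate_hz:.1f} s at {cfg.rate_hz:g} Hz)",
            f"horizon         : {cfg.horizon_samples} samples "
            f"({1e3 * cfg.horizon_s:.0f} ms)",
            f"LSTM units      : {list(cfg.lstm_units)}",
            f"parameters      : {n_params}",
            f"learning rate   : {cfg.learning_rate}  batch {cfg.batch_size}"
            f"  epochs {cfg.epochs}  seed {cfg.seed}",
        ]
        if self.history.get("train_loss"):
            lines.append(f"final train loss: {self.history['train_loss'][-1]:.3e}")
        if self.history.get("val_loss"):
            lines.append(f"final val loss  : {self.history['val_loss'][-1]:.3e}")
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training/validation loss per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["train_loss"], label="train")
        if self.history.get("val_loss"):
            ax.plot(self.history["val_loss"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE (scaled units)")
        ax.set_yscale("log")
        ax.legend(frameon=False)
        return ax

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist config, weights and history to one ``.npz`` file."""
        payload = dict(self.network.state_dict())
        payload["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        payload["history_json"] = np.frombuffer(
            json.dumps(self.history).encode(), dtype=np.uint8)
        buf = io.BytesIO()
        np.savez(buf, **payload)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedPredictor":
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["config_json"]).decode())
            history = json.loads(bytes(data["history_json"]).decode())
            cfg_dict["lstm_units"] = tuple(cfg_dict["lstm_units"])
            config = PredictorConfig(**cfg_dict)
            net = LSTMRegressor(1, config.lstm_units, config.n_outputs,
                                seed=config.seed)
            net.load_state_dict({k: data[k] for k in data.files
                                 if k.startswith("param_")})
        return cls(config, net, history)


class CyclicLSTM:
    """Breathing-motion predictor model (fit returns a results object)."""

    def __init__(self, config: PredictorConfig):
        self.config = config

    def fit(self, train_sets: Sequence[TrainingSamples] | TrainingSamples,
            val_sets: Sequence[TrainingSamples] | TrainingSamples | None = None,
            verbose: bool = False) -> TrainedPredictor:
        """Train with Adam on MSE over scaled targets.

        The sample pool is reshuffled at the start of every epoch with the
        run's seeded generator; the history records mean train loss per
        epoch and, when validation sets are given, the validation loss.
        """
        cfg = self.config
        if isinstance(train_sets, TrainingSamples):
            train_sets = [train_sets]
        X, Y = _concat_samples(train_sets)
        Xv = Yv = None
        if val_sets is not None:
            if isinstance(val_sets, TrainingSamples):
                val_sets = [val_sets]
            val_sets = [s for s in val_sets if len(s)]
            if val_sets:
                Xv = np.concatenate([s.X for s in val_sets])
                Yv = np.concatenate([s.Y for s in val_sets])
        net = LSTMRegressor(1, cfg.lstm_units, cfg.n_outputs, seed=cfg.seed)
        opt = Adam(lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        # the phase channel is an angle: penalise the minimal circular
        # difference so the 0/360 wrap does not dominate the loss
        circ = (0,) if cfg.output_mode == "components" else ()
        weights = None
        if cfg.output_mode == "components" and cfg.loss_weights is not None:
            weights = np.asarray(cfg.loss_weights, dtype=np.float32)
            weights = weights / weights.mean()
        n = len(X)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, cfg.batch_size):
                sel = order[lo:lo + cfg.batch_size]
                losses.append(net.train_step(X[sel], Y[sel], opt,
                                             circular_channels=circ,
                                             channel_weights=weights))
            history["train_loss"].append(float(np.mean(losses)))
            if Xv is not None:
                pv = np.concatenate(
                    [net.forward(Xv[lo:lo + 4096]) for lo in range(0, len(Xv), 4096)])
                rv = net.residual(pv, Yv.astype(pv.dtype), circ)
                wv = 1.0 if weights is None else weights
                history["val_loss"].append(float(np.mean(wv * rv ** 2)))
            if verbose:
                msg = f"epoch {epoch + 1}/{cfg.epochs} train {history['train_loss'][-1]:.4e}"
                if Xv is not None:
                    msg += f" val {history['val_loss'][-1]:.4e}"
                print(msg)
        if Xv is None:
            history.pop("val_loss")
        return TrainedPredictor(cfg, net, history)


def train(cfg: PredictorConfig, train_sets, val_sets=None,
          verbose: bool = False) -> TrainedPredictor:
    """Functional wrapper around :class:`CyclicLSTM`."""
    return CyclicLSTM(cfg).fit(train_sets, val_sets, verbose=verbose)


def persistence_baseline(sig: BreathingSignal, cfg: PredictorConfig) -> PredictionTrace:
    """Naive baseline: predict the last observed value, same alignment.

    Emits, at index ``i + horizon``, the value observed at ``i``, with the
    same leading gap as the LSTM stream so RMSEs are directly comparable.
    """
    n = len(sig)
    W, h = cfg.window_samples, cfg.horizon_samples
    y_pred = np.full(n, np.nan)
    if n >= W + h:
        i = np.arange(W - 1, n - h)
        y_pred[i + h] = sig.y[i]
    return PredictionTrace(t=sig.t.copy(), y_pred=y_pred)
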