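"""Breathing-trace I/O and conditioning.

A surrogate breathing trace is a scalar anterior-posterior surface
displacement sampled by an optical scanner at an irregular rate (typically
13-24 Hz).  Before decomposition and prediction the trace is resampled to a
uniform 20 Hz grid, optionally cropped to drop setup artefacts, and low-pass
filtered with a maximally flat (Butterworth) IIR filter of order 8 and 1 Hz
cutoff, which removes scanner noise while leaving the breathing band
(~0.1-0.5 Hz) untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidFilter, InvalidSignal, ParseError

__all__ = [
    "BreathingSignal",
    "FilterSpec",
    "read_signal",
    "write_signal",
    "resample_uniform",
    "crop_signal",
    "lowpass",
    "butter_sos",
    "filtfilt_window",
]

#: tolerance on uniform-grid spacing (seconds)
_GRID_TOL = 1e-9


@dataclass
class BreathingSignal:
    """A timestamped displacement trace in millimetres.

    Parameters
    ----------
    t : ndarray
        Timestamps in seconds, strictly increasing.
    y : ndarray
        AP surface displacement in mm, same length as ``t``.
    rate_hz : float or None
        Sampling rate; set only when the trace is uniformly sampled.
    meta : dict
        Free-form provenance (subject id, site label, device, history of
        processing steps).
    """

    t: np.ndarray
    y: np.ndarray
    rate_hz: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise InvalidSignal("timestamps and values must be 1-D and equal length")
        if self.t.size and not np.all(np.isfinite(self.t) & np.isfinite(self.y)):
            raise InvalidSignal("non-finite timestamp or value")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise InvalidSignal("timestamps must be strictly increasing")
        if self.rate_hz is not None:
            dt = np.diff(self.t)
            if dt.size and np.any(np.abs(dt - 1.0 / self.rate_hz) > _GRID_TOL):
                raise InvalidSignal("rate_hz set but sampling is not uniform")

    def __len__(self) -> int:
        return self.t.size

    def copy(self, **updates) -> "BreathingSignal":
        kw = dict(t=self.t.copy(), y=self.y.copy(), rate_hz=self.rate_hz,
                  meta=dict(self.meta))
        kw.update(updates)
        return BreathingSignal(**kw)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter specification (maximally flat / Butterworth).

    ``zero_phase`` applies the filter forward and backward (no phase lag,
    used offline and on finite windows); ``causal`` is forward-only.
    """

    order: int = 8
    cutoff_hz: float = 1.0
    mode: Literal["zero_phase", "causal"] = "zero_phase"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise InvalidFilter("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise InvalidFilter("cutoff must be positive")
        if self.mode not in ("zero_phase", "causal"):
            raise InvalidFilter(f"unknown mode {self.mode!r}")


def read_signal(path: str | Path) -> BreathingSignal:
    """Read a two-column ``time_s,pos_mm`` CSV into a :class:`BreathingSignal`.

    A sidecar ``<path>.json`` (keys such as ``subject``, ``site``,
    ``device``) is merged into ``meta`` when present.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    cols = [c.strip() for c in df.columns]
    if len(cols) < 2 or cols[:2] != ["time_s", "pos_mm"]:
        raise ParseError(f"{path}: expected header 'time_s,pos_mm', got {list(df.columns)!r}")
    if df.empty:
        raise ParseError(f"{path}: empty data section")
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    y = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    bad = np.flatnonzero(~(np.isfinite(t) & np.isfinite(y)))
    if bad.size:
        # +2: one header line, 1-based numbering
        raise ParseError(f"{path}: malformed row at line {bad[0] + 2}")
    meta = {"source": str(path)}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return BreathingSignal(t=t, y=y, rate_hz=None, meta=meta)


def write_signal(sig: BreathingSignal, path: str | Path) -> None:
    """Write a trace as ``time_s,pos_mm`` CSV (UTF-8, '.' decimal)."""
    pd.DataFrame({"time_s": sig.t, "pos_mm": sig.y}).to_csv(path, index=False)


def resample_uniform(sig: BreathingSignal, rate_hz: float = 20.0) -> BreathingSignal:
    """Linearly interpolate a trace onto a uniform grid at ``rate_hz``.

    The grid starts at the first timestamp and extends as far as the last
    timestamp allows; values are linearly interpolated.
    """
    if len(sig) < 2:
        raise InvalidSignal("resampling needs at least 2 samples")
    t0, t1 = sig.t[0], sig.t[-1]
    n = int(np.floor((t1 - t0) * rate_hz + _GRID_TOL)) + 1
    t = t0 + np.arange(n) / rate_hz
    y = np.interp(t, sig.t, sig.y)
    meta = dict(sig.meta)
    meta["resampled_hz"] = rate_hz
    return BreathingSignal(t=t, y=y, rate_hz=rate_hz, meta=meta)


def crop_signal(sig: BreathingSignal, t_start: float, t_end: float) -> BreathingSignal:
    """Keep samples with ``t_start <= t <= t_end`` (setup-artefact removal)."""
    if t_start >= t_end:
        raise InvalidSignal("t_start must be < t_end")
    keep = (sig.t >= t_start) & (sig.t <= t_end)
    if not keep.any():
        raise InvalidSignal("crop window does not overlap the signal")
    meta = dict(sig.meta)
    meta["crop"] = (float(t_start), float(t_end))
    return BreathingSignal(t=sig.t[keep], y=sig.y[keep], rate_hz=sig.rate_hz, meta=meta)


def butter_sos(spec: FilterSpec, rate_hz: float) -> np.ndarray:
    """Design the Butterworth low-pass as second-order sections."""
    if spec.cutoff_hz >= rate_hz / 2:
        raise InvalidFilter(
            f"cutoff {spec.cutoff_hz} Hz >= Nyquist {rate_hz / 2} Hz")
    return sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=rate_hz,
                      output="sos")


def _padlen(sos: np.ndarray, n: int) -> int:
    # default scipy choice, capped so short windows remain filterable
    return min(3 * (2 * len(sos) + 1), n - 1)


def lowpass(sig: BreathingSignal, spec: FilterSpec = FilterSpec()) -> BreathingSignal:
    """Low-pass filter a uniformly sampled trace.

    ``zero_phase`` mode runs the filter forward and backward (sosfiltfilt,
    reflect padding) so the breathing band suffers no group delay; ``causal``
    mode is a single forward pass for streaming use.
    """
    if sig.rate_hz is None:
        raise InvalidSignal("lowpass requires a uniformly sampled signal")
    sos = butter_sos(spec, sig.rate_hz)
    if spec.mode == "zero_phase":
        y = sps.sosfiltfilt(sos, sig.y, padlen=_padlen(sos, len(sig)))
    else:
        y = sps.sosfilt(sos, sig.y)
    meta = dict(sig.meta)
    meta["filter"] = (spec.order, spec.cutoff_hz, spec.mode)
    return BreathingSignal(t=sig.t.copy(), y=np.asarray(y), rate_hz=sig.rate_hz,
                           meta=meta)


def filtfilt_window(windows: np.ndarray, sos: np.ndarray) -> np.ndarray:
    """Zero-phase filter each row of ``windows`` independently.

    Used for per-window filtering at inference (and for training windows, so
    both see the same distribution); vectorised over the leading axis.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    return sps.sosfiltfilt(sos, windows, axis=-1,
                           padlen=_padlen(sos, windows.shape[-1]))
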