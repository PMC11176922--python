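"""Cyclic decomposition of a breathing trace.

The breathing signal is modelled as a modulated cosine

    y(t) = d(t) + d(t) * cos(phi(t)) + BL(t)

where ``d`` is the deflection (one-half of the peak-to-trough breathing
amplitude), ``BL`` the slowly varying baseline through the lower cycle
extrema, and ``phi`` the cycle phase: 0 deg at one extremum class and
180 deg at the other, advancing 360 deg per breath.  With this sign
convention the 0-deg anchors are the signal's local *maxima* (at phi = 0
the model gives y = 2d + BL, the upper envelope) and the baseline is the
lower envelope.  Whether the maximum is anatomically exhale or inhale
depends on the scanner's sign convention; negate the input to flip it.

Decomposition proceeds in three steps: detect alternating cycle extrema
with a prominence threshold of 55 % of the mean breathing amplitude, build
piecewise-linear envelopes through each extremum class, then invert the
model for the per-sample phase via arccos.  The inversion is exact, so
reassembling the components reproduces the signal to floating-point
precision wherever the arccos argument did not need clamping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, peak_prominences, sosfiltfilt

from .errors import (
    DegenerateEnvelope,
    InsufficientPeaks,
    InvalidComponents,
    NoPeaksDetected,
)
from .preprocess import BreathingSignal

__all__ = [
    "PeakSet",
    "CyclicDecomposition",
    "detect_peaks",
    "build_envelopes",
    "decompose",
    "reassemble",
]

log = logging.getLogger(__name__)

_MAX_ITER = 5


@dataclass
class PeakSet:
    """Alternating breathing-cycle anchors.

    ``upper_idx`` are the phase-0 anchors (local maxima of the filtered
    signal), ``lower_idx`` the phase-180 anchors (local minima); they
    strictly alternate in time.  ``mean_amplitude_mm`` is the converged
    mean peak-to-trough amplitude used by the 55 % rejection rule.
    """

    upper_idx: np.ndarray
    lower_idx: np.ndarray
    threshold_frac: float = 0.55
    mean_amplitude_mm: float = float("nan")

    def merged(self) -> tuple[np.ndarray, np.ndarray]:
        """All anchors sorted by index, with +1 for upper / -1 for lower."""
        idx = np.concatenate([self.upper_idx, self.lower_idx])
        kind = np.concatenate([np.ones(len(self.upper_idx), dtype=int),
                               -np.ones(len(self.lower_idx), dtype=int)])
        order = np.argsort(idx)
        return idx[order], kind[order]


@dataclass
class CyclicDecomposition:
    """Per-sample phase/deflection/baseline components of a trace."""

    phase_deg: np.ndarray            # wrapped to [0, 360)
    phase_unwrapped_deg: np.ndarray  # monotone, 360 deg per cycle
    deflection_mm: np.ndarray
    baseline_mm: np.ndarray
    midline_mm: np.ndarray           # baseline + deflection (the y_50% curve)
    valid_mask: np.ndarray
    clamp_mask: np.ndarray
    peaks: PeakSet = field(repr=False, default=None)

    def reassembled(self) -> np.ndarray:
        """Evaluate the modulated-cosine model from the stored components."""
        return reassemble(self.phase_deg, self.deflection_mm, self.baseline_mm)


def _alternate(idx: np.ndarray, kind: np.ndarray, y: np.ndarray):
    """Enforce strict alternation: of consecutive same-sign extrema keep the
    more extreme one (higher maximum / lower minimum)."""
    keep_idx: list[int] = []
    keep_kind: list[int] = []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            prev = keep_idx[-1]
            better = (y[i] > y[prev]) if k > 0 else (y[i] < y[prev])
            if better:
                keep_idx[-1] = int(i)
        else:
            keep_idx.append(int(i))
            keep_kind.append(int(k))
    return np.asarray(keep_idx, dtype=int), np.asarray(keep_kind, dtype=int)


def _mean_amplitude(idx: np.ndarray, kind: np.ndarray, y: np.ndarray) -> float:
    """Mean |y-step| over consecutive alternating extrema (peak-to-trough)."""
    if len(idx) < 2:
        return float("nan")
    return float(np.mean(np.abs(np.diff(y[idx]))))


def detect_peaks(sig: BreathingSignal, threshold_frac: float = 0.55,
                 localize_cutoff_hz: float | None = 0.6) -> PeakSet:
    """Detect alternating breathing extrema with amplitude-based rejection.

    Iterative scheme: find all local extrema, estimate the mean
    peak-to-trough amplitude from the alternating sequence, drop extrema
    whose prominence falls below ``threshold_frac`` times that amplitude,
    re-alternate, and repeat until the retained set is stable (at most 5
    passes).  The threshold suppresses ripple and noise extrema while
    keeping genuine shallow breaths.

    Residual noise above the breathing band shifts the apparent extremum
    by a sample or two, so candidates are localised on an additionally
    smoothed copy (zero-phase low-pass at ``localize_cutoff_hz``, well
    above the breathing fundamental); set it to ``None`` to detect on the
    raw input.  Downstream envelope values are always taken from the
    input signal at the detected indices.
    """
    y = sig.y
    ys = y
    if (localize_cutoff_hz is not None and sig.rate_hz is not None
            and localize_cutoff_hz < sig.rate_hz / 2 and len(y) > 30):
        sos = butter(4, localize_cutoff_hz, btype="low", fs=sig.rate_hz,
                     output="sos")
        ys = sosfiltfilt(sos, y)
    # candidates localised on the smoothed copy; plateau tie-break: first
    # sample of the plateau
    up, up_props = find_peaks(ys, plateau_size=(None, None))
    lo, lo_props = find_peaks(-ys, plateau_size=(None, None))
    up = up_props["left_edges"] if len(up) else up
    lo = lo_props["left_edges"] if len(lo) else lo
    if len(up) == 0 or len(lo) == 0:
        raise NoPeaksDetected("no alternating extrema found")
    up_prom = peak_prominences(ys, up)[0]
    lo_prom = peak_prominences(-ys, lo)[0]
    prom = {int(i): float(p) for i, p in zip(up, up_prom)}
    prom.update({int(i): float(p) for i, p in zip(lo, lo_prom)})

    idx = np.concatenate([up, lo])
    kind = np.concatenate([np.ones(len(up), dtype=int), -np.ones(len(lo), dtype=int)])
    order = np.argsort(idx)
    idx, kind = _alternate(idx[order], kind[order], y)

    mean_amp = float("nan")
    for _ in range(_MAX_ITER):
        mean_amp = _mean_amplitude(idx, kind, y)
        if not np.isfinite(mean_amp):
            raise NoPeaksDetected("no alternating pair of extrema")
        keep = np.array([prom[int(i)] >= threshold_frac * mean_amp for i in idx])
        new_idx, new_kind = _alternate(idx[keep], kind[keep], y)
        if len(new_idx) == len(idx) and np.array_equal(new_idx, idx):
            idx, kind = new_idx, new_kind
            break
        idx, kind = new_idx, new_kind
        if len(idx) < 2:
            raise NoPeaksDetected("threshold rejected all alternating extrema")
    mean_amp = _mean_amplitude(idx, kind, y)
    if len(idx) < 2 or not np.isfinite(mean_amp):
        raise NoPeaksDetected("no alternating pair of extrema after rejection")
    return PeakSet(upper_idx=idx[kind > 0], lower_idx=idx[kind < 0],
                   threshold_frac=threshold_frac, mean_amplitude_mm=mean_amp)


def build_envelopes(sig: BreathingSignal, peaks: PeakSet):
    """Piecewise-linear envelopes through the anchors.

    Returns ``(upper_curve, baseline, midline)`` in mm, each defined only
    where both interpolants are defined (NaN elsewhere): no extrapolation
    beyond the first/last anchor of either class.
    """
    y = sig.y
    up, lo = peaks.upper_idx, peaks.lower_idx
    if len(up) + len(lo) < 2 or len(up) == 0 or len(lo) == 0:
        raise InsufficientPeaks("need at least one anchor of each class")
    n = len(y)
    i = np.arange(n, dtype=float)
    upper = np.interp(i, up.astype(float), y[up])
    lower = np.interp(i, lo.astype(float), y[lo])
    start = max(up[0], lo[0])
    end = min(up[-1], lo[-1])
    valid = (np.arange(n) >= start) & (np.arange(n) <= end)
    upper[~valid] = np.nan
    lower[~valid] = np.nan
    mid = (upper + lower) / 2.0
    return upper, lower, mid


def decompose(sig: BreathingSignal, peaks: PeakSet) -> CyclicDecomposition:
    """Invert the modulated-cosine model for per-sample phase.

    With ``c = (y - d - BL) / d`` clamped to [-1, 1], the phase in a
    half-cycle running from an upper anchor to the next lower anchor is
    ``arccos(c)`` in [0, 180] deg, and ``360 - arccos(c)`` on the way back
    up; the unwrapped phase accumulates 360 deg per completed cycle.
    """
    y = sig.y
    upper, lower, mid = build_envelopes(sig, peaks)
    n = len(y)
    d = mid - lower                      # = (upper - lower) / 2
    bl = lower
    valid = np.isfinite(mid)
    if np.any(d[valid] <= 0):
        raise DegenerateEnvelope("non-positive deflection on the valid region")

    c = np.full(n, np.nan)
    c[valid] = (y[valid] - d[valid] - bl[valid]) / d[valid]
    clamp = np.zeros(n, dtype=bool)
    out_of_range = valid & ((c < -1) | (c > 1))
    clamp[out_of_range] = True
    if np.any(valid & ((c < -1.001) | (c > 1.001))):
        log.warning("arccos argument outside [-1.001, 1.001]: envelope inconsistency")
    cc = np.clip(c, -1.0, 1.0)

    phase = np.full(n, np.nan)
    unwrapped = np.full(n, np.nan)
    idx, kind = peaks.merged()
    # keep only anchors inside the valid span
    inside = (idx >= np.flatnonzero(valid)[0]) & (idx <= np.flatnonzero(valid)[-1])
    idx, kind = idx[inside], kind[inside]
    cum = 0.0
    for a, b, ka in zip(idx[:-1], idx[1:], kind[:-1]):
        sl = slice(a, b)
        acos = np.degrees(np.arccos(cc[sl]))
        if ka > 0:                       # upper -> lower: phi in [0, 180]
            unwrapped[sl] = cum + acos
        else:                            # lower -> upper: phi in [180, 360]
            unwrapped[sl] = cum + 360.0 - acos
        if ka < 0:                       # cycle completes at the next upper anchor
            cum += 360.0
    last = idx[-1]
    unwrapped[last] = cum if kind[-1] > 0 else cum + 180.0

    # Near the arccos branch points an imperfect envelope can make the raw
    # phase retreat by a fraction of a degree; enforce monotonicity with a
    # running maximum and flag adjusted samples as clamped (they indicate
    # the same envelope inconsistency clamping does).
    vi = np.flatnonzero(valid)
    mono = np.maximum.accumulate(unwrapped[vi])
    adjusted = mono > unwrapped[vi] + 1e-9
    clamp[vi[adjusted]] = True
    unwrapped[vi] = mono
    phase[valid] = np.mod(unwrapped[valid], 360.0)

    return CyclicDecomposition(
        phase_deg=phase,
        phase_unwrapped_deg=unwrapped,
        deflection_mm=d,
        baseline_mm=bl,
        midline_mm=mid,
        valid_mask=valid,
        clamp_mask=clamp,
        peaks=peaks,
    )


def reassemble(phase_deg, deflection_mm, baseline_mm) -> np.ndarray:
    """Evaluate ``y = d + d cos(phi) + BL`` elementwise."""
    d = np.asarray(deflection_mm, dtype=float)
    if np.any(d[np.isfinite(d)] < 0):
        raise InvalidComponents("negative deflection")
    phi = np.radians(np.asarray(phase_deg, dtype=float))
    return d + d * np.cos(phi) + np.asarray(baseline_mm, dtype=float)
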