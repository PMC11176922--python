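"""Dynamic per-window normalisation.

Each input window is mapped affinely into [-1, 1] using its own extremes:
with ``y_half = (y_max - y_min) / 2``,

    y_scaled = (y - y_min - y_half) / y_half

so the window minimum maps exactly to -1 and the maximum to +1.  The same
affine map applied to the modulated-cosine model splits into per-component
channels,

    d_channel  = d / y_half
    bl_channel = (BL - y_min - y_half) / y_half

and the scaled components recompose to the scaled signal:
``d_ch + d_ch * cos(phi) + bl_ch == scale(y)`` exactly, because the map is
affine.  This consistency is what lets the three-channel model train in
scaled space and still predict in millimetres after inversion.

The phase is not a length and is encoded separately: the wrapped phase is
mapped linearly to [-1, 1] via ``phi / 180 - 1`` so all channels share the
same numeric range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateWindow

__all__ = [
    "WindowScaling",
    "window_params",
    "scale_signal",
    "scale_components",
    "unscale",
    "encode_phase",
    "decode_phase",
    "unscale_components",
]

#: windows with a dynamic range below this are treated as flat (mm)
_RANGE_EPS = 1e-12


@dataclass(frozen=True)
class WindowScaling:
    """Per-window affine normalisation parameters (all mm)."""

    y_min: float
    y_max: float
    y_half: float

    def __post_init__(self) -> None:
        if not (self.y_max > self.y_min) or not (self.y_half > 0):
            raise DegenerateWindow("window has no dynamic range")


def window_params(window: np.ndarray) -> WindowScaling:
    """Scaling parameters from a window's extremes."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise DegenerateWindow("empty window")
    y_min = float(np.min(w))
    y_max = float(np.max(w))
    if y_max - y_min <= _RANGE_EPS:
        raise DegenerateWindow("flat window")
    return WindowScaling(y_min=y_min, y_max=y_max, y_half=(y_max - y_min) / 2.0)


def scale_signal(y, p: WindowScaling):
    """Affine map sending the window extremes to -1 and +1."""
    return (np.asarray(y, dtype=float) - p.y_min - p.y_half) / p.y_half


def unscale(values, p: WindowScaling):
    """Exact inverse of :func:`scale_signal` (back to mm)."""
    return np.asarray(values, dtype=float) * p.y_half + p.y_min + p.y_half


def encode_phase(phase_deg):
    """Wrapped phase [0, 360) -> [-1, 1) channel."""
    return np.asarray(phase_deg, dtype=float) / 180.0 - 1.0


def decode_phase(channel):
    """Inverse of :func:`encode_phase`, clipped to one turn."""
    phi = (np.asarray(channel, dtype=float) + 1.0) * 180.0
    return np.mod(phi, 360.0)


def scale_components(phase_deg, deflection_mm, baseline_mm, p: WindowScaling):
    """Scale decomposition components with the window's affine map.

    Returns ``(phase_channel, deflection_channel, baseline_channel)``.
    Deflection is a length difference, so only the scale factor applies;
    the baseline carries the offset; the phase is encoded linearly.
    """
    d = np.asarray(deflection_mm, dtype=float)
    if np.any(d[np.isfinite(d)] < 0):
        raise DegenerateWindow("negative deflection")
    d_ch = d / p.y_half
    bl_ch = (np.asarray(baseline_mm, dtype=float) - p.y_min - p.y_half) / p.y_half
    return encode_phase(phase_deg), d_ch, bl_ch


def unscale_components(phase_channel, deflection_channel, baseline_channel,
                       p: WindowScaling):
    """Invert :func:`scale_components` back to (phase_deg, d_mm, BL_mm)."""
    phi = decode_phase(phase_channel)
    d = np.asarray(deflection_channel, dtype=float) * p.y_half
    bl = np.asarray(baseline_channel, dtype=float) * p.y_half + p.y_min + p.y_half
    return phi, d, bl
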