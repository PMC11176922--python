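"""Synthetic respiratory surrogate traces with known ground truth.

The generator builds quasi-periodic breathing by construction of the same
components the decomposition extracts: alternating cycle anchors (upper =
peak inhale surface position, lower = resting exhale) placed on the 20 Hz
sample grid, piecewise-linear envelopes through those anchors, a phase
that advances linearly in time through each half-cycle, and a cycle-shape
function

    s(phi) = 2 * ((1 + cos phi) / 2) ** n - 1

whose exponent ``n >= 1`` flattens the end-exhale part of the cycle
(longer rest at exhale, as real abdominal traces show) while keeping the
extrema exactly at the anchors.  With ``n = 1`` the clean trace is exactly
the modulated-cosine model, so decomposition must recover the generator's
components; with ``n > 1`` the waveform deviates from the pure cosine
between anchors, which deliberately exercises the arccos inversion on
non-cosine shapes.

Per-cycle periods and amplitudes follow a stationary AR(1) process around
their means (lag-1 correlation 0.7): breath-to-breath parameters are
strongly autocorrelated in resting subjects, so successive cycles resemble
each other while the trace still wanders over minutes.  Slow sinusoidal
amplitude modulation and baseline wander emulate posture drift; white
Gaussian noise is added last (the standard 1 Hz low-pass in preprocessing
plays the role of scanner-noise removal).  Site presets match the two
cohort surrogate locations: 'sternum' (small, ~2.4 mm mean amplitude) and
'abdomen' (large, ~10.7 mm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import CyclicDecomposition, PeakSet
from .errors import InvalidConfig
from .preprocess import BreathingSignal

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SITE_PRESETS",
    "generate_trace",
    "generate_cohort",
    "write_cohort",
]

#: cohort-level amplitude statistics (mm, mean and between-trace SD) and the
#: typical min/max signal range for the two surrogate sites
SITE_PRESETS: dict[str, dict] = {
    "sternum": {"amplitude_mean_mm": 2.4, "amplitude_between_sd_mm": 1.9},
    "abdomen": {"amplitude_mean_mm": 10.7, "amplitude_between_sd_mm": 2.7},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic trace.

    ``period_s`` / ``amplitude_mm`` give the per-cycle mean and SD;
    ``amplitude_drift`` is a slow multiplicative modulation (relative
    amplitude, period in s); ``baseline_drift_mm`` an additive sinusoidal
    wander (amplitude in mm, period in s).
    """

    duration_s: float = 180.0
    rate_hz: float = 20.0
    period_s: tuple[float, float] = (4.0, 0.35)
    amplitude_mm: tuple[float, float] = (10.7, 1.3)
    amplitude_drift: tuple[float, float] = (0.12, 60.0)
    baseline_drift_mm: tuple[float, float] = (1.0, 90.0)
    baseline_offset_mm: float = 0.0
    exhale_rest_exponent: float = 1.0
    noise_sd_mm: float = 0.3
    cycle_autocorr: float = 0.7      # lag-1 correlation of cycle parameters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_s[0] <= 0 or self.amplitude_mm[0] <= 0:
            raise InvalidConfig("period and amplitude means must be positive")
        if self.exhale_rest_exponent < 1:
            raise InvalidConfig("exhale_rest_exponent must be >= 1")
        if self.duration_s < 3 * self.period_s[0]:
            raise InvalidConfig("duration must cover at least 3 breathing periods")
        if self.rate_hz <= 0 or self.noise_sd_mm < 0:
            raise InvalidConfig("rate_hz must be positive, noise_sd_mm >= 0")
        if not 0.0 <= self.cycle_autocorr < 1.0:
            raise InvalidConfig("cycle_autocorr must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground-truth components recorded before noise was added."""

    dec: CyclicDecomposition
    clean_mm: np.ndarray
    cycle_amplitudes_mm: np.ndarray
    cycle_periods_s: np.ndarray


def _truncated_normal(rng, mean, sd, lo, n):
    """Normal draws with resampling below ``lo`` (no distribution folding)."""
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = out < lo
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(out, lo)


def generate_trace(cfg: SyntheticConfig) -> tuple[BreathingSignal, SyntheticTruth]:
    """Generate one trace plus its ground-truth decomposition.

    Anchors land exactly on the sample grid; with zero noise, zero drift
    and exponent 1 the trace is an exact raised cosine with constant
    components.  The same seed always reproduces the same trace.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.rate_hz
    n_target = int(round(cfg.duration_s * cfg.rate_hz))
    p_mean, p_sd = cfg.period_s
    a_mean, a_sd = cfg.amplitude_mm
    drift_rel, drift_period = cfg.amplitude_drift
    bl_amp, bl_period = cfg.baseline_drift_mm

    # alternating anchors on the grid, starting with an upper anchor at 0
    upper_idx: list[int] = [0]
    lower_idx: list[int] = []
    amps: list[float] = []
    periods: list[float] = []
    i = 0
    rho = cfg.cycle_autocorr
    innov = np.sqrt(1.0 - rho * rho)
    z_amp = float(rng.standard_normal())
    z_per = float(rng.standard_normal())
    while i < n_target:
        # stationary AR(1) deviations: successive breaths resemble each other
        z_per = rho * z_per + innov * float(rng.standard_normal())
        z_amp = rho * z_amp + innov * float(rng.standard_normal())
        period = max(p_mean + p_sd * z_per, 0.4 * p_mean)
        half = max(2, int(round(period * cfg.rate_hz / 2.0)))
        amp = max(a_mean + a_sd * z_amp, 0.15 * a_mean)
        if drift_rel > 0:
            amp *= 1.0 + drift_rel * np.sin(2 * np.pi * i * dt / drift_period)
        amps.append(max(amp, 0.05 * a_mean))
        periods.append(2 * half * dt)
        lower_idx.append(i + half)
        upper_idx.append(i + 2 * half)
        i += 2 * half
    n = upper_idx[-1] + 1
    t = np.arange(n) * dt
    up = np.asarray(upper_idx)
    lo = np.asarray(lower_idx)
    amps_arr = np.asarray(amps)

    def bl_fun(tt):
        out = np.full_like(np.asarray(tt, dtype=float), cfg.baseline_offset_mm)
        if bl_amp > 0:
            out = out + bl_amp * np.sin(2 * np.pi * np.asarray(tt) / bl_period)
        return out

    # envelope knots; the last upper anchor reuses the final cycle amplitude
    up_vals = bl_fun(t[up]) + np.append(amps_arr, amps_arr[-1])[: len(up)]
    lo_vals = bl_fun(t[lo])
    grid = np.arange(n, dtype=float)
    upper_env = np.interp(grid, up.astype(float), up_vals)
    lower_env = np.interp(grid, lo.astype(float), lo_vals)
    mid = (upper_env + lower_env) / 2.0
    d = (upper_env - lower_env) / 2.0

    # phase: linear in time through each half-cycle, 360 deg per breath
    merged = np.sort(np.concatenate([up, lo]))
    kinds = np.isin(merged, up)
    unwrapped = np.empty(n)
    cum = 0.0
    for a, b, a_is_up in zip(merged[:-1], merged[1:], kinds[:-1]):
        frac = (grid[a:b] - a) / (b - a)
        if a_is_up:
            unwrapped[a:b] = cum + 180.0 * frac
        else:
            unwrapped[a:b] = cum + 180.0 + 180.0 * frac
            cum += 360.0
    unwrapped[-1] = cum if kinds[-1] else cum + 180.0
    phase = np.mod(unwrapped, 360.0)

    nexp = cfg.exhale_rest_exponent
    shape = 2.0 * ((1.0 + np.cos(np.radians(phase))) / 2.0) ** nexp - 1.0
    clean = mid + d * shape
    y = clean + rng.normal(0.0, cfg.noise_sd_mm, size=n) if cfg.noise_sd_mm > 0 \
        else clean.copy()

    start = max(up[0], lo[0])
    end = min(up[-1], lo[-1])
    valid = (grid >= start) & (grid <= end)
    truth_dec = CyclicDecomposition(
        phase_deg=phase, phase_unwrapped_deg=unwrapped, deflection_mm=d,
        baseline_mm=lower_env, midline_mm=mid, valid_mask=valid,
        clamp_mask=np.zeros(n, dtype=bool),
        peaks=PeakSet(upper_idx=up, lower_idx=lo,
                      mean_amplitude_mm=float(np.mean(amps_arr))))
    sig = BreathingSignal(
        t=t, y=y, rate_hz=cfg.rate_hz,
        meta={"source": "synthetic", "seed": cfg.seed,
              "config": {"duration_s": cfg.duration_s,
                         "amplitude_mm": cfg.amplitude_mm,
                         "period_s": cfg.period_s,
                         "noise_sd_mm": cfg.noise_sd_mm,
                         "exhale_rest_exponent": cfg.exhale_rest_exponent}})
    truth = SyntheticTruth(dec=truth_dec, clean_mm=clean,
                           cycle_amplitudes_mm=amps_arr,
                           cycle_periods_s=np.asarray(periods))
    return sig, truth


def _subject_config(rng, site: str, duration_s: float,
                    overrides: dict | None) -> SyntheticConfig:
    preset = SITE_PRESETS[site]
    a_mean = float(_truncated_normal(
        rng, preset["amplitude_mean_mm"], preset["amplitude_between_sd_mm"],
        0.6, 1)[0])
    p_mean = float(np.clip(rng.normal(4.0, 0.6), 2.6, 6.0))
    kw = dict(
        duration_s=duration_s,
        period_s=(p_mean, 0.08 * p_mean),
        amplitude_mm=(a_mean, 0.12 * a_mean),
        amplitude_drift=(float(rng.uniform(0.05, 0.18)),
                         float(rng.uniform(45.0, 90.0))),
        baseline_drift_mm=(float(rng.uniform(0.3, 1.5)),
                           float(rng.uniform(60.0, 120.0))),
        baseline_offset_mm=float(rng.normal(0.0, 2.0)),
        exhale_rest_exponent=float(rng.uniform(1.0, 2.5)),
        noise_sd_mm=0.3,
        seed=int(rng.integers(2 ** 31)),
    )
    if overrides:
        kw.update(overrides)
    return SyntheticConfig(**kw)


def generate_cohort(n_subjects: int, site_mix=("sternum", "abdomen"),
                    duration_s: float = 240.0, seed: int = 0,
                    overrides: dict | None = None):
    """Generate a cohort of traces (``site_mix`` sites per subject).

    Returns ``(traces, manifest)`` where ``traces`` is a list of
    ``(BreathingSignal, SyntheticTruth)`` and the manifest records
    subject, site, per-trace seed and true parameters.  Deterministic
    under the master seed.
    """
    if n_subjects < 1:
        raise InvalidConfig("n_subjects must be >= 1")
    for site in site_mix:
        if site not in SITE_PRESETS:
            raise InvalidConfig(f"unknown site {site!r}")
    rng = np.random.default_rng(seed)
    traces, rows = [], []
    for s in range(n_subjects):
        for site in site_mix:
            cfg = _subject_config(rng, site, duration_s, overrides)
            sig, truth = generate_trace(cfg)
            sig.meta.update(subject=f"S{s:03d}", site=site)
            traces.append((sig, truth))
            rows.append({
                "subject": f"S{s:03d}", "site": site, "seed": cfg.seed,
                "duration_s": cfg.duration_s,
                "period_mean_s": cfg.period_s[0],
                "amplitude_mean_mm": cfg.amplitude_mm[0],
                "exhale_rest_exponent": cfg.exhale_rest_exponent,
                "noise_sd_mm": cfg.noise_sd_mm,
                "mean_cycle_amplitude_mm": float(np.mean(truth.cycle_amplitudes_mm)),
            })
    return traces, pd.DataFrame(rows)


def write_cohort(traces, manifest: pd.DataFrame, out_dir: str | Path) -> None:
    """Write per-trace signal and ground-truth CSVs plus manifest.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, (sig, truth) in enumerate(traces):
        name = f"{sig.meta.get('subject', 'S')}_{sig.meta.get('site', '')}_{k:03d}"
        pd.DataFrame({"time_s": sig.t, "pos_mm": sig.y}).to_csv(
            out / f"{name}.csv", index=False)
        d = truth.dec
        pd.DataFrame({
            "time_s": sig.t, "pos_mm": truth.clean_mm,
            "phase_deg": d.phase_deg, "deflection_mm": d.deflection_mm,
            "baseline_mm": d.baseline_mm,
            "valid": d.valid_mask.astype(int),
            "clamped": d.clamp_mask.astype(int),
        }).to_csv(out / f"{name}_truth.csv", index=False)
    manifest.to_csv(out / "manifest.csv", index=False)
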