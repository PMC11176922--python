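"""Prediction-accuracy metrics and cohort summaries.

Per dataset the absolute RMSE of the reassembled signal and of each
decomposition component is computed; the phase error is circular (the
minimal angular difference, so 350 deg vs 10 deg counts as 20 deg).
Datasets are grouped by breathing amplitude: 'large' when any cycle
exceeds 12 mm peak-to-trough, else 'small'.  Cohort summaries report the
unweighted mean +/- sample SD over datasets, overall and per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decompose import CyclicDecomposition
from .errors import EmptyEval, ShapeError

__all__ = [
    "rmse",
    "circular_rmse",
    "amplitude_group",
    "cohort_summary",
    "EvalReport",
    "AMPLITUDE_THRESHOLD_MM",
]

#: peak-to-trough amplitude separating the 'small' and 'large' groups (strict >)
AMPLITUDE_THRESHOLD_MM = 12.0

_METRICS = ["rmse_y_mm", "rmse_phase_deg", "rmse_d_mm", "rmse_bl_mm"]


def _paired(pred, truth):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ShapeError(f"length mismatch: {pred.shape} vs {truth.shape}")
    keep = np.isfinite(pred) & np.isfinite(truth)
    if not keep.any():
        raise EmptyEval("no finite prediction/truth pairs")
    return pred[keep], truth[keep]


def rmse(pred, truth) -> float:
    """Root-mean-square error; NaN gaps are excluded pairwise."""
    p, t = _paired(pred, truth)
    return float(np.sqrt(np.mean((p - t) ** 2)))


def circular_rmse(pred_deg, truth_deg) -> float:
    """RMSE of the minimal angular difference, in degrees.

    Per-sample errors are wrapped into (-180, 180], so the result is
    bounded by 180 deg and agrees with the plain RMSE whenever no
    difference crosses the wrap.
    """
    p, t = _paired(pred_deg, truth_deg)
    delta = np.mod(p - t, 360.0)
    delta = np.where(delta > 180.0, delta - 360.0, delta)
    return float(np.sqrt(np.mean(delta ** 2)))


def cycle_amplitudes(dec: CyclicDecomposition) -> np.ndarray:
    """Peak-to-trough amplitude (2 d) of each breathing half-cycle,
    evaluated at the midpoint between consecutive anchors."""
    if dec.peaks is None:
        raise EmptyEval("decomposition carries no anchors")
    idx, _ = dec.peaks.merged()
    if len(idx) < 2:
        raise EmptyEval("no complete cycle")
    mids = ((idx[:-1] + idx[1:]) // 2).astype(int)
    amps = 2.0 * dec.deflection_mm[mids]
    amps = amps[np.isfinite(amps)]
    if amps.size == 0:
        raise EmptyEval("no cycle amplitude on the valid region")
    return amps


def amplitude_group(dec: CyclicDecomposition) -> str:
    """'large' iff any cycle amplitude strictly exceeds 12 mm, else 'small'."""
    amps = cycle_amplitudes(dec)
    return "large" if np.any(amps > AMPLITUDE_THRESHOLD_MM) else "small"


@dataclass
class EvalReport:
    """Per-dataset metrics plus cohort mean +/- SD rows (All/large/small)."""

    per_dataset: list[dict] = field(default_factory=list)
    cohort: pd.DataFrame | None = None
    single_dataset_sd_flag: bool = False

    def to_json_dict(self) -> dict:
        return {
            "per_dataset": self.per_dataset,
            "cohort": self.cohort.reset_index().to_dict(orient="records"),
            "single_dataset_sd_flag": self.single_dataset_sd_flag,
        }


def cohort_summary(per_dataset: list[dict]) -> EvalReport:
    """Aggregate per-dataset metric dicts into the cohort table.

    Each dict needs at least ``id``, ``group`` and one of the metric keys
    (``rmse_y_mm``, ``rmse_phase_deg``, ``rmse_d_mm``, ``rmse_bl_mm``).
    SD is the sample standard deviation (ddof=1); a single-dataset group
    reports SD 0 and sets a flag.
    """
    if not per_dataset:
        raise EmptyEval("no datasets to summarise")
    df = pd.DataFrame(per_dataset)
    rows = []
    flag = False

    def one_row(label: str, sub: pd.DataFrame):
        nonlocal flag
        row: dict = {"group": label, "n": len(sub)}
        for m in _METRICS:
            if m not in sub.columns:
                continue
            vals = sub[m].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            row[f"{m}_mean"] = float(np.mean(vals))
            if vals.size == 1:
                row[f"{m}_sd"] = 0.0
                flag = True
            else:
                row[f"{m}_sd"] = float(np.std(vals, ddof=1))
        return row

    rows.append(one_row("All", df))
    for label in ("large", "small"):
        sub = df[df["group"] == label]
        if len(sub):
            rows.append(one_row(label, sub))
    cohort = pd.DataFrame(rows).set_index("group")
    return EvalReport(per_dataset=per_dataset, cohort=cohort,
                      single_dataset_sd_flag=flag)
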