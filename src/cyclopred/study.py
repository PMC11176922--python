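"""Scaled-down end-to-end study: cohort, training, head-to-head evaluation.

This module wires the whole pipeline together at desk scale: a seeded
synthetic cohort of 12 training traces (8 abdomen-preset, 4 sternum-preset,
3 min each) plus 3 held-out test traces, both predictor variants trained
under an identical budget (window 160 samples, units 20/20/20, learning
rate 0.01, batch 256, 30 epochs), and causal streaming evaluation on the
held-out traces against the persistence baseline.

Problem sizes are deliberately small compared to the 70-dataset volunteer
study the method was designed around, but preserve its structure: subject-
level 4:1 train/validation split, dynamic per-window scaling, per-window
filtering, and the 500 ms horizon.  Training windows are subsampled with
stride 4 (one window start every 200 ms); consecutive 20 Hz windows
overlap in all but one sample, so this keeps the sample pool diverse while
cutting redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decompose import decompose, detect_peaks
from .evaluate import circular_rmse, cycle_amplitudes, rmse
from .predict import (
    CyclicLSTM,
    PredictorConfig,
    make_samples,
    persistence_baseline,
    split_train_val,
)
from .preprocess import lowpass
from .synth import _subject_config, generate_trace

__all__ = ["StudyResult", "study_config", "make_study_cohort", "run_study"]

N_ABDOMEN = 8
N_STERNUM = 4
N_HELD_OUT = 3          # 2 abdomen + 1 sternum
TRACE_DURATION_S = 180.0


def study_config(seed: int, output_mode: str) -> PredictorConfig:
    """The fixed scaled-down training budget (identical for both models)."""
    return PredictorConfig(
        window_samples=160, horizon_samples=10, lstm_units=(20, 20, 20),
        learning_rate=0.01, batch_size=256, epochs=30, seed=seed,
        output_mode=output_mode, stride=4)


def _prepare(sig):
    """Offline preprocessing + decomposition of one synthetic trace."""
    filt = lowpass(sig)
    dec = decompose(filt, detect_peaks(filt))
    return filt, dec


def make_study_cohort(seed: int):
    """Seeded cohort: 12 training and 3 held-out traces with metadata.

    Returns ``(train_list, test_list)`` of dicts with keys ``raw``,
    ``filt``, ``dec`` and ``site``; every trace belongs to its own
    subject so the 4:1 split is subject-respecting by construction.
    """
    rng = np.random.default_rng(seed)
    sites = ["abdomen"] * N_ABDOMEN + ["sternum"] * N_STERNUM
    test_sites = ["abdomen", "abdomen", "sternum"]
    cohort = []
    for k, site in enumerate(sites + test_sites):
        cfg = _subject_config(rng, site, TRACE_DURATION_S, None)
        sig, truth = generate_trace(cfg)
        sig.meta.update(subject=f"S{k:03d}", site=site)
        filt, dec = _prepare(sig)
        cohort.append({"raw": sig, "filt": filt, "dec": dec,
                       "truth": truth, "site": site})
    return cohort[: len(sites)], cohort[len(sites):]


@dataclass
class StudyResult:
    """Head-to-head outcome of the scaled-down study."""

    model1_rmse_mm: float
    model2_rmse_mm: float
    persistence_rmse_mm: float
    model2_phase_rmse_deg: float
    model2_deflection_rmse_mm: float
    model2_baseline_rmse_mm: float
    cohort_mean_amplitude_mm: float
    per_trace_rmse_mm: dict
    n_train_samples: int
    n_predictions: int
    history: dict


def _stream_metrics(pred_result, ds):
    """Streaming signal RMSE (and component RMSEs) on one held-out trace."""
    trace = pred_result.predict_stream(ds["raw"])
    truth_y = ds["filt"].y
    mask = np.isfinite(trace.y_pred)
    out = {"rmse_y_mm": rmse(trace.y_pred[mask], truth_y[mask]),
           "n": int(mask.sum())}
    if trace.phase_pred_deg is not None:
        dec = ds["dec"]
        m = mask & dec.valid_mask
        out["rmse_phase_deg"] = circular_rmse(trace.phase_pred_deg[m],
                                              dec.phase_deg[m])
        out["rmse_d_mm"] = rmse(trace.deflection_pred_mm[m],
                                dec.deflection_mm[m])
        out["rmse_bl_mm"] = rmse(trace.baseline_pred_mm[m],
                                 dec.baseline_mm[m])
    return out


def run_study(seed: int = 1, verbose: bool = False) -> StudyResult:
    """Generate the cohort, train Model 1 and Model 2, evaluate held-out.

    Both models share the training traces, the subject-level 4:1 split and
    the training budget; only the output encoding differs.  Reported RMSEs
    are unweighted means over the three held-out traces.
    """
    train_ds, test_ds = make_study_cohort(seed)
    signals = [ds["filt"] for ds in train_ds]
    for ds, sig in zip(train_ds, signals):
        sig.meta.setdefault("subject", ds["raw"].meta["subject"])
    tr_sigs, val_sigs = split_train_val(signals, seed=seed)
    tr_ids = {id(s) for s in tr_sigs}

    results = {}
    histories = {}
    n_train = 0
    for mode in ("signal", "components"):
        cfg = study_config(seed, mode)
        samp = [make_samples(ds["filt"], ds["dec"], cfg, raw=ds["raw"])
                for ds in train_ds]
        tr = [s for s, ds in zip(samp, train_ds) if id(ds["filt"]) in tr_ids]
        va = [s for s, ds in zip(samp, train_ds) if id(ds["filt"]) not in tr_ids]
        n_train = sum(len(s) for s in tr)
        fitted = CyclicLSTM(cfg).fit(tr, va, verbose=verbose)
        results[mode] = fitted
        histories[mode] = fitted.history

    per_trace = {"model1": [], "model2": [], "persistence": []}
    comp = {"rmse_phase_deg": [], "rmse_d_mm": [], "rmse_bl_mm": []}
    n_pred = 0
    for ds in test_ds:
        m1 = _stream_metrics(results["signal"], ds)
        m2 = _stream_metrics(results["components"], ds)
        pers = persistence_baseline(ds["raw"], results["signal"].config)
        mask = np.isfinite(pers.y_pred)
        per_trace["model1"].append(m1["rmse_y_mm"])
        per_trace["model2"].append(m2["rmse_y_mm"])
        per_trace["persistence"].append(
            rmse(pers.y_pred[mask], ds["filt"].y[mask]))
        for k in comp:
            comp[k].append(m2[k])
        n_pred += m2["n"]

    amp = float(np.mean([np.mean(cycle_amplitudes(ds["dec"]))
                         for ds in train_ds]))
    return StudyResult(
        model1_rmse_mm=float(np.mean(per_trace["model1"])),
        model2_rmse_mm=float(np.mean(per_trace["model2"])),
        persistence_rmse_mm=float(np.mean(per_trace["persistence"])),
        model2_phase_rmse_deg=float(np.mean(comp["rmse_phase_deg"])),
        model2_deflection_rmse_mm=float(np.mean(comp["rmse_d_mm"])),
        model2_baseline_rmse_mm=float(np.mean(comp["rmse_bl_mm"])),
        cohort_mean_amplitude_mm=amp,
        per_trace_rmse_mm={k: list(map(float, v)) for k, v in per_trace.items()},
        n_train_samples=int(n_train),
        n_predictions=int(n_pred),
        history=histories,
    )
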