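"""End-to-end synthetic recovery experiments.

These run the full analysis pipelines on simulated data where ground truth
is known, and measure how well each stage recovers it:

* :func:`run_peak_recovery` — train the wave-1 CNN regressor on synthetic
  waveforms, then measure end-to-end (scale -> CNN -> refinement) latency
  and amplitude errors on held-out subjects;
* :func:`run_threshold_recovery` — train the supra-threshold CNN
  classifier on synthetic stacks, then score held-out stacks and measure
  per-waveform classification metrics and threshold agreement with truth.

Both are seeded and sized to complete in a few minutes on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import Stack
from .peakfind import PeakRegressor, PeakRegressorConfig, refine_peaks
from .preprocess import scale_per_waveform
from .synthetic import SynthConfig, SyntheticTruth, generate_dataset
from .threshold import (ThresholdClassifierConfig, batch_thresholds,
                        make_classifier, stack_features)
from .train_eval import (AugmentConfig, SplitSpec, augment, augment_dataset,
                         evaluate_classifier, evaluate_peaks,
                         source_balanced_weights, split_by_subject,
                         within_k_db)

logger = logging.getLogger("abrkit")


def _supra_arrays(stacks: list[Stack], truth: SyntheticTruth,
                  noise_sd: float):
    """Scaled supra-threshold waveforms with wave-1 labels and SNR."""
    X, y, snr, amp_t, lat_t, waves, src = [], [], [], [], [], [], []
    for s in stacks:
        for w in s:
            wt = truth.waves[(w.subject_id, w.frequency_khz, w.level_db)]
            if not wt.above_threshold:
                continue
            X.append(scale_per_waveform(w).voltages)
            y.append(wt.peak_idx[0])
            snr.append(wt.wave1_amplitude_uv / noise_sd if noise_sd > 0
                       else np.inf)
            amp_t.append(wt.wave1_amplitude_uv)
            lat_t.append(wt.wave1_latency_ms)
            waves.append(w)
            src.append(w.source_label)
    return (np.asarray(X), np.asarray(y, dtype=float), np.asarray(snr),
            np.asarray(amp_t), np.asarray(lat_t), waves, src)


@dataclass
class PeakRecoveryResult:
    latency_mae_ms: float
    latency_rmse_ms: float
    amplitude_rmse_uv: float
    cnn_raw_mae_ms: float
    n_eval: int
    n_train: int
    noise_sd_uv: float
    n_missing: int = 0


def run_peak_recovery(seed: int = 0, n_subjects: int = 90,
                      n_eval: int = 500, min_snr: float = 3.0,
                      max_epochs: int = 150) -> PeakRecoveryResult:
    """Train the peak regressor on synthetic data; score held-out subjects.

    Subjects are split 80/20/20 by subject; training waveforms are doubled
    with noise-injection augmentation (positional labels forbid warping or
    shifting copies); evaluation keeps the first ``n_eval`` held-out
    supra-threshold waveforms with wave-1 SNR at or above ``min_snr``.
    """
    cfg = SynthConfig(n_subjects=n_subjects, seed=seed)
    stacks, truth = generate_dataset(cfg)
    train_s, val_s, test_s = split_by_subject(stacks, SplitSpec(seed=seed))

    Xtr, ytr, _, _, _, _, _ = _supra_arrays(train_s, truth, cfg.noise_sd_uv)
    Xva, yva, _, _, _, _, _ = _supra_arrays(val_s, truth, cfg.noise_sd_uv)
    Xte, yte, snr, amp_t, lat_t, wte, _ = _supra_arrays(
        test_s, truth, cfg.noise_sd_uv)
    logger.info("peak recovery: %d train / %d val / %d test supra-threshold",
                len(Xtr), len(Xva), len(Xte))

    Xa = augment(Xtr, AugmentConfig(kinds=("noise",)),
                 rng=np.random.default_rng(seed))
    X = np.concatenate([Xtr, Xa])
    y = np.concatenate([ytr, ytr])

    model = PeakRegressor(PeakRegressorConfig(seed=seed,
                                              max_epochs=max_epochs))
    model.fit(X, y, Xva, yva)

    pred_idx = model.predict(Xte)
    dt = model.grid.dt_ms
    cnn_raw_mae = float(np.mean(np.abs(pred_idx - yte))) * dt

    sel = np.where(snr >= min_snr)[0][:n_eval]
    lat_p, amp_p, keep = [], [], []
    missing = 0
    for i in sel:
        ps = refine_peaks(wte[i], pred_idx[i])
        if ps.wave1_latency_ms is None:
            missing += 1
            continue
        lat_p.append(ps.wave1_latency_ms)
        amp_p.append(ps.wave1_amplitude_uv)
        keep.append(i)
    lat_rep = evaluate_peaks(lat_p, lat_t[keep], n_boot=0)
    amp_rep = evaluate_peaks(amp_p, amp_t[keep], n_boot=0)
    return PeakRecoveryResult(
        latency_mae_ms=lat_rep.mae, latency_rmse_ms=lat_rep.rmse,
        amplitude_rmse_uv=amp_rep.rmse, cnn_raw_mae_ms=cnn_raw_mae,
        n_eval=len(sel), n_train=len(X), noise_sd_uv=cfg.noise_sd_uv,
        n_missing=missing,
    )


@dataclass
class ThresholdRecoveryResult:
    within_5_db: float
    within_10_db: float
    within_15_db: float
    accuracy: float
    tpr: float
    fpr: float
    aucroc: float | None
    aucpr: float | None
    n_train_stacks: int
    n_eval_stacks: int
    n_eval_waveforms: int


def _stack_arrays(stacks, truth, family):
    X, y, src = [], [], []
    for s in stacks:
        thr = truth.thresholds[(s.subject_id, s.frequency_khz)]
        for row, w in zip(stack_features(s, family), s):
            X.append(row)
            y.append(int(w.level_db >= thr))
            src.append(w.source_label)
    return np.asarray(X), np.asarray(y), src


def run_threshold_recovery(seed: int = 0, family: str = "cnn",
                           n_train_subjects: int = 32,
                           n_eval_subjects: int = 20,
                           max_epochs: int = 40,
                           rule: str = "literal") -> ThresholdRecoveryResult:
    """Train a supra-threshold classifier; recover thresholds on fresh stacks.

    Training stacks come from one simulated cohort (subjects split
    train/val); evaluation stacks come from an independently seeded cohort,
    so no subject-level leakage is possible.  Per-waveform labels are
    "level at or above the stack's true threshold"; stack thresholds are
    read off the per-level calls with the configured rule.
    """
    cfg_train = SynthConfig(n_subjects=n_train_subjects, seed=seed)
    cfg_eval = SynthConfig(n_subjects=n_eval_subjects,
                           seed=seed + 100_003)
    stacks_tr, truth_tr = generate_dataset(cfg_train)
    stacks_ev, truth_ev = generate_dataset(cfg_eval)
    train_s, val_s, _ = split_by_subject(
        stacks_tr, SplitSpec(train_frac_subjects=0.9, seed=seed))

    X, y, src = _stack_arrays(train_s, truth_tr, family)
    Xv, yv, srcv = _stack_arrays(val_s, truth_tr, family)
    w, wv = source_balanced_weights(src), source_balanced_weights(srcv)
    X, y, w = augment_dataset(X, y, w, rng=np.random.default_rng(seed))
    logger.info("threshold recovery: %d train rows, %d val rows, "
                "%d eval stacks", len(X), len(Xv), len(stacks_ev))

    cfg = ThresholdClassifierConfig(family=family, seed=seed,
                                    max_epochs=max_epochs)
    model = make_classifier(cfg)
    model.fit(X, y, w, Xv, yv, wv)

    calls = batch_thresholds(stacks_ev, model, family=family, rule=rule)
    pred_thr = [c.threshold_db for c in calls]
    true_thr = [truth_ev.thresholds[(c.subject_id, c.frequency_khz)]
                for c in calls]

    scores, labels = [], []
    for c in calls:
        thr = truth_ev.thresholds[(c.subject_id, c.frequency_khz)]
        for lv, sc in zip(c.levels_db, c.scores):
            scores.append(sc)
            labels.append(int(lv >= thr))
    rep = evaluate_classifier(scores, labels, n_boot=0)

    return ThresholdRecoveryResult(
        within_5_db=within_k_db(pred_thr, true_thr, 5),
        within_10_db=within_k_db(pred_thr, true_thr, 10),
        within_15_db=within_k_db(pred_thr, true_thr, 15),
        accuracy=rep.accuracy, tpr=rep.tpr, fpr=rep.fpr,
        aucroc=rep.aucroc, aucpr=rep.aucpr,
        n_train_stacks=len(train_s), n_eval_stacks=len(calls),
        n_eval_waveforms=len(scores),
    )
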