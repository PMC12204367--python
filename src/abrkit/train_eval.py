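"""Dataset splitting, loss weighting, augmentation, early stopping, metrics.

Splits are always by subject, never by waveform: an animal's recordings
must not straddle the train/validation/test partitions, or evaluation
leaks subject-specific morphology.  When data come from several sources
(labs), splitting is done per source and per-sample loss weights equalize
each source's total contribution to the loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger("abrkit")


# ---------------------------------------------------------------------------
# Subject-level splitting
# ---------------------------------------------------------------------------

class HasSubjectAndSource(Protocol):
    subject_id: str

    @property
    def source_label(self) -> str: ...


@dataclass(frozen=True)
class SplitSpec:
    """Per-source 80/20 subject split, then 20% of the training subjects
    held out for validation."""

    train_frac_subjects: float = 0.8
    val_frac_of_train: float = 0.2
    seed: int = 0


def _counts(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    """(train, val, test) subject counts: round to nearest, min 1 each."""
    n_test = min(max(1, round((1 - spec.train_frac_subjects) * n)), n - 2)
    pool = n - n_test
    n_val = min(max(1, round(spec.val_frac_of_train * pool)), pool - 1)
    return pool - n_val, n_val, n_test


def split_by_subject(items: Sequence, spec: SplitSpec = SplitSpec()
                     ) -> tuple[list, list, list]:
    """Partition items (waveforms or stacks) into train/val/test by subject.

    Subjects are shuffled (seeded) and cut per source; every subject lands
    in exactly one partition.  A source with fewer than 3 subjects cannot
    populate three partitions and raises.
    """
    by_source: dict[str, list[str]] = {}
    for it in items:
        subs = by_source.setdefault(it.source_label, [])
        if it.subject_id not in subs:
            subs.append(it.subject_id)

    rng = np.random.default_rng(spec.seed)
    assignment: dict[str, str] = {}
    for source in sorted(by_source):
        subjects = sorted(by_source[source])
        if len(subjects) < 3:
            raise ValueError(
                f"source {source!r} has {len(subjects)} subjects; "
                "at least 3 are needed for train/val/test"
            )
        rng.shuffle(subjects)
        n_train, n_val, n_test = _counts(len(subjects), spec)
        for s in subjects[:n_train]:
            assignment[s] = "train"
        for s in subjects[n_train:n_train + n_val]:
            assignment[s] = "val"
        for s in subjects[n_train + n_val:]:
            assignment[s] = "test"

    train = [it for it in items if assignment[it.subject_id] == "train"]
    val = [it for it in items if assignment[it.subject_id] == "val"]
    test = [it for it in items if assignment[it.subject_id] == "test"]
    return train, val, test


def source_balanced_weights(source_labels: Sequence[str]) -> np.ndarray:
    """Per-sample loss weights equalizing each source's total contribution.

    ``w_i = N / (S * n_source(i))`` with N samples and S sources, so every
    source's weights sum to N/S and all weights sum to N.
    """
    labels = np.asarray(source_labels)
    if labels.size == 0:
        raise ValueError("no samples")
    sources, counts = np.unique(labels, return_counts=True)
    n, s = labels.size, len(sources)
    per_source = {src: n / (s * c) for src, c in zip(sources, counts)}
    return np.array([per_source[l] for l in labels], dtype=float)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """One augmented copy per original, kind drawn uniformly per sample.

    Magnitudes are expressed on the scaled [0, 1] waveforms: additive noise
    sd, elastic control-point jitter in samples, and maximum time shift in
    samples.
    """

    kinds: tuple[str, ...] = ("noise", "elastic", "shift")
    noise_sd: float = 0.02
    elastic_jitter_samples: float = 2.0
    elastic_control_points: int = 8
    shift_max_samples: int = 3


def _elastic_warp(x: np.ndarray, jitter: float, n_cp: int,
                  rng: np.random.Generator) -> np.ndarray:
    L = len(x)
    cp = np.linspace(0, L - 1, n_cp)
    moved = cp.copy()
    moved[1:-1] += rng.uniform(-jitter, jitter, size=n_cp - 2)
    moved = np.maximum.accumulate(np.clip(moved, 0, L - 1))
    warped_t = CubicSpline(cp, moved)(np.arange(L))
    return np.interp(np.clip(warped_t, 0, L - 1), np.arange(L), x)


def _shift(x: np.ndarray, k: int) -> np.ndarray:
    if k == 0:
        return x.copy()
    out = np.empty_like(x)
    if k > 0:
        out[k:] = x[:-k]
        out[:k] = x[0]
    else:
        out[:k] = x[-k:]
        out[k:] = x[-1]
    return out


def augment(X: np.ndarray, cfg: AugmentConfig = AugmentConfig(),
            rng: np.random.Generator | int = 0) -> np.ndarray:
    """Produce exactly one augmented copy per input row.

    The caller concatenates originals and copies (doubling the training
    matrix) and tiles labels/weights alongside.  With all magnitudes zero
    the copies equal the originals.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    out = np.empty_like(X)
    kinds = rng.choice(len(cfg.kinds), size=len(X))
    for i, (row, ki) in enumerate(zip(X, kinds)):
        kind = cfg.kinds[ki]
        if kind == "noise":
            out[i] = row + rng.normal(0.0, cfg.noise_sd, size=len(row))
        elif kind == "elastic":
            out[i] = _elastic_warp(row, cfg.elastic_jitter_samples,
                                   cfg.elastic_control_points, rng)
        elif kind == "shift":
            k = int(rng.integers(-cfg.shift_max_samples,
                                 cfg.shift_max_samples + 1))
            out[i] = _shift(row, k)
        else:
            raise ValueError(f"unknown augmentation kind {kind!r}")
    return out


def augment_dataset(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                    cfg: AugmentConfig = AugmentConfig(),
                    rng: np.random.Generator | int = 0
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Double the training matrix: originals plus one augmented copy each."""
    Xa = augment(X, cfg, rng)
    return (np.concatenate([X, Xa]), np.concatenate([y, y]),
            np.concatenate([w, w]))


# ---------------------------------------------------------------------------
# Early stopping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EarlyStopSpec:
    """Halt when the validation loss fails to decrease for ``patience``
    consecutive epochs; the best epoch's weights are restored."""

    patience: int = 25
    max_epochs: int = 500

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class EarlyStopper:
    """Tracks validation loss; strict decrease counts as improvement."""

    def __init__(self, patience: int = 25) -> None:
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = math.inf
        self.best_epoch = 0            # 1-based
        self.epoch = 0
        self._since_improve = 0

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; True if it improved."""
        self.epoch += 1
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = self.epoch
            self._since_improve = 0
            return True
        self._since_improve += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self._since_improve >= self.patience


class EpochTrainable(Protocol):
    """Protocol for models driven by :func:`fit_with_early_stopping`."""

    def train_epoch(self, train) -> float: ...
    def val_loss(self, val) -> float: ...
    def snapshot(self): ...
    def restore(self, state) -> None: ...


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


def fit_with_early_stopping(model: EpochTrainable, train, val,
                            spec: EarlyStopSpec = EarlyStopSpec()
                            ) -> tuple[EpochTrainable, TrainHistory]:
    """Drive any epoch-trainable model with patience-based early stopping.

    Stops at the first epoch with ``spec.patience`` consecutive
    non-improving validation losses (or at ``max_epochs``); restores the
    best epoch's snapshot before returning.
    """
    stopper = EarlyStopper(spec.patience)
    history = TrainHistory()
    best_state = model.snapshot()
    for _ in range(spec.max_epochs):
        tl = model.train_epoch(train)
        vl = model.val_loss(val)
        if not (math.isfinite(tl) and math.isfinite(vl)):
            raise RuntimeError(
                f"non-finite loss at epoch {stopper.epoch + 1}: "
                f"train={tl}, val={vl}"
            )
        history.train_loss.append(tl)
        history.val_loss.append(vl)
        if stopper.update(vl):
            best_state = model.snapshot()
        if stopper.should_stop:
            break
    history.best_epoch = stopper.best_epoch
    history.stopped_epoch = stopper.epoch
    model.restore(best_state)
    return model, history


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Classifier and/or regression metrics with bootstrap CIs.

    Rates are at the stated operating point; AUCs are threshold-free
    (trapezoidal ROC, step-integrated precision-recall).  ``ci`` maps
    metric name to a (lo, hi) percentile bootstrap interval.
    """

    accuracy: float | None = None
    tpr: float | None = None
    fpr: float | None = None
    tnr: float | None = None
    aucroc: float | None = None
    aucpr: float | None = None
    rmse: float | None = None
    mae: float | None = None
    mean_error: float | None = None
    sem: float | None = None
    within_k_db: dict[int, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {}
        for name in ("accuracy", "tpr", "fpr", "tnr", "aucroc", "aucpr",
                     "rmse", "mae", "mean_error", "sem"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        for k, v in self.within_k_db.items():
            out[f"within_{k}_db"] = v
        for k, (lo, hi) in self.ci.items():
            out[f"{k}_ci"] = [lo, hi]
        return out


def _rates(scores: np.ndarray, labels: np.ndarray,
           op: float) -> tuple[float, float, float, float]:
    calls = scores >= op
    pos, neg = labels == 1, labels == 0
    accuracy = float(np.mean(calls == labels))
    tpr = float(np.mean(calls[pos])) if pos.any() else float("nan")
    fpr = float(np.mean(calls[neg])) if neg.any() else float("nan")
    return accuracy, tpr, fpr, 1.0 - fpr


def evaluate_classifier(scores: Sequence[float], labels: Sequence[int],
                        operating_point: float = 0.5, n_boot: int = 2000,
                        seed: int = 0) -> EvalReport:
    """Accuracy/TPR/FPR/TNR at the operating point plus AUCROC and AUCPR.

    AUCs are undefined (None) for a single-class label vector.  Percentile
    bootstrap CIs (seeded, ``n_boot`` resamples; 0 disables) are attached
    for each defined metric.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")

    report = EvalReport()
    report.accuracy, report.tpr, report.fpr, report.tnr = _rates(
        scores, labels, operating_point
    )
    two_class = len(np.unique(labels)) == 2
    if two_class:
        report.aucroc = float(roc_auc_score(labels, scores))
        report.aucpr = float(average_precision_score(labels, scores))
    else:
        logger.warning("single-class labels: AUCROC/AUCPR undefined")

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot: dict[str, list[float]] = {k: [] for k in
                                        ("accuracy", "tpr", "fpr", "aucroc", "aucpr")}
        n = len(scores)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            s, l = scores[idx], labels[idx]
            a, tp, fp, _ = _rates(s, l, operating_point)
            boot["accuracy"].append(a)
            boot["tpr"].append(tp)
            boot["fpr"].append(fp)
            if len(np.unique(l)) == 2:
                boot["aucroc"].append(float(roc_auc_score(l, s)))
                boot["aucpr"].append(float(average_precision_score(l, s)))
        for k, vals in boot.items():
            vals = np.asarray(vals, dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) and getattr(report, k) is not None:
                report.ci[k] = (float(np.percentile(vals, 2.5)),
                                float(np.percentile(vals, 97.5)))
    return report


def evaluate_peaks(pred: Sequence[float], truth: Sequence[float],
                   n_boot: int = 2000, seed: int = 0) -> EvalReport:
    """RMSE, MAE and mean signed error (+-SEM) of paired peak metrics."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth length mismatch")
    err = pred - truth
    report = EvalReport(
        rmse=float(np.sqrt(np.mean(err ** 2))),
        mae=float(np.mean(np.abs(err))),
        mean_error=float(np.mean(err)),
        sem=float(np.std(err, ddof=1) / np.sqrt(len(err))) if len(err) > 1 else 0.0,
    )
    if n_boot > 0 and len(err) > 1:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(err), size=(n_boot, len(err)))
        res = err[idx]
        rmses = np.sqrt(np.mean(res ** 2, axis=1))
        maes = np.mean(np.abs(res), axis=1)
        report.ci["rmse"] = (float(np.percentile(rmses, 2.5)),
                             float(np.percentile(rmses, 97.5)))
        report.ci["mae"] = (float(np.percentile(maes, 2.5)),
                            float(np.percentile(maes, 97.5)))
    return report


def within_k_db(pred: Sequence[float | None], truth: Sequence[float | None],
                k: float) -> float:
    """Fraction of threshold pairs within k dB.

    ``None`` encodes "no response": a pair where both are no-response is a
    hit, a pair where only one is counts as a miss; the number of such
    pairs is logged.
    """
    if len(pred) != len(truth):
        raise ValueError("pred and truth length mismatch")
    if not pred:
        raise ValueError("empty threshold vectors")
    hits = 0
    n_nr = 0
    for p, t in zip(pred, truth):
        if p is None or t is None:
            n_nr += 1
            hits += p is None and t is None
        else:
            hits += abs(p - t) <= k
    if n_nr:
        logger.info("within_k_db: %d pair(s) involved a no-response call", n_nr)
    return hits / len(pred)


@dataclass(frozen=True)
class ProportionComparison:
    difference: float
    ci: tuple[float, float]
    z: float
    p_value: float


def compare_proportions(hits1: int, n1: int, hits2: int, n2: int,
                        bonferroni_m: int = 1, alpha: float = 0.05
                        ) -> ProportionComparison:
    """Two-sample z-test on proportions with an unpooled difference CI.

    ``bonferroni_m`` multiplies the p-value (capped at 1) for multiple
    comparisons.  Degenerate pooled proportions (0 or 1) yield z = 0,
    p = 1 and a collapsed CI.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    p1, p2 = hits1 / n1, hits2 / n2
    diff = p1 - p2
    pooled = (hits1 + hits2) / (n1 + n2)
    if pooled in (0.0, 1.0) or p1 == p2:
        z_stat, p_val = 0.0, 1.0
    else:
        z_stat, p_val = proportions_ztest([hits1, hits2], [n1, n2])
        z_stat, p_val = float(z_stat), float(p_val)
    from scipy.stats import norm
    zc = norm.ppf(1 - alpha / 2)
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    p_val = min(1.0, p_val * bonferroni_m)
    return ProportionComparison(
        difference=diff, ci=(diff - zc * se, diff + zc * se),
        z=z_stat, p_value=p_val,
    )
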