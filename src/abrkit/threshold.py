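"""Supra/sub-threshold classification and the stack-level threshold rule.

A binary classifier scores each waveform of a stack as containing a
hearing response (positive class, "above threshold") or noise only.  The
hearing threshold for the stack is then the quietest stimulus level whose
waveform is classified as a response; if no level is, the stack is called
"no-response".

Three classifier families are supported, all consuming the 244 stack-scaled
voltages as their only features (stimulus level and frequency are withheld
to avoid label leakage):

* a 1-D CNN (three conv blocks, two dense layers, sigmoid head) on the
  stack-scaled traces;
* gradient-boosted trees (XGBoost) and logistic regression, both on
  time-warp-aligned stack-scaled traces, where alignment removes the
  level-dependent latency shift those flat feature views cannot model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .core_io import CANONICAL_GRID, SamplingGrid, Stack, Waveform
from .timewarp import AlignConfig, align_stack
from .preprocess import scale_per_stack

logger = logging.getLogger("abrkit")

FAMILIES = ("cnn", "xgb", "logreg")


@dataclass(frozen=True)
class ThresholdClassifierConfig:
    """Hyperparameters for the three classifier families.

    The CNN head is a sigmoid and the operating point on the resulting
    score defaults to 0.5 (configurable; a lower point trades false
    negatives near threshold for false positives).
    """

    family: str = "cnn"
    # CNN
    channels: tuple[int, int, int] = (16, 32, 64)
    kernels: tuple[int, int, int] = (9, 5, 3)
    pool: int = 2
    dropout: float = 0.25
    fc_hidden: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 120
    patience_epochs: int = 25
    # trees
    n_estimators: int = 300
    max_depth: int = 4
    tree_learning_rate: float = 0.1
    # logistic
    l2_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")


class _CNNClassifier:
    """Three conv blocks + two dense layers + sigmoid, trained with
    sample-weighted binary cross-entropy."""

    def __init__(self, cfg: ThresholdClassifierConfig,
                 grid: SamplingGrid = CANONICAL_GRID) -> None:
        self.cfg = cfg
        self.grid = grid
        self.net: nn.Sequential | None = None
        self.history: nn.FitHistory | None = None

    def _build(self, rng: np.random.Generator) -> nn.Sequential:
        cfg = self.cfg
        length = self.grid.n_points
        layers: list[nn.Layer] = []
        c_in = 1
        for c_out, k in zip(cfg.channels, cfg.kernels):
            layers += [
                nn.Conv1d(c_in, c_out, k, rng),
                nn.BatchNorm1d(c_out),
                nn.ReLU(),
                nn.MaxPool1d(cfg.pool),
                nn.Dropout(cfg.dropout, rng),
            ]
            c_in = c_out
            length //= cfg.pool
        layers += [
            nn.Flatten(),
            nn.Dense(c_in * length, cfg.fc_hidden, rng),
            nn.ReLU(),
            nn.Dense(cfg.fc_hidden, 1, rng),  # logits; sigmoid applied in predict
        ]
        return nn.Sequential(layers)

    def fit(self, X, y, w, X_val, y_val, w_val) -> None:
        rng = np.random.default_rng(self.cfg.seed)
        self.net = self._build(rng)
        self.history = nn.fit(
            self.net, nn.weighted_bce_logits,
            np.asarray(X)[:, None, :], np.asarray(y, dtype=float), np.asarray(w),
            np.asarray(X_val)[:, None, :], np.asarray(y_val, dtype=float),
            np.asarray(w_val),
            lr=self.cfg.learning_rate, batch_size=self.cfg.batch_size,
            max_epochs=self.cfg.max_epochs, patience=self.cfg.patience_epochs,
            rng=rng,
        )

    def predict_scores(self, X) -> np.ndarray:
        if self.net is None:
            raise RuntimeError("classifier is not fitted")
        logits = self.net.forward(
            np.asarray(X, dtype=np.float32)[:, None, :], train=False
        ).ravel()
        return nn.sigmoid(logits)


class _XGBClassifier:
    def __init__(self, cfg: ThresholdClassifierConfig) -> None:
        self.cfg = cfg
        self.model = None

    def fit(self, X, y, w, X_val, y_val, w_val) -> None:
        import xgboost as xgb
        self.model = xgb.XGBClassifier(
            n_estimators=self.cfg.n_estimators, max_depth=self.cfg.max_depth,
            learning_rate=self.cfg.tree_learning_rate,
            random_state=self.cfg.seed, n_jobs=1,
            eval_metric="logloss",
        )
        self.model.fit(X, y, sample_weight=w,
                       eval_set=[(X_val, y_val)],
                       sample_weight_eval_set=[w_val], verbose=False)

    def predict_scores(self, X) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        return self.model.predict_proba(X)[:, 1]


class _LogisticClassifier:
    def __init__(self, cfg: ThresholdClassifierConfig) -> None:
        self.cfg = cfg
        self.model = None

    def fit(self, X, y, w, X_val, y_val, w_val) -> None:
        from sklearn.linear_model import LogisticRegression
        self.model = LogisticRegression(
            C=self.cfg.l2_c, max_iter=2000, random_state=self.cfg.seed,
        )
        self.model.fit(X, y, sample_weight=w)

    def predict_scores(self, X) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        return self.model.predict_proba(X)[:, 1]


def make_classifier(cfg: ThresholdClassifierConfig = ThresholdClassifierConfig()):
    """Instantiate the configured classifier family."""
    if cfg.family == "cnn":
        return _CNNClassifier(cfg)
    if cfg.family == "xgb":
        return _XGBClassifier(cfg)
    return _LogisticClassifier(cfg)


def stack_features(s: Stack, family: str = "cnn",
                   align_cfg: AlignConfig = AlignConfig()) -> np.ndarray:
    """Per-family preprocessing of one stack into a (n_levels, 244) matrix.

    The CNN consumes unaligned stack-scaled traces; trees and logistic
    regression consume time-warp-aligned then stack-scaled traces.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if family in ("xgb", "logreg") and len(s) >= 2:
        s, _ = align_stack(s, align_cfg)
    scaled = scale_per_stack(s)
    return np.stack([w.voltages for w in scaled])


def classify_waveform(model, w: Waveform) -> float:
    """Score one preprocessed waveform; 1 = confident hearing response."""
    score = float(model.predict_scores(np.asarray(w.voltages)[None, :])[0])
    if not 0 <= score <= 1:
        raise ValueError(f"classifier returned a score outside [0,1]: {score}")
    return score


# ---------------------------------------------------------------------------
# Stack-level threshold rule
# ---------------------------------------------------------------------------

@dataclass
class ThresholdCall:
    """Per-stack threshold estimate with the per-level evidence behind it.

    ``threshold_db is None`` encodes "no-response".
    """

    subject_id: str
    frequency_khz: float
    levels_db: list[float]
    scores: list[float]
    calls: list[bool]
    threshold_db: float | None


def estimate_threshold(levels_db: Sequence[float], calls: Sequence[bool],
                       mode: str = "literal") -> float | None:
    """Apply the threshold rule to per-level binary calls.

    ``literal`` (default) returns the quietest level with a positive call.
    ``contiguous`` returns the quietest level such that it and every louder
    level are positive, which is robust to isolated false positives deep
    below threshold.  All-negative calls give None ("no-response");
    all-positive give the quietest tested level.
    """
    if len(levels_db) == 0:
        raise ValueError("empty stack")
    if len(levels_db) != len(calls):
        raise ValueError("one call per level is required")
    order = np.argsort(levels_db)[::-1]  # loudest first
    lv = [float(levels_db[i]) for i in order]
    cl = [bool(calls[i]) for i in order]
    if mode == "literal":
        positives = [l for l, c in zip(lv, cl) if c]
        return min(positives) if positives else None
    if mode == "contiguous":
        thr: float | None = None
        for l, c in zip(lv, cl):
            if not c:
                break
            thr = l
        return thr
    raise ValueError(f"unknown threshold rule {mode!r}")


def batch_thresholds(stacks: Sequence[Stack], model,
                     family: str = "cnn", rule: str = "literal",
                     operating_point: float = 0.5,
                     align_cfg: AlignConfig = AlignConfig()
                     ) -> list[ThresholdCall]:
    """Score every stack and apply the threshold rule; failures are isolated.

    A stack that raises during preprocessing or scoring is logged and
    skipped so a long batch run survives one corrupt stack.
    """
    out: list[ThresholdCall] = []
    for s in stacks:
        try:
            X = stack_features(s, family, align_cfg)
            scores = model.predict_scores(X)
            calls = scores >= operating_point
            thr = estimate_threshold(s.levels_db, calls, mode=rule)
            out.append(ThresholdCall(
                subject_id=s.subject_id, frequency_khz=s.frequency_khz,
                levels_db=list(s.levels_db), scores=[float(x) for x in scores],
                calls=[bool(c) for c in calls], threshold_db=thr,
            ))
        except Exception:
            logger.exception(
                "stack (%s, %s kHz) failed; continuing batch",
                s.subject_id, s.frequency_khz,
            )
    return out
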