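"""Elastic time warping: align peaks/troughs across a stack.

Alignment is landmark-guided piecewise-linear warping: detected peaks of
each waveform are matched, in time order, to the peaks of a reference
waveform (by default the loudest level, where the response is cleanest),
and a monotone piecewise-linear map of the time axis carries each waveform
onto the reference's landmark positions.  When landmarks cannot be
detected on both curves, a dynamic-time-warping fallback produces the
monotone map instead; sub-threshold (landmark-free) and flat waveforms
receive the identity warp.

Warping reparameterizes time only — voltages are re-evaluated by linear
interpolation at the warped times — so amplitudes are preserved up to
interpolation error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core_io import Stack, Waveform
from .preprocess import SmoothingConfig, gaussian_smooth

logger = logging.getLogger("abrkit")


@dataclass
class WarpFunction:
    """Monotone map of the time axis, as source sample positions per output
    sample: ``aligned[i] = w(values[i])`` by linear interpolation.

    Endpoints are fixed (``values[0] = 0``, ``values[-1] = n-1``) and the
    map is non-decreasing, so features are shifted and stretched but never
    reordered.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 2:
            raise ValueError("warp needs at least 2 samples")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("warp must be non-decreasing")
        n = len(self.values)
        if not (abs(self.values[0]) < 1e-9 and abs(self.values[-1] - (n - 1)) < 1e-9):
            raise ValueError("warp endpoints must be fixed")

    @classmethod
    def identity(cls, n: int) -> "WarpFunction":
        return cls(np.arange(n, dtype=float))

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.values, np.arange(len(self.values)), atol=tol))

    def apply(self, voltages: np.ndarray) -> np.ndarray:
        x = np.arange(len(voltages))
        return np.interp(self.values, x, np.asarray(voltages, dtype=float))


def _landmarks(voltages: np.ndarray, smoothing: SmoothingConfig,
               min_sep: int, max_landmarks: int,
               min_prominence: float) -> np.ndarray:
    """Prominent smoothed peaks; ``min_prominence`` is absolute (uV), keyed
    to the reference waveform's span so noise-only members yield none."""
    sm = gaussian_smooth(voltages, smoothing)
    if sm.max() - sm.min() == 0 or min_prominence <= 0:
        return np.array([], dtype=int)
    peaks, props = find_peaks(sm, distance=min_sep,
                              prominence=min_prominence)
    if len(peaks) > max_landmarks:
        keep = np.sort(np.argsort(props["prominences"])[-max_landmarks:])
        peaks = peaks[keep]
    return peaks


def _landmark_warp(n: int, src_landmarks: np.ndarray,
                   ref_landmarks: np.ndarray) -> WarpFunction | None:
    """Piecewise-linear map sending reference landmark times to source ones."""
    m = min(len(src_landmarks), len(ref_landmarks))
    if m == 0:
        return None
    xp = np.concatenate([[0.0], ref_landmarks[:m], [n - 1.0]])
    fp = np.concatenate([[0.0], src_landmarks[:m], [n - 1.0]])
    if np.any(np.diff(xp) <= 0) or np.any(np.diff(fp) < 0):
        return None  # crossing landmarks: fall back to DTW
    return WarpFunction(np.interp(np.arange(n), xp, fp))


def _dtw_warp(src: np.ndarray, ref: np.ndarray) -> WarpFunction:
    """Classic O(n^2) dynamic time warping on z-scored curves.

    The optimal path is collapsed to a function by averaging the source
    indices matched to each reference index, then made monotone with fixed
    endpoints.
    """

    def z(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    a, b = z(ref), z(src)
    n, m = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    acc[0, 1:] = np.cumsum(cost[0, 1:]) + cost[0, 0]
    acc[1:, 0] = np.cumsum(cost[1:, 0]) + cost[0, 0]
    for i in range(1, n):
        prev, cur = acc[i - 1], acc[i]
        for j in range(1, m):
            cur[j] = cost[i, j] + min(prev[j], prev[j - 1], cur[j - 1])
    # backtrack
    i, j = n - 1, m - 1
    matched: list[list[int]] = [[] for _ in range(n)]
    matched[i].append(j)
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            step = np.argmin([acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]])
            if step == 0:
                i, j = i - 1, j - 1
            elif step == 1:
                i -= 1
            else:
                j -= 1
        matched[i].append(j)
    gamma = np.array([np.mean(js) for js in matched])
    gamma = np.maximum.accumulate(gamma)
    gamma[0], gamma[-1] = 0.0, m - 1.0
    return WarpFunction(gamma)


@dataclass(frozen=True)
class AlignConfig:
    smoothing: SmoothingConfig = SmoothingConfig(sigma_samples=1.0)
    min_landmark_sep_samples: int = 16
    max_landmarks: int = 5
    min_prominence_frac: float = 0.10
    use_dtw_fallback: bool = True


def align_stack(s: Stack, cfg: AlignConfig = AlignConfig(),
                reference: int = 0) -> tuple[Stack, list[WarpFunction]]:
    """Align every waveform of a stack to a reference (default: loudest).

    Returns the aligned stack and one audit :class:`WarpFunction` per
    waveform (identity for the reference).  Flat or landmark-free
    waveforms — typically sub-threshold, noise-only recordings — keep the
    identity warp.
    """
    if len(s) < 2:
        raise ValueError("alignment needs at least 2 waveforms")
    n = s.waveforms[0].n_samples
    for w in s:
        if w.n_samples != n:
            raise ValueError("all waveforms must share one grid for alignment")

    ref_w = s.waveforms[reference]
    # prominence cut is a fraction of the REFERENCE span, so quiet noise-only
    # members of the stack do not sprout spurious landmarks
    prominence = cfg.min_prominence_frac * float(
        np.ptp(gaussian_smooth(ref_w.voltages, cfg.smoothing)))
    ref_lm = _landmarks(ref_w.voltages, cfg.smoothing,
                        cfg.min_landmark_sep_samples, cfg.max_landmarks,
                        prominence)

    warps: list[WarpFunction] = []
    aligned: list[Waveform] = []
    for i, w in enumerate(s):
        if i == reference:
            warp = WarpFunction.identity(n)
        else:
            span = w.voltages.max() - w.voltages.min()
            lm = _landmarks(w.voltages, cfg.smoothing,
                            cfg.min_landmark_sep_samples, cfg.max_landmarks,
                            prominence)
            if span == 0:
                logger.warning(
                    "flat waveform %s: identity warp", w.key()
                )
                warp = WarpFunction.identity(n)
            elif len(lm) == 0 or len(ref_lm) == 0:
                # landmark-free (typically sub-threshold) on either side:
                # nothing reliable to align, keep the time axis untouched
                warp = WarpFunction.identity(n)
            else:
                warp = _landmark_warp(n, lm, ref_lm)
                if warp is None:
                    warp = (_dtw_warp(w.voltages, ref_w.voltages)
                            if cfg.use_dtw_fallback
                            else WarpFunction.identity(n))
        warps.append(warp)
        aligned.append(w.replace(voltages=warp.apply(w.voltages)))
    return s.replace_waveforms(aligned), warps
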