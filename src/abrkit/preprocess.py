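"""Resampling to the canonical grid, waveform/stack scaling, Gaussian smoothing.

All models consume waveforms on the canonical 244-point / 10 ms grid.
Recordings sampled differently are truncated to the window and resampled:
piecewise-linear interpolation when downsampling, a natural cubic spline
when upsampling.  Two scaling schemes feed the two model families: a
per-waveform z-score + min-max rescale (peak finding) and a pooled
per-stack z-score + min-max rescale (threshold classification), both
mapping onto [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .core_io import CANONICAL_GRID, SamplingGrid, Stack, Waveform

logger = logging.getLogger("abrkit")


@dataclass(frozen=True)
class SmoothingConfig:
    """Gaussian smoothing kernel: ``sigma_samples`` wide, truncated at
    ``kernel_truncation`` sigmas and renormalized to sum 1."""

    sigma_samples: float = 1.0
    kernel_truncation: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma_samples <= 0:
            raise ValueError("sigma_samples must be positive")
        if self.kernel_truncation <= 0:
            raise ValueError("kernel_truncation must be positive")


def resample_to_grid(w: Waveform, grid: SamplingGrid = CANONICAL_GRID) -> Waveform:
    """Resample a waveform onto the canonical grid.

    Samples beyond the grid window are dropped first.  A trace with more
    native samples than the grid is downsampled by piecewise-linear
    interpolation; one with fewer is upsampled with a natural cubic spline;
    one already at the grid length is returned unchanged.  Both branches
    reproduce polynomials of degree <= 1 exactly.

    Raises
    ------
    ValueError
        If fewer than 4 samples remain (the cubic spline is underdetermined).
    """
    times = w.native_times_ms()
    volts = w.voltages
    keep = times <= grid.window_ms
    times, volts = times[keep], volts[keep]
    if len(volts) < 4:
        raise ValueError(
            f"waveform {w.key()}: fewer than 4 samples within the "
            f"{grid.window_ms} ms window"
        )
    if len(volts) == grid.n_points:
        return w.replace(voltages=volts, times_ms=None, grid=grid)

    target = grid.times_ms()
    if len(volts) > grid.n_points:
        out = np.interp(target, times, volts)
    else:
        out = CubicSpline(times, volts, bc_type="natural")(target)
        # spline may be evaluated slightly beyond the last native sample;
        # natural extrapolation is linear there, which is what we want for
        # the degree-<=1 exactness contract.
    return w.replace(voltages=out, times_ms=None, grid=grid)


def _z_then_minmax(values: np.ndarray, what: str) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        logger.warning("constant %s: scaling degenerates, returning all 0.5", what)
        return np.full_like(values, 0.5, dtype=float)
    z = (values - values.mean()) / sd
    return (z - z.min()) / (z.max() - z.min())


def scale_per_waveform(w: Waveform) -> Waveform:
    """Z-score the waveform across timepoints, then min-max onto [0, 1].

    The composition is a strictly increasing affine map, so sample ordering
    is preserved and the result is invariant to affine transforms of the
    input.  A constant (zero-variance) waveform maps to all 0.5 with a
    logged warning rather than erroring mid-batch.
    """
    return w.replace(voltages=_z_then_minmax(w.voltages, f"waveform {w.key()}"))


def scale_per_stack(s: Stack) -> Stack:
    """Pooled z-score over every sample in the stack, then min-max onto [0, 1].

    One affine map is applied to all member waveforms, so relative
    amplitudes across levels are preserved: the pooled minimum maps to 0 and
    the pooled maximum to 1.
    """
    pooled = np.concatenate([w.voltages for w in s.waveforms])
    sd = pooled.std()
    if sd == 0:
        logger.warning(
            "constant stack (%s, %s): scaling degenerates, returning all 0.5",
            s.subject_id, s.frequency_khz,
        )
        return s.replace_waveforms(
            [w.replace(voltages=np.full_like(w.voltages, 0.5, dtype=float))
             for w in s.waveforms]
        )
    mean = pooled.mean()
    z_min = (pooled.min() - mean) / sd
    z_max = (pooled.max() - mean) / sd
    span = z_max - z_min
    out = [
        w.replace(voltages=((w.voltages - mean) / sd - z_min) / span)
        for w in s.waveforms
    ]
    return s.replace_waveforms(out)


def gaussian_smooth(voltages: np.ndarray,
                    cfg: SmoothingConfig = SmoothingConfig()) -> np.ndarray:
    """Convolve with a normalized truncated Gaussian kernel.

    Reflect padding at the boundaries; output length equals input length.
    Because the kernel sums to 1, constants pass through unchanged and
    smoothing commutes with constant offsets.
    """
    voltages = np.asarray(voltages, dtype=float)
    if voltages.ndim != 1 or len(voltages) < 1:
        raise ValueError("voltages must be a non-empty 1-D sequence")
    return gaussian_filter1d(
        voltages, sigma=cfg.sigma_samples, mode="reflect",
        truncate=cfg.kernel_truncation,
    )
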