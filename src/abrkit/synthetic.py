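"""Seeded generator of synthetic ABR stacks with ground truth.

The generator emulates the phenomenology the analysis models must learn
from real rodent recordings:

* five biphasic waves (positive Gaussian lobe followed ~0.3 ms later by a
  negative lobe) whose amplitudes grow sigmoidally with stimulus level
  above a per-stack hearing threshold and whose latencies shorten as the
  level rises;
* below the threshold, recordings contain additive Gaussian noise only;
* per-subject random effects on latency and amplitude so that subject-level
  train/test splits are meaningful;
* optionally several recording "sources" with different native sampling
  rates, to exercise resampling and per-source loss weighting.

Wave latencies are quantized to the canonical sampling grid so that
ground-truth peak indices are well defined at the sample level.  Truth peak
and trough indices are read off the noise-free trace (argmax/argmin in a
small window around the nominal latency), so the truth is always consistent
with the rendered signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import CANONICAL_GRID, SamplingGrid, Stack, Waveform


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the simulator.

    Defaults describe a typical murine ABR protocol: levels from 90 down to
    10 dB in 5 dB steps, five waves with base latencies ~1.5-5.3 ms at 90 dB
    that lengthen by 0.01 ms per dB of attenuation, peak amplitudes of a few
    uV that grow sigmoidally above a per-stack threshold drawn from
    [20, 55] dB, and 0.2 uV RMS recording noise.
    """

    n_subjects: int = 10
    frequencies_khz: Sequence[float] = (8.0, 16.0, 32.0)
    levels_db: Sequence[float] = tuple(range(90, 5, -5))
    wave_latencies_ms: Sequence[float] = (1.5, 2.5, 3.4, 4.4, 5.3)
    latency_shift_per_db: float = -0.01   # ms per dB: latency shortens as level rises
    amp_max_uv: Sequence[float] = (3.0, 1.8, 2.2, 1.4, 1.0)
    amp_growth_slope: float = 0.1         # 1/dB, sigmoidal growth above threshold
    threshold_range_db: tuple[float, float] = (20.0, 55.0)
    threshold_step_db: float = 5.0        # thresholds drawn on this grid
    noise_sd_uv: float = 0.2
    lobe_sigma_ms: float = 0.15           # width of the positive lobe
    trough_delay_ms: float = 0.30         # negative lobe lag behind the peak
    trough_ratio: float = 0.7             # negative lobe depth / positive lobe height
    trough_sigma_ms: float = 0.18
    subject_latency_jitter: float = 0.10  # +-10% per-subject latency scaling
    subject_amp_jitter: float = 0.20      # +-20% per-subject amplitude scaling
    freq_latency_offset_ms_per_octave: float = -0.08  # re 16 kHz
    source_n_points: Mapping[str, int] = field(
        default_factory=lambda: {"sim": 244}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.levels_db or not self.frequencies_khz:
            raise ValueError("levels_db and frequencies_khz must be non-empty")
        if list(self.levels_db) != sorted(self.levels_db, reverse=True):
            raise ValueError("levels_db must be sorted descending")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")
        lo, hi = self.threshold_range_db
        if not (min(self.levels_db) <= lo <= hi <= max(self.levels_db)):
            raise ValueError("threshold range must lie within the level range")
        if len(self.wave_latencies_ms) != 5 or len(self.amp_max_uv) != 5:
            raise ValueError("five waves are required")


@dataclass
class WaveTruth:
    """Ground truth for one supra-threshold waveform (canonical grid)."""

    peak_idx: list[int]        # 5 sample indices of wave 1-5 peaks
    trough_idx: list[int]      # 5 sample indices of the following troughs
    peak_uv: list[float]       # noise-free voltages at the peaks
    trough_uv: list[float]
    above_threshold: bool

    @property
    def wave1_latency_ms(self) -> float:
        return self.peak_idx[0] * CANONICAL_GRID.dt_ms

    @property
    def wave1_amplitude_uv(self) -> float:
        return self.peak_uv[0] - self.trough_uv[0]


@dataclass
class SyntheticTruth:
    """Ground truth for a generated dataset.

    ``waves[(subject, freq, level)]`` is a :class:`WaveTruth` (peak/trough
    entries are empty lists for sub-threshold waveforms); ``thresholds``
    maps (subject, freq) to the true per-stack hearing threshold in dB.
    """

    waves: dict[tuple[str, float, float], WaveTruth] = field(default_factory=dict)
    thresholds: dict[tuple[str, float], float] = field(default_factory=dict)


@dataclass(frozen=True)
class _SubjectEffects:
    latency_factor: float
    amp_factor: float
    source_label: str
    n_points: int


def _subject_effects(cfg: SynthConfig, subject_index: int) -> _SubjectEffects:
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 1000 + subject_index])
    )
    sources = list(cfg.source_n_points.items())
    label, n_points = sources[subject_index % len(sources)]
    return _SubjectEffects(
        latency_factor=1.0 + cfg.subject_latency_jitter * rng.uniform(-1, 1),
        amp_factor=1.0 + cfg.subject_amp_jitter * rng.uniform(-1, 1),
        source_label=label,
        n_points=n_points,
    )


def _stack_threshold(cfg: SynthConfig, subject_index: int, freq_index: int) -> float:
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 2000 + subject_index, freq_index])
    )
    lo, hi = cfg.threshold_range_db
    grid = np.arange(lo, hi + 0.5 * cfg.threshold_step_db, cfg.threshold_step_db)
    return float(rng.choice(grid))


def _wave_params(cfg: SynthConfig, eff: _SubjectEffects, frequency: float,
                 level: float, threshold: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-wave latencies (ms, grid-quantized) and peak amplitudes (uV)."""
    ref_level = max(cfg.levels_db)
    octaves = np.log2(frequency / 16.0)
    base = np.asarray(cfg.wave_latencies_ms, dtype=float)
    lat = (base + cfg.latency_shift_per_db * (level - ref_level)) * eff.latency_factor
    lat = lat + cfg.freq_latency_offset_ms_per_octave * octaves
    dt = CANONICAL_GRID.dt_ms
    lat = np.round(lat / dt) * dt  # quantize to the canonical grid
    growth = 1.0 / (1.0 + np.exp(-cfg.amp_growth_slope * (level - threshold)))
    amp = np.asarray(cfg.amp_max_uv, dtype=float) * eff.amp_factor * growth
    return lat, amp


def _render_clean(cfg: SynthConfig, times_ms: np.ndarray,
                  latencies: np.ndarray, amplitudes: np.ndarray) -> np.ndarray:
    out = np.zeros_like(times_ms)
    for tau, a in zip(latencies, amplitudes):
        out += a * np.exp(-0.5 * ((times_ms - tau) / cfg.lobe_sigma_ms) ** 2)
        out -= (cfg.trough_ratio * a
                * np.exp(-0.5 * ((times_ms - tau - cfg.trough_delay_ms)
                                 / cfg.trough_sigma_ms) ** 2))
    return out


def _truth_from_clean(clean: np.ndarray, latencies: np.ndarray,
                      grid: SamplingGrid) -> WaveTruth:
    """Read truth peak/trough indices off the noise-free canonical trace.

    Latency truth follows the measurement convention of the peak finder:
    an extremum *index* is the argmax/argmin of the sigma = 1 smoothed
    trace (the raw and smoothed discrete extrema can disagree by one
    sample on near-ties, so the index truth is otherwise ill-defined),
    while truth *voltages* are read from the unsmoothed clean trace.
    """
    from .preprocess import gaussian_smooth

    dt = grid.dt_ms
    half = grid.ms_to_samples(0.3)
    trough_span = grid.ms_to_samples(0.6)
    smoothed = gaussian_smooth(clean)
    peak_idx: list[int] = []
    trough_idx: list[int] = []
    for tau in latencies:
        c = int(round(tau / dt))
        lo, hi = max(0, c - half), min(grid.n_points, c + half + 1)
        p = lo + int(np.argmax(smoothed[lo:hi]))
        t_lo, t_hi = p + 1, min(grid.n_points, p + trough_span + 1)
        t = t_lo + int(np.argmin(smoothed[t_lo:t_hi]))
        peak_idx.append(p)
        trough_idx.append(t)
    return WaveTruth(
        peak_idx=peak_idx,
        trough_idx=trough_idx,
        peak_uv=[float(clean[i]) for i in peak_idx],
        trough_uv=[float(clean[i]) for i in trough_idx],
        above_threshold=True,
    )


def generate_waveform(cfg: SynthConfig, subject_index: int, freq_index: int,
                      level: float,
                      rng: np.random.Generator | None = None
                      ) -> tuple[Waveform, WaveTruth]:
    """Generate one waveform and its truth record.

    ``rng`` supplies the additive noise; when omitted, a stream derived
    deterministically from (seed, subject, frequency, level) is used so the
    call is reproducible in isolation.
    """
    if level not in cfg.levels_db:
        raise ValueError(f"level {level} not in cfg.levels_db")
    frequency = float(cfg.frequencies_khz[freq_index])
    eff = _subject_effects(cfg, subject_index)
    threshold = _stack_threshold(cfg, subject_index, freq_index)
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [cfg.seed, 3000 + subject_index, freq_index, int(round(level * 10))]
            )
        )

    native_grid = SamplingGrid(n_points=eff.n_points)
    times = native_grid.times_ms()
    above = level >= threshold
    if above:
        lat, amp = _wave_params(cfg, eff, frequency, level, threshold)
        clean_native = _render_clean(cfg, times, lat, amp)
        clean_canonical = (
            clean_native if eff.n_points == CANONICAL_GRID.n_points
            else _render_clean(cfg, CANONICAL_GRID.times_ms(), lat, amp)
        )
        truth = _truth_from_clean(clean_canonical, lat, CANONICAL_GRID)
    else:
        clean_native = np.zeros_like(times)
        truth = WaveTruth([], [], [], [], above_threshold=False)

    noisy = clean_native + rng.normal(0.0, cfg.noise_sd_uv, size=len(times))
    w = Waveform(
        subject_id=f"s{subject_index:03d}",
        frequency_khz=frequency,
        level_db=float(level),
        voltages=noisy,
        source_label=eff.source_label,
        times_ms=None if eff.n_points == CANONICAL_GRID.n_points else times,
        grid=native_grid if eff.n_points != CANONICAL_GRID.n_points else CANONICAL_GRID,
    )
    return w, truth


def generate_dataset(cfg: SynthConfig) -> tuple[list[Stack], SyntheticTruth]:
    """Generate ``n_subjects x |frequencies|`` stacks plus ground truth.

    Deterministic under a fixed ``cfg.seed``; each (subject, frequency,
    level) waveform draws noise from its own independent stream.
    """
    if cfg.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    stacks: list[Stack] = []
    truth = SyntheticTruth()
    for si in range(cfg.n_subjects):
        for fi, freq in enumerate(cfg.frequencies_khz):
            waveforms = []
            for level in cfg.levels_db:
                w, wt = generate_waveform(cfg, si, fi, level)
                waveforms.append(w)
                truth.waves[(w.subject_id, float(freq), float(level))] = wt
            stacks.append(Stack(f"s{si:03d}", float(freq), waveforms))
            truth.thresholds[(f"s{si:03d}", float(freq))] = _stack_threshold(
                cfg, si, fi
            )
    return stacks, truth
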