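"""Domain types, the canonical sampling grid, and file I/O.

An auditory brainstem response (ABR) recording is a short scalp-potential
time series evoked by an acoustic stimulus.  Recordings are indexed by
subject, stimulus frequency (kHz) and stimulus level (dB); the family of
recordings for one subject at one frequency across descending levels is a
*stack*, which is the unit at which a hearing threshold is defined.

Two plain-text input dialects are supported:

* a **wide CSV** with columns ``subject, frequency_khz, level_db,
  t0..t{K-1}`` — one waveform per row, sample columns in time order;
* a **long TSV** with columns ``subject, frequency_khz, level_db, time_ms,
  voltage_uv`` — one sample per row.

Both readers keep voltages at the native sampling rate; resampling onto the
canonical 244-point / 10 ms grid is a separate preprocessing stage.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("abrkit")

#: Sentinel written to the metrics CSV when a stack shows no response at any
#: tested level ("no-response"). Unambiguous and spreadsheet-safe.
NO_RESPONSE = "NR"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingGrid:
    """Uniform sampling grid: ``n_points`` samples spanning ``window_ms``.

    Sample ``i`` maps to time ``i * dt_ms`` with ``dt_ms = window_ms /
    n_points``.  The canonical ABR grid is 244 points over 10 ms, under
    which the peak-refinement constants 0.4098, 0.6557 and 0.2869 ms are
    exactly 10, 16 and 7 samples.
    """

    n_points: int = 244
    window_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")

    @property
    def dt_ms(self) -> float:
        return self.window_ms / self.n_points

    def times_ms(self) -> np.ndarray:
        """Sample times ``i * dt_ms`` for ``i = 0 .. n_points-1``."""
        return np.arange(self.n_points) * self.dt_ms

    def ms_to_samples(self, ms: float) -> int:
        """Round a duration in ms to the nearest whole number of samples."""
        return int(round(ms / self.dt_ms))


#: Module-wide default grid.
CANONICAL_GRID = SamplingGrid()


@dataclass
class Waveform:
    """One ABR voltage trace at a (subject, frequency, level) condition.

    ``times_ms`` is the native time axis; when ``None`` the trace is assumed
    uniform over ``grid.window_ms`` (sample i at ``i * window/len``).
    """

    subject_id: str
    frequency_khz: float
    level_db: float
    voltages: np.ndarray
    source_label: str = "default"
    times_ms: np.ndarray | None = None
    grid: SamplingGrid = CANONICAL_GRID

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.frequency_khz <= 0:
            raise ValueError("frequency_khz must be positive")
        if not np.all(np.isfinite(self.voltages)):
            raise ValueError(
                f"non-finite voltage in waveform {self.key()}"
            )
        if self.times_ms is not None:
            self.times_ms = np.asarray(self.times_ms, dtype=float)
            if len(self.times_ms) != len(self.voltages):
                raise ValueError("times_ms and voltages length mismatch")

    def key(self) -> tuple[str, float, float]:
        return (self.subject_id, self.frequency_khz, self.level_db)

    def native_times_ms(self) -> np.ndarray:
        """Native time axis; uniform over the window when not recorded."""
        if self.times_ms is not None:
            return self.times_ms
        n = len(self.voltages)
        return np.arange(n) * (self.grid.window_ms / n)

    @property
    def n_samples(self) -> int:
        return len(self.voltages)

    def on_canonical_grid(self) -> bool:
        return self.times_ms is None and self.n_samples == self.grid.n_points

    def replace(self, **changes) -> "Waveform":
        return dataclasses.replace(self, **changes)


@dataclass
class Stack:
    """Ordered set of waveforms for one subject x frequency, loudest first."""

    subject_id: str
    frequency_khz: float
    waveforms: list[Waveform] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.waveforms:
            raise ValueError("a stack needs at least one waveform")
        for w in self.waveforms:
            if w.subject_id != self.subject_id or w.frequency_khz != self.frequency_khz:
                raise ValueError(
                    f"waveform {w.key()} does not belong to stack "
                    f"({self.subject_id}, {self.frequency_khz})"
                )
        self.waveforms = sorted(
            self.waveforms, key=lambda w: -w.level_db
        )
        levels = [w.level_db for w in self.waveforms]
        if len(set(levels)) != len(levels):
            raise ValueError(
                f"duplicate level in stack ({self.subject_id}, "
                f"{self.frequency_khz}): {levels}"
            )

    @property
    def levels_db(self) -> list[float]:
        """Tested levels, strictly decreasing."""
        return [w.level_db for w in self.waveforms]

    @property
    def source_label(self) -> str:
        return self.waveforms[0].source_label

    def __len__(self) -> int:
        return len(self.waveforms)

    def __iter__(self):
        return iter(self.waveforms)

    def replace_waveforms(self, waveforms: Sequence[Waveform]) -> "Stack":
        return Stack(self.subject_id, self.frequency_khz, list(waveforms))


@dataclass
class MetricsRow:
    """One exported row: wave-1 metrics for a waveform plus its stack threshold.

    ``threshold_db is None`` encodes "no response at any tested level" and is
    written as the literal ``NR``.  Absent peak metrics are written empty.
    """

    subject_id: str
    frequency_khz: float
    level_db: float
    wave1_amplitude_uv: float | None
    wave1_latency_ms: float | None
    threshold_db: float | None

    def __post_init__(self) -> None:
        if self.wave1_latency_ms is not None and not (
            0 <= self.wave1_latency_ms <= CANONICAL_GRID.window_ms
        ):
            raise ValueError(
                f"latency {self.wave1_latency_ms} ms outside the recording window"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_REQUIRED_WIDE = ("subject", "frequency_khz", "level_db")
_SAMPLE_COL = re.compile(r"^t(\d+)$")


def _to_uv(values: np.ndarray, unit: str) -> np.ndarray:
    if unit == "uV":
        return values
    if unit == "V":
        return values * 1e6
    raise ValueError(f"unknown voltage unit {unit!r} (expected 'uV' or 'V')")


def _group_stacks(waveforms: Iterable[Waveform]) -> list[Stack]:
    groups: dict[tuple[str, float], list[Waveform]] = {}
    for w in waveforms:
        groups.setdefault((w.subject_id, w.frequency_khz), []).append(w)
    return [
        Stack(subject, freq, ws)
        for (subject, freq), ws in sorted(groups.items())
    ]


def read_wide_csv(path: str | Path, unit: str = "uV",
                  source_label: str | None = None) -> list[Stack]:
    """Read the wide CSV dialect into stacks.

    Each data row is one waveform; sample columns ``t0..t{K-1}`` are taken in
    index order and the native grid is assumed uniform over 10 ms.  Rows are
    grouped by (subject, frequency) and sorted loudest-first within a stack.

    Raises
    ------
    ValueError
        On a missing required column, a non-numeric voltage cell (reported
        with its row index), or a duplicate (subject, frequency, level) key.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject": str})
    for col in _REQUIRED_WIDE:
        if col not in df.columns:
            raise ValueError(
                f"{path.name}: format error — required column {col!r} is missing"
            )
    sample_cols = sorted(
        (c for c in df.columns if _SAMPLE_COL.match(c)),
        key=lambda c: int(_SAMPLE_COL.match(c).group(1)),
    )
    if not sample_cols:
        raise ValueError(f"{path.name}: format error — no sample columns t0..tK found")
    expected = [f"t{i}" for i in range(len(sample_cols))]
    if sample_cols != expected:
        raise ValueError(
            f"{path.name}: format error — sample columns are not contiguous t0..t{len(sample_cols)-1}"
        )

    label = source_label if source_label is not None else path.stem
    seen: set[tuple[str, float, float]] = set()
    waveforms: list[Waveform] = []
    for i, row in df.iterrows():
        try:
            volts = row[sample_cols].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path.name}: non-numeric voltage in row {i}: {exc}"
            ) from None
        if not np.all(np.isfinite(volts)):
            raise ValueError(f"{path.name}: non-finite voltage in row {i}")
        key = (str(row["subject"]), float(row["frequency_khz"]), float(row["level_db"]))
        if key in seen:
            raise ValueError(
                f"{path.name}: duplicate (subject, frequency, level) key {key}"
            )
        seen.add(key)
        waveforms.append(
            Waveform(
                subject_id=key[0],
                frequency_khz=key[1],
                level_db=key[2],
                voltages=_to_uv(volts, unit),
                source_label=label,
            )
        )
    return _group_stacks(waveforms)


_REQUIRED_LONG = ("subject", "frequency_khz", "level_db", "time_ms", "voltage_uv")


def read_long_tsv(path: str | Path, unit: str = "uV",
                  source_label: str | None = None) -> list[Stack]:
    """Read the long TSV dialect (one sample per row) into stacks.

    Within each (subject, frequency, level) group ``time_ms`` must be
    strictly increasing; the native time grid is retained per waveform.
    An empty file (header only) yields an empty list.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject": str})
    for col in _REQUIRED_LONG:
        if col not in df.columns:
            raise ValueError(
                f"{path.name}: format error — required column {col!r} is missing"
            )
    label = source_label if source_label is not None else path.stem
    waveforms: list[Waveform] = []
    for key, grp in df.groupby(["subject", "frequency_khz", "level_db"], sort=True):
        times = grp["time_ms"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(
                f"{path.name}: time_ms not strictly increasing in group {key}"
            )
        waveforms.append(
            Waveform(
                subject_id=str(key[0]),
                frequency_khz=float(key[1]),
                level_db=float(key[2]),
                voltages=_to_uv(grp["voltage_uv"].to_numpy(dtype=float), unit),
                times_ms=times,
                source_label=label,
            )
        )
    return _group_stacks(waveforms)


# ---------------------------------------------------------------------------
# Metrics export
# ---------------------------------------------------------------------------

_METRICS_COLUMNS = (
    "subject_id",
    "frequency_khz",
    "level_db",
    "wave1_amplitude_uv",
    "wave1_latency_ms",
    "threshold_db",
)


def write_metrics_csv(rows: Iterable[MetricsRow], path: str | Path) -> None:
    """Write metrics rows to CSV in a deterministic column and row order.

    Rows are sorted by (subject asc, frequency asc, level desc); numeric
    fields are written with 6 decimals so a write/read round trip preserves
    them to 1e-6; a ``None`` threshold is written as ``NR`` and absent peak
    metrics as empty cells.
    """
    rows = sorted(
        rows, key=lambda r: (r.subject_id, r.frequency_khz, -r.level_db)
    )

    def fmt(x: float | None) -> str:
        return "" if x is None else f"{x:.6f}"

    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_METRICS_COLUMNS) + "\n")
        for r in rows:
            thr = NO_RESPONSE if r.threshold_db is None else f"{r.threshold_db:.6f}"
            fh.write(
                f"{r.subject_id},{r.frequency_khz:.6f},{r.level_db:.6f},"
                f"{fmt(r.wave1_amplitude_uv)},{fmt(r.wave1_latency_ms)},{thr}\n"
            )


def read_metrics_csv(path: str | Path) -> list[MetricsRow]:
    """Re-read a metrics CSV written by :func:`write_metrics_csv`."""
    df = pd.read_csv(path, dtype={"subject_id": str, "threshold_db": str})
    rows: list[MetricsRow] = []
    for _, r in df.iterrows():
        thr_raw = r["threshold_db"]
        if isinstance(thr_raw, str) and thr_raw.strip() == NO_RESPONSE:
            thr: float | None = None
        elif thr_raw is None or (isinstance(thr_raw, float) and math.isnan(thr_raw)):
            thr = None
        else:
            thr = float(thr_raw)

        def opt(v) -> float | None:
            return None if pd.isna(v) else float(v)

        rows.append(
            MetricsRow(
                subject_id=str(r["subject_id"]),
                frequency_khz=float(r["frequency_khz"]),
                level_db=float(r["level_db"]),
                wave1_amplitude_uv=opt(r["wave1_amplitude_uv"]),
                wave1_latency_ms=opt(r["wave1_latency_ms"]),
                threshold_db=thr,
            )
        )
    return rows
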