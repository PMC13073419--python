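"""Hypnograms, REM-period selection, the 3 s mini-epoch grid, and scoring.

Sleep staging arrives as a hypnogram of 30 s epochs labelled W/N1/N2/N3/R.
Maximal runs of consecutive R epochs form REM periods; periods shorter than
5 min are excluded.  Each surviving period is tiled from its onset with
contiguous 3 s mini-epochs — the unit of every cross-modality agreement
analysis.  EMG is scored per mini-epoch against a per-period atonia baseline;
left and right wrists are merged by elementwise OR.

All times are seconds from a single recording-start origin; intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .counts import TriaxialRecording

__all__ = [
    "STAGES",
    "Hypnogram",
    "RemPeriod",
    "MiniEpochGrid",
    "EmgEnvelope",
    "ModalityLabels",
    "rem_periods",
    "mini_epoch_grid",
    "estimate_sync_offset",
    "score_emg_mini_epochs",
    "merge_bilateral",
]

STAGES = ("W", "N1", "N2", "N3", "R")

#: Minimum REM period duration retained for analysis (s); strictly shorter
#: periods are excluded, exactly 5 min is kept.
MIN_REM_PERIOD_S = 300.0


@dataclass
class Hypnogram:
    """Sequence of 30 s sleep-stage labels."""

    stages: tuple[str, ...]
    epoch_len: float = 30.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if not self.stages:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = sorted(set(self.stages) - set(STAGES))
        if bad:
            raise ValueError(f"unknown stage labels: {bad}; expected {STAGES}")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return len(self.stages) * self.epoch_len


@dataclass(frozen=True)
class RemPeriod:
    """One REM sleep period, seconds from recording start, half-open."""

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class MiniEpochGrid:
    """Contiguous 3 s bins tiling each REM period from its onset."""

    starts: np.ndarray
    period_index: np.ndarray
    bin_s: float = 3.0
    periods: tuple[RemPeriod, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.period_index = np.asarray(self.period_index, dtype=int)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.bin_s

    @property
    def total_rem_hours(self) -> float:
        return sum(p.duration for p in self.periods) / 3600.0


@dataclass
class EmgEnvelope:
    """Rectified EMG envelope (µV) at a uniform rate, one side."""

    rate: float
    values: np.ndarray
    side: str = "L"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")


@dataclass
class ModalityLabels:
    """Binary active/inactive labels on the mini-epoch grid.

    ``sustained`` flags epochs overlapped only by suprathreshold EMG runs
    longer than the scoring window ("sustained activity, unscored").
    """

    modality: str
    side: str
    labels: np.ndarray
    sustained: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.modality not in ("emg", "acti", "video"):
            raise ValueError(f"unknown modality {self.modality!r}")

    def __len__(self) -> int:
        return len(self.labels)


def rem_periods(hyp: Hypnogram, min_duration: float = MIN_REM_PERIOD_S) -> list[RemPeriod]:
    """Maximal runs of consecutive R epochs, dropping runs shorter than 5 min.

    The exclusion is strict ("shorter than"): a period of exactly
    ``min_duration`` is kept.  A single non-R epoch splits a period.
    """
    periods: list[RemPeriod] = []
    run_start: int | None = None
    stages = list(hyp.stages) + ["_"]  # sentinel closes a trailing run
    for i, s in enumerate(stages):
        if s == "R" and run_start is None:
            run_start = i
        elif s != "R" and run_start is not None:
            start = hyp.start_time + run_start * hyp.epoch_len
            end = hyp.start_time + i * hyp.epoch_len
            if end - start >= min_duration:
                periods.append(RemPeriod(start, end))
            run_start = None
    return periods


def mini_epoch_grid(periods: list[RemPeriod], bin_s: float = 3.0) -> MiniEpochGrid:
    """Tile each REM period from its onset with ``bin_s`` bins.

    Bins per period = floor(duration / bin_s); with 30 s staging the division
    is exact and no partial bin arises.
    """
    starts: list[np.ndarray] = []
    idx: list[np.ndarray] = []
    for k, p in enumerate(periods):
        n = int(np.floor(p.duration / bin_s + 1e-9))
        starts.append(p.start + bin_s * np.arange(n))
        idx.append(np.full(n, k))
    if starts:
        all_starts = np.concatenate(starts)
        all_idx = np.concatenate(idx)
    else:
        all_starts = np.empty(0)
        all_idx = np.empty(0, dtype=int)
    return MiniEpochGrid(all_starts, all_idx, bin_s, tuple(periods))


def estimate_sync_offset(
    rec: TriaxialRecording,
    reference: TriaxialRecording,
    search_window_s: float = 60.0,
    min_peak_corr: float = 0.2,
) -> float:
    """Time offset of ``rec`` relative to ``reference`` from the sync maneuver.

    Cross-correlates the mean-removed magnitude signals and returns the lag
    (s) maximizing correlation within ``±search_window_s``; positive means
    ``rec`` lags ``reference``.  If the normalized correlation peak falls
    below ``min_peak_corr`` a warning is emitted and 0.0 returned.
    """
    if not np.isclose(rec.sampling_rate, reference.sampling_rate):
        raise ValueError("recordings must share a sampling rate; resample first")
    fs = rec.sampling_rate
    a = rec.magnitude()
    b = reference.magnitude()
    a = a - a.mean()
    b = b - b.mean()
    corr = _signal.correlate(a, b, mode="full")
    lags = _signal.correlation_lags(len(a), len(b), mode="full")
    max_lag = int(round(search_window_s * fs))
    mask = np.abs(lags) <= max_lag
    corr = corr[mask]
    lags = lags[mask]
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        warnings.warn("flat signals: sync offset indeterminate, using 0 s")
        return 0.0
    k = int(np.argmax(corr))
    if corr[k] / denom < min_peak_corr:
        warnings.warn(
            "sync correlation peak below prominence floor; using offset 0 s"
        )
        return 0.0
    return float(lags[k] / fs)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i0, i1) index ranges of consecutive True samples."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def score_emg_mini_epochs(
    env: EmgEnvelope,
    grid: MiniEpochGrid,
    threshold_ratio: float = 2.0,
    min_burst_s: float = 0.1,
    max_burst_s: float = 5.0,
    use_preceding_nrem: bool = True,
    atonia_floor: float | None = None,
) -> ModalityLabels:
    """Score EMG activity per 3 s mini-epoch against the atonia baseline.

    For each REM period, the atonia baseline is the lowest envelope amplitude
    within the period — or within the preceding non-REM interval (from the
    previous period's end, or recording start) if that is lower.  A
    suprathreshold run (envelope >= ``threshold_ratio`` x atonia) counts as an
    activity burst when its duration lies in ``[min_burst_s, max_burst_s]``;
    a mini-epoch is active iff it overlaps at least one qualifying burst.
    Longer runs are flagged per-epoch as sustained activity, unscored.

    Raises
    ------
    ValueError
        If the envelope does not cover all periods, or the atonia baseline is
        zero and no ``atonia_floor`` is supplied (threshold undefined).
    """
    fs = env.rate
    t0 = env.start_time
    n = len(env.values)
    labels = np.zeros(len(grid), dtype=np.int8)
    sustained = np.zeros(len(grid), dtype=np.int8)
    eps = 1e-9
    prev_end = t0
    for k, p in enumerate(grid.periods):
        i0 = int(round((p.start - t0) * fs))
        i1 = int(round((p.end - t0) * fs))
        if i0 < 0 or i1 > n:
            raise ValueError(f"envelope does not cover REM period [{p.start}, {p.end}) s")
        seg = env.values[i0:i1]
        atonia = float(seg.min())
        if use_preceding_nrem:
            j0 = int(round((prev_end - t0) * fs))
            if j0 < i0:
                atonia = min(atonia, float(env.values[j0:i0].min()))
        prev_end = p.end
        if atonia <= 0:
            if atonia_floor is not None and atonia_floor > 0:
                atonia = atonia_floor
            else:
                raise ValueError(
                    f"atonia baseline is 0 in REM period {k}; the 2x threshold is "
                    "undefined — supply atonia_floor"
                )
        supra = seg >= threshold_ratio * atonia
        in_period = grid.period_index == k
        epoch_starts = grid.starts[in_period]
        epoch_idx = np.flatnonzero(in_period)
        for r0, r1 in _runs(supra):
            dur = (r1 - r0) / fs
            b_start = p.start + r0 / fs
            b_end = p.start + r1 / fs
            overlapped = epoch_idx[
                (epoch_starts < b_end - eps) & (epoch_starts + grid.bin_s > b_start + eps)
            ]
            if min_burst_s - eps <= dur <= max_burst_s + eps:
                labels[overlapped] = 1
            elif dur > max_burst_s:
                sustained[overlapped] = 1
    return ModalityLabels("emg", env.side, labels, sustained=sustained)


def merge_bilateral(left: ModalityLabels, right: ModalityLabels) -> ModalityLabels:
    """Merge the two wrists: an epoch is active if either side is active."""
    if left.modality != right.modality:
        raise ValueError("cannot merge labels from different modalities")
    if len(left) != len(right):
        raise ValueError("label vectors lie on different grids")
    merged = np.maximum(left.labels, right.labels)
    sus = None
    if left.sustained is not None or right.sustained is not None:
        ls = left.sustained if left.sustained is not None else np.zeros(len(left), np.int8)
        rs = right.sustained if right.sustained is not None else np.zeros(len(right), np.int8)
        sus = np.maximum(ls, rs)
    return ModalityLabels(left.modality, "merged", merged, sustained=sus)
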