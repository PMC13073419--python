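"""Cross-modality agreement statistics on the REM mini-epoch grid.

Given merged binary labels from EMG, actigraphy and video on one grid, this
module decomposes detections into the seven exclusive overlap regions,
computes Cohen's κ and directional conditional probabilities per modality
pair, Mantel–Haenszel pooled odds ratios across participants, per-modality
activity burden (ratio and rate), consensus-stratified actigraphy count
magnitudes, and participant-level bootstrap confidence intervals.

Convention for a modality pair (A, B): the 2x2 table is oriented with A on
rows and B on columns, so ``a`` = both active, ``b`` = A only, ``c`` = B
only, ``d`` = neither.  Undefined quantities (degenerate margins, empty
strata) are returned as NaN, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .grid import MiniEpochGrid, ModalityLabels

__all__ = [
    "OverlapCounts",
    "ContingencyTable2x2",
    "overlap_regions",
    "contingency_table",
    "cohens_kappa",
    "conditional_probs",
    "pooled_odds_ratio",
    "activity_ratio",
    "activity_rate",
    "stratified_activity_counts",
    "bootstrap_group_ci",
]

STRATA = ("all_three", "emg_acti", "acti_video", "acti_only")


@dataclass(frozen=True)
class OverlapCounts:
    """Exclusive three-modality region decomposition of mini-epoch detections."""

    n_total: int
    emg_only: int
    acti_only: int
    video_only: int
    emg_acti: int
    emg_video: int
    acti_video: int
    all_three: int
    none_active: int

    def __post_init__(self) -> None:
        regions = (
            self.emg_only + self.acti_only + self.video_only + self.emg_acti
            + self.emg_video + self.acti_video + self.all_three
        )
        if regions + self.none_active != self.n_total:
            raise ValueError("overlap regions + none_active must sum to n_total")

    @property
    def union_active(self) -> int:
        """Mini-epochs with activity in at least one modality."""
        return self.n_total - self.none_active

    @property
    def marginals(self) -> dict[str, int]:
        """Total detections per modality (sum of its four regions)."""
        return {
            "emg": self.emg_only + self.emg_acti + self.emg_video + self.all_three,
            "acti": self.acti_only + self.emg_acti + self.acti_video + self.all_three,
            "video": self.video_only + self.emg_video + self.acti_video + self.all_three,
        }


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 agreement table: a=both, b=first only, c=second only, d=neither."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


def _vec(labels) -> np.ndarray:
    v = labels.labels if isinstance(labels, ModalityLabels) else np.asarray(labels)
    return v.astype(bool)


def overlap_regions(emg, acti, video) -> OverlapCounts:
    """Decompose three equal-length binary label vectors into the 7 regions."""
    e, a, v = _vec(emg), _vec(acti), _vec(video)
    if not (len(e) == len(a) == len(v)):
        raise ValueError("label vectors must have equal length")
    return OverlapCounts(
        n_total=len(e),
        emg_only=int((e & ~a & ~v).sum()),
        acti_only=int((~e & a & ~v).sum()),
        video_only=int((~e & ~a & v).sum()),
        emg_acti=int((e & a & ~v).sum()),
        emg_video=int((e & ~a & v).sum()),
        acti_video=int((~e & a & v).sum()),
        all_three=int((e & a & v).sum()),
        none_active=int((~e & ~a & ~v).sum()),
    )


def contingency_table(first, second) -> ContingencyTable2x2:
    """2x2 table of two binary label vectors (first = rows, second = columns)."""
    x, y = _vec(first), _vec(second)
    if len(x) != len(y):
        raise ValueError("label vectors must have equal length")
    return ContingencyTable2x2(
        a=int((x & y).sum()),
        b=int((x & ~y).sum()),
        c=int((~x & y).sum()),
        d=int((~x & ~y).sum()),
    )


def cohens_kappa(t: ContingencyTable2x2) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e).

    Returns NaN when expected agreement is 1 (both raters constant), where κ
    is undefined.
    """
    n = t.n
    if n == 0:
        raise ValueError("empty table")
    p_o = (t.a + t.d) / n
    p_e = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / n**2
    if np.isclose(p_e, 1.0):
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def conditional_probs(t: ContingencyTable2x2) -> dict[str, float]:
    """Directional conditional probabilities for a pair (A=rows, B=columns).

    Keys: ``p_a1_given_b1`` = a/(a+c), ``p_b1_given_a1`` = a/(a+b),
    ``p_a0_given_b0`` = d/(b+d), ``p_b0_given_a0`` = d/(c+d).  A zero
    conditioning margin yields NaN for that probability.
    """

    def ratio(num: float, den: float) -> float:
        return float(num / den) if den > 0 else float("nan")

    return {
        "p_a1_given_b1": ratio(t.a, t.a + t.c),
        "p_b1_given_a1": ratio(t.a, t.a + t.b),
        "p_a0_given_b0": ratio(t.d, t.b + t.d),
        "p_b0_given_a0": ratio(t.d, t.c + t.d),
    }


def pooled_odds_ratio(
    tables: Sequence[ContingencyTable2x2], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Mantel–Haenszel pooled odds ratio across participants, with CI.

    A Haldane–Anscombe 0.5 continuity correction is applied to any table
    containing a zero cell.  The confidence interval comes from the
    Robins–Breslow–Greenland log-scale standard error (via statsmodels).
    """
    from scipy import stats as _st
    from statsmodels.stats.contingency_tables import StratifiedTable

    if not tables:
        raise ValueError("at least one table is required")
    arrays = []
    for t in tables:
        cells = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5
        arrays.append(cells)
    informative = [c for c in arrays if (c[0, 0] + c[0, 1]) > 0 and (c[1, 0] + c[1, 1]) > 0]
    if not informative:
        raise ValueError("all tables are degenerate")
    stacked = np.stack(informative, axis=-1)
    st = StratifiedTable(stacked)
    or_pooled = float(st.oddsratio_pooled)
    se = float(st.logodds_pooled_se)
    z = float(_st.norm.ppf(1 - alpha / 2))
    lo = float(np.exp(np.log(or_pooled) - z * se))
    hi = float(np.exp(np.log(or_pooled) + z * se))
    return or_pooled, (lo, hi)


def activity_ratio(labels) -> float:
    """Percentage of REM mini-epochs with detected activity."""
    v = _vec(labels)
    if len(v) == 0:
        raise ValueError("empty grid")
    return float(100.0 * v.sum() / len(v))


def activity_rate(labels, grid: MiniEpochGrid) -> float:
    """Distinct motor events per hour of REM sleep.

    An event is a maximal run of consecutive active mini-epochs within one
    REM period (runs never span periods); a multi-epoch run counts once, from
    onset to offset.
    """
    v = _vec(labels).astype(np.int8)
    if len(v) != len(grid):
        raise ValueError("labels do not match the grid")
    hours = grid.total_rem_hours
    if hours <= 0:
        raise ValueError("zero REM duration")
    n_events = 0
    for k in np.unique(grid.period_index):
        seg = v[grid.period_index == k]
        # onsets: 0->1 transitions, counting a leading 1
        n_events += int(seg[0] + np.sum((seg[1:] == 1) & (seg[:-1] == 0)))
    return float(n_events / hours)


def stratified_activity_counts(
    acti_counts,
    emg,
    acti,
    video,
    grid: MiniEpochGrid,
    per_epoch: str = "max",
) -> dict[str, float]:
    """Mean actigraphy count magnitude by multimodal consensus category.

    Actigraphy-active epochs are split into four mutually exclusive strata —
    all three modalities, EMG+actigraphy (no video), actigraphy+video (no
    EMG), actigraphy only — and the mean over each stratum of the per-epoch
    count magnitude (max of the epoch's 1 Hz counts by default, ``"mean"``
    as alternative) is returned.  Empty strata yield NaN.
    """
    from .counts import ActivityCountSeries

    e, a, v = _vec(emg), _vec(acti), _vec(video)
    if not (len(e) == len(a) == len(v) == len(grid)):
        raise ValueError("labels and grid must align")
    if not a.any():
        raise ValueError("no actigraphy-active epochs to stratify")
    assert isinstance(acti_counts, ActivityCountSeries)
    reducer = np.max if per_epoch == "max" else np.mean
    t0 = acti_counts.start_time
    mags = np.empty(len(grid))
    for i, (s, en) in enumerate(zip(grid.starts, grid.ends)):
        i0 = int(np.floor(s - t0 + 1e-9))
        i1 = int(np.ceil(en - t0 - 1e-9))
        mags[i] = reducer(acti_counts.values[i0:i1])
    strata = {
        "all_three": e & a & v,
        "emg_acti": e & a & ~v,
        "acti_video": ~e & a & v,
        "acti_only": ~e & a & ~v,
    }
    return {
        name: (float(mags[m].mean()) if m.any() else float("nan"))
        for name, m in strata.items()
    }


def bootstrap_group_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Group-level statistic with a nonparametric participant bootstrap CI.

    Participants are resampled with replacement ``n_boot`` times; the CI is
    the percentile interval of the resampled statistic.  NaN entries are
    dropped first; at least two non-missing values are required.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("need at least two non-missing values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    boots = np.apply_along_axis(statistic, 1, v[idx])
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(statistic(v)), (float(lo), float(hi))
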