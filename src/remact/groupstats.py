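"""Stage-wise movement load and the within/between-group hypothesis tests.

Movement load for one participant and stage = (sum of left + right wrist 1 Hz
activity counts over all 30 s epochs of that stage) / stage minutes.  Loads
are compared within participants across stage pairs by exact Wilcoxon
signed-rank tests with Holm correction, and between groups by Mann–Whitney U
with Cliff's delta as the effect size and Benjamini–Hochberg FDR across
stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as st
from statsmodels.stats.multitest import multipletests

from .counts import ActivityCountSeries
from .grid import Hypnogram

__all__ = [
    "StatResult",
    "movement_load",
    "movement_load_table",
    "wilcoxon_holm",
    "mannwhitney_cliffs",
    "cliffs_delta",
    "bh_fdr",
    "DEFAULT_STAGE_PAIRS",
]

#: The six pairwise combinations of the sleep stages tested by default; wake
#: is computed but excluded from hypothesis testing.
DEFAULT_STAGE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    combinations(("N1", "N2", "N3", "R"), 2)
)


@dataclass
class StatResult:
    """One hypothesis-test outcome with its multiplicity adjustment."""

    label: str
    statistic: float
    p: float
    p_adjusted: float
    adjustment: str
    effect_size: float | None = None
    n: int | None = None


def movement_load(
    left: ActivityCountSeries | None,
    right: ActivityCountSeries | None,
    hyp: Hypnogram,
    stages: Sequence[str] = ("W", "N1", "N2", "N3", "R"),
) -> pd.Series:
    """Per-stage movement load (counts/min) for one participant.

    Counts from both wrists are summed within each 30 s staging epoch and
    accumulated per stage; the total is divided by the minutes spent in the
    stage.  A stage absent from the hypnogram is NaN, never 0.  If only one
    wrist is supplied the load is computed unilaterally and the result is
    marked via ``result.attrs["unilateral"]``.
    """
    series = [s for s in (left, right) if s is not None]
    if not series:
        raise ValueError("at least one wrist's counts are required")
    n_per_epoch = int(hyp.epoch_len)  # 1 Hz counts
    sums = {s: 0.0 for s in stages}
    minutes = {s: 0.0 for s in stages}
    for i, stage in enumerate(hyp.stages):
        if stage not in sums:
            continue
        t0 = hyp.start_time + i * hyp.epoch_len
        for cs in series:
            j0 = int(round(t0 - cs.start_time))
            j1 = j0 + n_per_epoch
            if j0 < 0 or j1 > len(cs.values):
                raise ValueError(
                    f"counts do not cover staging epoch {i} ([{t0}, {t0 + hyp.epoch_len}) s)"
                )
            sums[stage] += float(cs.values[j0:j1].sum())
        minutes[stage] += hyp.epoch_len / 60.0
    load = pd.Series(
        {s: (sums[s] / minutes[s] if minutes[s] > 0 else np.nan) for s in stages},
        name="movement_load",
    )
    load.attrs["unilateral"] = len(series) == 1
    return load


def movement_load_table(loads: Sequence[pd.Series], ids: Sequence | None = None) -> pd.DataFrame:
    """Stack per-participant load series into a participants x stages table."""
    df = pd.DataFrame(list(loads))
    if ids is not None:
        df.index = list(ids)
    return df


def wilcoxon_holm(
    load_table: pd.DataFrame,
    stage_pairs: Sequence[tuple[str, str]] = DEFAULT_STAGE_PAIRS,
) -> list[StatResult]:
    """Within-participant Wilcoxon signed-rank tests with Holm correction.

    Each stage pair is tested two-sided across participants having both
    stages; zero differences are dropped before ranking and the exact null
    distribution is used for small samples.  All-zero differences give p = 1.
    """
    raw: list[float] = []
    results: list[StatResult] = []
    for s1, s2 in stage_pairs:
        sub = load_table[[s1, s2]].dropna()
        x, y = sub[s1].to_numpy(), sub[s2].to_numpy()
        if len(x) < 2:
            raise ValueError(f"fewer than two participants with both {s1} and {s2}")
        if np.allclose(x, y):
            stat_val, p = float("nan"), 1.0
        else:
            res = st.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
            stat_val, p = float(res.statistic), float(res.pvalue)
        raw.append(p)
        results.append(
            StatResult(f"{s1} vs {s2}", stat_val, p, np.nan, "holm", n=len(x))
        )
    adjusted = multipletests(raw, method="holm")[1]
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
    return results


def cliffs_delta(a: Sequence[float], b: Sequence[float]) -> float:
    """Cliff's delta: [#(a > b) − #(a < b)] / (n_a · n_b), in [−1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    diff = a[:, None] - b[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (len(a) * len(b)))


def mannwhitney_cliffs(
    group_a: Sequence[float], group_b: Sequence[float], label: str = "A vs B"
) -> StatResult:
    """Two-sided Mann–Whitney U test with Cliff's delta effect size.

    The exact null distribution is used for small tie-free samples; otherwise
    the tie-corrected normal approximation applies.  The adjusted p is left
    equal to the raw p — callers combine results with :func:`bh_fdr`.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = st.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return StatResult(
        label,
        float(res.statistic),
        float(res.pvalue),
        float(res.pvalue),
        "none",
        effect_size=cliffs_delta(a, b),
        n=len(a) + len(b),
    )


def bh_fdr(raw_p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(raw_p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
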