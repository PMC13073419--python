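"""Plain-text formats, recording manifests, and the full-analysis driver.

Formats (all headered, tab- or comma-separated text):

- accelerometer CSV: ``time_s,x_g,y_g,z_g``
- hypnogram TSV: ``epoch_index<TAB>stage`` (stage aliases REM->R, SWS->N3,
  WAKE->W accepted)
- annotation TSV: ``epoch_start_s<TAB>label`` with binary labels on the REM
  mini-epoch grid
- counts CSV: ``time_s,count_g``
- manifest YAML/JSON naming every stream of one participant

Written tables carry a provenance comment header (package version, config
hash, seed); readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as cc
from . import groupstats as gs
from .counts import (
    ActivityCountSeries,
    CountsConfig,
    TriaxialRecording,
    compute_activity_counts,
    epoch_activity,
)
from .grid import (
    EmgEnvelope,
    Hypnogram,
    MiniEpochGrid,
    ModalityLabels,
    merge_bilateral,
    mini_epoch_grid,
    rem_periods,
    score_emg_mini_epochs,
)

__all__ = [
    "RecordingManifest",
    "read_accel_csv",
    "write_accel_csv",
    "read_hypnogram_tsv",
    "write_hypnogram_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_counts_csv",
    "write_counts_csv",
    "load_manifest",
    "run_full_analysis",
    "run_study",
    "AnalysisConfig",
]

STAGE_ALIASES = {
    "W": "W", "WAKE": "W", "N1": "N1", "N2": "N2",
    "N3": "N3", "SWS": "N3", "R": "R", "REM": "R",
}

MODALITY_PAIRS = (("emg", "acti"), ("emg", "video"), ("acti", "video"))


@dataclass(frozen=True)
class AnalysisConfig:
    """End-to-end analysis parameters."""

    counts: CountsConfig = field(default_factory=CountsConfig)
    bootstrap_n: int = 10_000
    bootstrap_seed: int = 0
    emg_atonia_floor: float | None = None

    def hash(self) -> str:
        payload = json.dumps(
            {
                "counts": self.counts.__dict__ | {"filter_spec": self.counts.filter_spec.__dict__},
                "bootstrap_n": self.bootstrap_n,
                "bootstrap_seed": self.bootstrap_seed,
                "emg_atonia_floor": self.emg_atonia_floor,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RecordingManifest:
    """Paths and metadata for one participant's multimodal streams."""

    participant_id: str
    files: dict[str, Path]
    device_rate: float = 50.0
    device_range: float = 8.0
    sync_offsets: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.files = {k: Path(v) for k, v in self.files.items()}
        for k, p in self.files.items():
            if not p.exists():
                raise FileNotFoundError(f"manifest stream {k!r}: {p} does not exist")
        for k, off in self.sync_offsets.items():
            if not np.isfinite(off):
                raise ValueError(f"sync offset for {k!r} is not finite")


def _provenance_header(kind: str, config_hash: str | None = None, seed=None) -> str:
    from . import __version__

    parts = [f"# remact v{__version__} {kind}"]
    if config_hash:
        parts.append(f"config_hash={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts) + "\n"


def write_accel_csv(rec: TriaxialRecording, path, seed=None) -> None:
    t = rec.start_time + np.arange(len(rec)) / rec.sampling_rate
    df = pd.DataFrame({"time_s": t, "x_g": rec.x, "y_g": rec.y, "z_g": rec.z})
    with open(path, "w") as fh:
        fh.write(_provenance_header("accelerometer", seed=seed))
        df.to_csv(fh, index=False, float_format="%.6f")


def read_accel_csv(path, side: str = "L", dynamic_range: float = 8.0) -> TriaxialRecording:
    """Read an accelerometer CSV into a uniform-rate recording.

    The rate is inferred from the median time step; visibly non-uniform input
    is interpolated onto a uniform grid with a warning.  Non-monotone time or
    missing columns raise with the offending line number.
    """
    df = pd.read_csv(path, comment="#")
    required = ["time_s", "x_g", "y_g", "z_g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if len(bad):
        # +3: 1-based line numbers, header line, provenance comment absent in count
        raise ValueError(
            f"{path}: time not strictly increasing at data line {bad[0] + 2}"
        )
    med = float(np.median(dt))
    rate = 1.0 / med
    x, y, z = (df[c].to_numpy(dtype=float) for c in ("x_g", "y_g", "z_g"))
    if np.max(np.abs(dt - med)) > 0.01 * med:
        warnings.warn(f"{path}: non-uniform sampling; interpolating to {rate:.6g} Hz")
        tu = t[0] + np.arange(int(np.floor((t[-1] - t[0]) / med)) + 1) * med
        x, y, z = (np.interp(tu, t, v) for v in (x, y, z))
        t = tu
    return TriaxialRecording(
        sampling_rate=rate, x=x, y=y, z=z, side=side,
        start_time=float(t[0]), dynamic_range=dynamic_range,
    )


def write_hypnogram_tsv(hyp: Hypnogram, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header("hypnogram", seed=seed))
        fh.write("epoch_index\tstage\n")
        for i, s in enumerate(hyp.stages):
            fh.write(f"{i}\t{s}\n")


def read_hypnogram_tsv(path) -> Hypnogram:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "stage" not in df.columns:
        raise ValueError(f"{path}: missing 'stage' column")
    stages = []
    for raw in df["stage"].astype(str):
        key = raw.strip().upper()
        if key not in STAGE_ALIASES:
            raise ValueError(f"{path}: unknown stage label {raw!r}")
        stages.append(STAGE_ALIASES[key])
    return Hypnogram(tuple(stages))


def write_annotation_tsv(labels: ModalityLabels, grid: MiniEpochGrid, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(f"annotation modality={labels.modality}", seed=seed))
        fh.write("epoch_start_s\tlabel\n")
        for s, v in zip(grid.starts, labels.labels):
            fh.write(f"{s:.1f}\t{int(v)}\n")


def read_annotation_tsv(path, grid: MiniEpochGrid, modality: str, side: str = "merged") -> ModalityLabels:
    df = pd.read_csv(path, sep="\t", comment="#")
    for c in ("epoch_start_s", "label"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    starts = df["epoch_start_s"].to_numpy(dtype=float)
    if len(starts) != len(grid) or not np.allclose(starts, grid.starts, atol=1e-6):
        raise ValueError(f"{path}: annotation epochs do not match the REM grid")
    lab = df["label"].to_numpy()
    if not np.isin(lab, (0, 1)).all():
        raise ValueError(f"{path}: labels must be 0 or 1")
    return ModalityLabels(modality, side, lab.astype(np.int8))


def write_counts_csv(counts: ActivityCountSeries, path, config_hash=None, seed=None) -> None:
    t = counts.start_time + np.arange(len(counts))
    df = pd.DataFrame({"time_s": t, "count_g": counts.values})
    with open(path, "w") as fh:
        fh.write(_provenance_header("activity_counts", config_hash, seed))
        df.to_csv(fh, index=False, float_format="%.6f")


def read_counts_csv(path, side: str = "L") -> ActivityCountSeries:
    df = pd.read_csv(path, comment="#")
    for c in ("time_s", "count_g"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    return ActivityCountSeries(
        values=df["count_g"].to_numpy(dtype=float),
        side=side,
        start_time=float(df["time_s"].iloc[0]),
    )


def load_manifest(path) -> RecordingManifest:
    """Load a participant manifest (YAML or JSON); paths resolve relative to it."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    base = path.parent
    files = {k: base / v for k, v in data.get("files", {}).items()}
    return RecordingManifest(
        participant_id=str(data.get("participant_id", path.stem)),
        files=files,
        device_rate=float(data.get("device_rate", 50.0)),
        device_range=float(data.get("device_range", 8.0)),
        sync_offsets={k: float(v) for k, v in data.get("sync_offsets", {}).items()},
        seed=data.get("seed"),
    )


def _shift(rec: TriaxialRecording, offset: float) -> TriaxialRecording:
    from dataclasses import replace

    return replace(rec, start_time=rec.start_time - offset) if offset else rec


def run_full_analysis(manifest: RecordingManifest, config: AnalysisConfig | None = None) -> dict:
    """Run counts -> grid -> labels -> concordance for one participant.

    Returns a bundle dict with the REM grid, per-side counts, merged labels
    per available modality, pairwise agreement (κ, conditional probabilities,
    2x2 tables), per-modality burden, stage-wise movement load and, when all
    three modalities are present, the overlap decomposition and
    consensus-stratified count magnitudes.  Missing modalities degrade the
    analysis to the available pairs; missing quantities are NaN, never zero.
    """
    cfg = config or AnalysisConfig()
    stage = "input"
    try:
        hyp = read_hypnogram_tsv(manifest.files["hypnogram"])
        periods = rem_periods(hyp)
        grid = mini_epoch_grid(periods)

        stage = "counts"
        counts: dict[str, ActivityCountSeries] = {}
        for side in ("L", "R"):
            key = f"accel_{side}"
            if key in manifest.files:
                rec = read_accel_csv(manifest.files[key], side, manifest.device_range)
                rec = _shift(rec, manifest.sync_offsets.get(key, 0.0))
                counts[side] = compute_activity_counts(rec, cfg.counts)

        stage = "labels"
        labels: dict[str, ModalityLabels] = {}
        if counts and len(grid):
            acti_sides = [
                ModalityLabels("acti", s, epoch_activity(c, grid))
                for s, c in counts.items()
            ]
            acti = acti_sides[0]
            for other in acti_sides[1:]:
                acti = merge_bilateral(acti, other)
            if acti.side != "merged":
                acti = ModalityLabels("acti", "merged", acti.labels)
            labels["acti"] = acti
        if "emg_labels" in manifest.files and len(grid):
            labels["emg"] = read_annotation_tsv(manifest.files["emg_labels"], grid, "emg")
        elif len(grid) and ("emg_envelope_L" in manifest.files or "emg_envelope_R" in manifest.files):
            scored = []
            for side in ("L", "R"):
                key = f"emg_envelope_{side}"
                if key in manifest.files:
                    env = _read_envelope_csv(manifest.files[key], side)
                    scored.append(
                        score_emg_mini_epochs(env, grid, atonia_floor=cfg.emg_atonia_floor)
                    )
            emg = scored[0]
            for other in scored[1:]:
                emg = merge_bilateral(emg, other)
            if emg.side != "merged":
                emg = ModalityLabels("emg", "merged", emg.labels, sustained=emg.sustained)
            labels["emg"] = emg
        if "video_labels" in manifest.files and len(grid):
            labels["video"] = read_annotation_tsv(manifest.files["video_labels"], grid, "video")

        stage = "concordance"
        pairs = {}
        for m1, m2 in MODALITY_PAIRS:
            if m1 in labels and m2 in labels:
                t = cc.contingency_table(labels[m1], labels[m2])
                pairs[(m1, m2)] = {
                    "table": t,
                    "kappa": cc.cohens_kappa(t),
                    **cc.conditional_probs(t),
                }
        burden = {
            m: {
                "activity_ratio": cc.activity_ratio(lab),
                "activity_rate": cc.activity_rate(lab, grid),
            }
            for m, lab in labels.items()
        } if len(grid) else {}
        overlap = None
        stratified = None
        if all(m in labels for m in ("emg", "acti", "video")):
            overlap = cc.overlap_regions(labels["emg"], labels["acti"], labels["video"])
            summed = _sum_counts(list(counts.values()))
            if labels["acti"].labels.any():
                stratified = cc.stratified_activity_counts(
                    summed, labels["emg"], labels["acti"], labels["video"], grid
                )

        stage = "movement_load"
        load = gs.movement_load(counts.get("L"), counts.get("R"), hyp) if counts else None
    except Exception as exc:
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc

    return {
        "participant_id": manifest.participant_id,
        "hypnogram": hyp,
        "periods": periods,
        "grid": grid,
        "counts": counts,
        "labels": labels,
        "pairs": pairs,
        "burden": burden,
        "overlap": overlap,
        "stratified": stratified,
        "movement_load": load,
        "config_hash": cfg.hash(),
    }


def _sum_counts(series: list[ActivityCountSeries]) -> ActivityCountSeries:
    """Bilateral sum of 1 Hz count series (movement-load convention)."""
    if len(series) == 1:
        return series[0]
    n = min(len(s) for s in series)
    total = sum(s.values[:n] for s in series)
    return ActivityCountSeries(values=total, side="merged", start_time=series[0].start_time)


def run_study(
    manifests: list[RecordingManifest], config: AnalysisConfig | None = None
) -> dict:
    """Per-participant analyses plus group-level summaries.

    Computes each bundle via :func:`run_full_analysis`, then: bootstrap mean
    CIs for κ, conditional probabilities and burden across participants;
    Mantel–Haenszel pooled odds ratios per modality pair; and stage-wise
    Wilcoxon signed-rank tests with Holm correction on the movement-load
    table.
    """
    cfg = config or AnalysisConfig()
    bundles = [run_full_analysis(m, cfg) for m in manifests]
    group: dict = {"participants": [b["participant_id"] for b in bundles]}

    pair_stats: dict = {}
    for pair in MODALITY_PAIRS:
        per = [b["pairs"][pair] for b in bundles if pair in b["pairs"]]
        if len(per) < 2:
            continue
        entry: dict = {}
        for stat in ("kappa", "p_a1_given_b1", "p_b1_given_a1", "p_a0_given_b0", "p_b0_given_a0"):
            vals = [p[stat] for p in per]
            mean, ci = cc.bootstrap_group_ci(
                vals, n_boot=cfg.bootstrap_n, seed=cfg.bootstrap_seed
            )
            entry[stat] = {"values": vals, "mean": mean, "ci": ci}
        tables = [p["table"] for p in per]
        try:
            or_pooled, or_ci = cc.pooled_odds_ratio(tables)
            entry["pooled_or"] = {"value": or_pooled, "ci": or_ci}
        except ValueError:
            entry["pooled_or"] = {"value": float("nan"), "ci": (float("nan"),) * 2}
        pair_stats[pair] = entry
    group["pairs"] = pair_stats

    burden_stats: dict = {}
    for modality in ("emg", "acti", "video"):
        for metric in ("activity_ratio", "activity_rate"):
            vals = [
                b["burden"][modality][metric]
                for b in bundles
                if modality in b["burden"]
            ]
            if len(vals) >= 2:
                mean, ci = cc.bootstrap_group_ci(
                    vals, n_boot=cfg.bootstrap_n, seed=cfg.bootstrap_seed
                )
                burden_stats[(modality, metric)] = {
                    "values": vals, "mean": mean,
                    "sd": float(np.std(vals, ddof=1)), "ci": ci,
                }
    group["burden"] = burden_stats

    loads = [b["movement_load"] for b in bundles if b["movement_load"] is not None]
    if len(loads) >= 2:
        table = gs.movement_load_table(loads, ids=[b["participant_id"] for b in bundles if b["movement_load"] is not None])
        group["movement_load_table"] = table
        group["stage_tests"] = gs.wilcoxon_holm(table)

    return {"bundles": bundles, "group": group, "config_hash": cfg.hash()}


def _read_envelope_csv(path, side: str) -> EmgEnvelope:
    df = pd.read_csv(path, comment="#")
    for c in ("time_s", "envelope_uv"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    t = df["time_s"].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(t)))
    return EmgEnvelope(
        rate=rate, values=df["envelope_uv"].to_numpy(dtype=float),
        side=side, start_time=float(t[0]),
    )
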