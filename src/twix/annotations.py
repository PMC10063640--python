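"""Multi-rater skill and explanation annotations.

Human raters annotate each video sample with (a) an ordinal skill score and
(b) segments of time considered relevant to that assessment.  This module
represents those annotations, converts time segments to per-frame binary
relevance masks, aggregates across raters (intersection by default, the
conservative convention: a frame counts as relevant only when every rater
flagged it), measures rater agreement, and summarizes annotations as
normalized-time heatmaps.

Conventions (stated once, used everywhere):

* time segments are half-open ``[start, end)`` in seconds;
* frame ``t`` (0-based) covers ``[t/fps, (t+1)/fps)`` and belongs to a
  segment iff its midpoint ``(t + 0.5)/fps`` lies inside it;
* overlapping or touching segments from one rater are merged before use.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TimeSegment",
    "ExplanationAnnotation",
    "ExplanationMask",
    "SkillAnnotation",
    "HeatmapCurve",
    "canonicalize_segments",
    "segments_to_mask",
    "mask_to_segments",
    "aggregate_explanation_masks",
    "aggregate_skill_scores",
    "interrater_iou",
    "percent_agreement",
    "heatmap_normalized_time",
    "load_annotations",
    "save_annotations",
    "heatmap_to_csv",
]

#: default ordering of string skill levels, most severe first
SKILL_LEVELS = ("low", "intermediate", "high")


@dataclass(frozen=True)
class TimeSegment:
    """Half-open time interval ``[start, end)`` in seconds."""

    start: float
    end: float

    def __post_init__(self):
        if not (np.isfinite(self.start) and np.isfinite(self.end)):
            raise ValueError(f"segment bounds must be finite, got {self}")
        if self.start < 0:
            raise ValueError(f"segment start must be non-negative, got {self}")
        if not self.start < self.end:
            raise ValueError(f"segment start must precede end, got {self}")

    @property
    def length(self) -> float:
        return self.end - self.start


def canonicalize_segments(segments: Iterable[TimeSegment]) -> list[TimeSegment]:
    """Sort by start and merge overlapping or touching segments."""
    segs = sorted(segments, key=lambda s: (s.start, s.end))
    merged: list[TimeSegment] = []
    for s in segs:
        if merged and s.start <= merged[-1].end:
            last = merged.pop()
            s = TimeSegment(last.start, max(last.end, s.end))
        merged.append(s)
    return merged


@dataclass
class ExplanationAnnotation:
    """One rater's relevant time segments for one video sample."""

    rater_id: str
    segments: list[TimeSegment] = field(default_factory=list)

    def __post_init__(self):
        self.segments = canonicalize_segments(self.segments)


@dataclass
class ExplanationMask:
    """Binary per-frame relevance vector ``y_t`` at a fixed frame rate."""

    values: np.ndarray
    frame_rate: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("mask must be a non-empty 1-D vector")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be binary")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.values = v.astype(np.int8)

    def __len__(self) -> int:
        return self.values.size

    @property
    def prevalence(self) -> float:
        """Fraction of frames marked relevant."""
        return float(self.values.mean())


@dataclass(frozen=True)
class SkillAnnotation:
    """One rater's ordinal skill score (int index or named level)."""

    rater_id: str
    score: int | str


@dataclass
class HeatmapCurve:
    """Mean relevance over normalized time (0 = sample start, 1 = end)."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must align")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("heatmap values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# segment <-> mask conversion


def segments_to_mask(
    segments: Sequence[TimeSegment], duration: float, frame_rate: float = 1.0
) -> ExplanationMask:
    """Rasterize time segments into a per-frame binary mask.

    Frame membership is decided by the frame midpoint under the half-open
    ``[start, end)`` convention; ``T = round(duration * frame_rate)``.
    An empty segment list yields an all-zero mask.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    for s in segments:
        if s.end > duration + 1e-9:
            raise ValueError(f"segment {s} exceeds sample duration {duration} s")
    T = int(round(duration * frame_rate))
    mid = (np.arange(T) + 0.5) / frame_rate
    values = np.zeros(T, dtype=np.int8)
    for s in canonicalize_segments(segments):
        values[(mid >= s.start) & (mid < s.end)] = 1
    return ExplanationMask(values, frame_rate)


def mask_to_segments(mask: ExplanationMask) -> list[TimeSegment]:
    """Inverse rasterization: maximal runs of 1-frames as time segments."""
    v = np.concatenate([[0], mask.values, [0]])
    starts = np.flatnonzero(np.diff(v) == 1)
    ends = np.flatnonzero(np.diff(v) == -1)
    fps = mask.frame_rate
    return [TimeSegment(a / fps, b / fps) for a, b in zip(starts, ends)]


# ---------------------------------------------------------------------------
# aggregation and agreement


def aggregate_explanation_masks(
    masks: Sequence[ExplanationMask], mode: str = "intersection"
) -> ExplanationMask:
    """Combine rater masks elementwise: ``intersection`` (AND) or ``union`` (OR)."""
    if not masks:
        raise ValueError("need at least one mask")
    T = len(masks[0])
    fps = masks[0].frame_rate
    for m in masks[1:]:
        if len(m) != T or m.frame_rate != fps:
            raise ValueError(
                f"mask length/frame-rate mismatch: ({len(m)}, {m.frame_rate}) "
                f"vs ({T}, {fps})"
            )
    stacked = np.stack([m.values for m in masks])
    if mode == "intersection":
        values = stacked.min(axis=0)
    elif mode == "union":
        values = stacked.max(axis=0)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return ExplanationMask(values, fps)


def _score_rank(score: int | str, levels: Sequence[str]) -> int:
    if isinstance(score, str):
        if score not in levels:
            raise ValueError(f"score {score!r} not in levels {levels}")
        return levels.index(score)
    return int(score)


def aggregate_skill_scores(
    annotations: Sequence[SkillAnnotation], levels: Sequence[str] = SKILL_LEVELS
):
    """Resolve rater disagreement by taking the lowest (most severe) score."""
    if not annotations:
        raise ValueError("need at least one skill annotation")
    kinds = {isinstance(a.score, str) for a in annotations}
    if len(kinds) > 1:
        raise ValueError("cannot mix named and integer skill scores")
    return min((a.score for a in annotations), key=lambda s: _score_rank(s, levels))


def interrater_iou(a: ExplanationMask, b: ExplanationMask) -> float:
    """Intersection-over-union of two rater masks.

    Two all-zero masks agree vacuously (nothing was deemed important); that
    case returns 1.0 with a warning rather than 0/0.
    """
    if len(a) != len(b):
        raise ValueError("masks must have equal length")
    union = int(np.maximum(a.values, b.values).sum())
    if union == 0:
        warnings.warn("both masks are empty; IoU defined as 1.0", stacklevel=2)
        return 1.0
    inter = int(np.minimum(a.values, b.values).sum())
    return inter / union


def percent_agreement(a: Sequence, b: Sequence) -> float:
    """Fraction of paired samples on which two raters give identical scores."""
    if len(a) != len(b):
        raise ValueError("paired score lists must have equal length")
    if len(a) == 0:
        raise ValueError("cannot compute agreement on an empty pairing")

    def val(x):
        return x.score if isinstance(x, SkillAnnotation) else x

    return float(np.mean([val(x) == val(y) for x, y in zip(a, b)]))


# ---------------------------------------------------------------------------
# normalized-time heatmap


def heatmap_normalized_time(
    masks: Sequence[ExplanationMask], n_bins: int = 100
) -> HeatmapCurve:
    """Average masks of unequal length over a common normalized-time axis.

    Frame ``t`` of a length-``T`` mask maps to normalized time
    ``(t + 0.5)/T``; each of ``n_bins`` equal-width bins over [0, 1] averages
    all pooled frame values falling in it.  Bins that receive no frame are
    filled by linear interpolation between populated neighbours (edge bins
    clamp to the nearest populated value).
    """
    if not masks:
        raise ValueError("need at least one mask")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for m in masks:
        T = len(m)
        pos = (np.arange(T) + 0.5) / T
        idx = np.minimum((pos * n_bins).astype(int), n_bins - 1)
        np.add.at(sums, idx, m.values)
        np.add.at(counts, idx, 1)
    centers = (np.arange(n_bins) + 0.5) / n_bins
    filled = counts > 0
    values = np.empty(n_bins)
    values[filled] = sums[filled] / counts[filled]
    if not filled.all():
        values[~filled] = np.interp(
            centers[~filled], centers[filled], values[filled]
        )
    return HeatmapCurve(centers, values)


# ---------------------------------------------------------------------------
# file I/O
#
# Annotations file schema (JSON):
# {
#   "frame_rate": 1.0,
#   "samples": {
#     "<sample_id>": {
#       "duration_s": 25.0,
#       "raters": [
#         {"rater_id": "r0", "skill_score": "low",
#          "segments": [[2.0, 4.5], [10.0, 12.0]]},
#         ...
#       ]
#     }, ...
#   }
# }


def save_annotations(
    path: str | Path,
    frame_rate: float,
    durations: dict[str, float],
    skill: dict[str, list[SkillAnnotation]],
    explanations: dict[str, list[ExplanationAnnotation]],
) -> None:
    samples = {}
    for sid, dur in durations.items():
        raters = []
        expl = {a.rater_id: a for a in explanations.get(sid, [])}
        for sk in skill.get(sid, []):
            raters.append(
                {
                    "rater_id": sk.rater_id,
                    "skill_score": sk.score,
                    "segments": [
                        [s.start, s.end]
                        for s in (expl[sk.rater_id].segments if sk.rater_id in expl else [])
                    ],
                }
            )
        samples[sid] = {"duration_s": dur, "raters": raters}
    payload = {"frame_rate": frame_rate, "samples": samples}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_annotations(path: str | Path):
    """Load the annotations JSON; returns (frame_rate, durations, skill, explanations)."""
    payload = json.loads(Path(path).read_text())
    frame_rate = float(payload["frame_rate"])
    durations: dict[str, float] = {}
    skill: dict[str, list[SkillAnnotation]] = {}
    explanations: dict[str, list[ExplanationAnnotation]] = {}
    for sid, rec in payload["samples"].items():
        durations[sid] = float(rec["duration_s"])
        skill[sid] = []
        explanations[sid] = []
        for r in rec["raters"]:
            skill[sid].append(SkillAnnotation(r["rater_id"], r["skill_score"]))
            if r["segments"]:
                explanations[sid].append(
                    ExplanationAnnotation(
                        r["rater_id"],
                        [TimeSegment(a, b) for a, b in r["segments"]],
                    )
                )
    return frame_rate, durations, skill, explanations


def heatmap_to_csv(curve: HeatmapCurve, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bin_center", "mean_relevance"])
        for c, v in zip(curve.grid, curve.values):
            w.writerow([f"{c:.6f}", f"{v:.6f}"])
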