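"""Reliability and fairness metrics for frame-level explanations.

Reliability compares real-valued frame-importance scores against the human
explanation mask: sweeping a threshold over the (normalized) scores yields a
precision–recall curve, and its area (AUPRC, computed as right-step average
precision over the distinct score values — no interpolation) is the summary
reliability measure.  Fairness stratifies that measure across sub-cohorts:
the minimum sub-cohort AUPRC is the worst-case AUPRC, and the max−min spread
is the explanation bias gap.  Classification quality is measured by ROC AUC.
Cross-fold aggregation reports mean, sample standard deviation and a normal
95% confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import sklearn.metrics

__all__ = [
    "ImportanceScores",
    "PRCurve",
    "ReliabilityReport",
    "BiasReport",
    "FoldSummary",
    "normalize_scores",
    "pr_curve",
    "auprc",
    "pooled_reliability",
    "stratify_by_cohort",
    "roc_auc",
    "fold_summary",
]

#: explanation sources whose scores are already probabilities in [0, 1]
_PROBABILITY_SOURCES = {"twix"}


@dataclass
class ImportanceScores:
    """Per-frame real importance scores from one explanation source.

    ``source`` is one of ``attention`` (final-layer classification-token
    attention of a model trained without explanation supervision),
    ``attention_with_twix`` (same read-out after TWIX training) or ``twix``
    (the supervised importance head's probabilities).
    """

    values: np.ndarray
    source: str = "attention"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("scores must be a non-empty 1-D vector")
        self.values = v

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auprc: float


@dataclass
class FoldSummary:
    mean: float
    sd: float
    ci95: tuple[float, float]

    @property
    def ci95_halfwidth(self) -> float:
        return (self.ci95[1] - self.ci95[0]) / 2.0


@dataclass
class ReliabilityReport:
    per_fold: list[float]
    summary: FoldSummary
    explanation_source: str
    site: str = ""


@dataclass
class BiasReport:
    group_variable: str
    per_subcohort: dict[str, dict] = field(default_factory=dict)
    worst_case: float = float("nan")
    worst_subcohort: str = ""
    bias_gap: float = float("nan")
    threshold: float | None = None


# ---------------------------------------------------------------------------
# score normalization and PR curves


def normalize_scores(scores: ImportanceScores) -> ImportanceScores:
    """Min–max rescale scores to [0, 1] per sample.

    TWIX-head outputs are already probabilities and pass through unchanged.
    Constant score vectors carry no ranking information and map to 0.5
    everywhere, with a warning.
    """
    if scores.source in _PROBABILITY_SOURCES:
        return scores
    v = scores.values
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("constant scores: no ranking information, mapped to 0.5",
                      stacklevel=2)
        return ImportanceScores(np.full_like(v, 0.5), scores.source)
    return ImportanceScores((v - lo) / (hi - lo), scores.source)


def pr_curve(scores, mask) -> PRCurve:
    """Precision–recall curve of frame scores against the human mask.

    Thresholds are the distinct score values in descending order; at each
    threshold θ the frames with score ≥ θ are predicted important.  The area
    is the step integral Σ_k (R_k − R_{k−1}) P_k (average precision).
    """
    s = np.asarray(scores.values if isinstance(scores, ImportanceScores) else scores,
                   dtype=float)
    y = np.asarray(mask.values if hasattr(mask, "values") else mask)
    if s.shape != y.shape:
        raise ValueError(f"scores ({s.shape}) and mask ({y.shape}) must align")
    P = int(y.sum())
    if P == 0:
        raise ValueError(
            "explanation mask has no positive frame; reliability is defined "
            "on annotated low-skill samples only"
        )
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # last index of each distinct score value = that threshold's cut
    last = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    precision = tp[last] / (tp[last] + fp[last])
    recall = tp[last] / P
    area = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return PRCurve(s_sorted[last], precision, recall, area)


def auprc(scores, mask) -> float:
    """Area under the precision–recall curve (average precision)."""
    return pr_curve(scores, mask).auprc


def pooled_reliability(
    scored_samples: Sequence[tuple[ImportanceScores, "ExplanationMask"]],
    fold_id: int | None = None,
) -> float | None:
    """One fold's AUPRC: pool frames across the fold's annotated samples.

    Scores are normalized per sample first, then all frames enter a single
    score/mask pair (one curve per fold rather than a mean of per-sample
    areas).  Returns ``None`` with a warning when the fold has no annotated
    sample or no positive frame.
    """
    if not scored_samples:
        warnings.warn(f"fold {fold_id}: no annotated samples, skipped",
                      stacklevel=2)
        return None
    pooled_s, pooled_y = [], []
    for sc, mask in scored_samples:
        if len(sc) != len(mask):
            raise ValueError("scores and mask must have equal length")
        pooled_s.append(normalize_scores(sc).values)
        pooled_y.append(np.asarray(mask.values))
    s = np.concatenate(pooled_s)
    y = np.concatenate(pooled_y)
    if y.sum() == 0:
        warnings.warn(f"fold {fold_id}: no positive frame, skipped", stacklevel=2)
        return None
    return pr_curve(s, y).auprc


# ---------------------------------------------------------------------------
# fairness


def stratify_by_cohort(
    fold_samples: Sequence[Sequence[tuple[ImportanceScores, "ExplanationMask", object]]],
    group_variable: str,
    threshold: float | str | None = None,
) -> BiasReport:
    """Per-sub-cohort reliability, worst case and bias gap.

    ``fold_samples`` holds, per fold, the annotated test samples as
    (scores, mask, covariate value) triples.  Continuous covariates are cut
    at ``threshold`` (default: the median over all provided values, the
    balanced-cohort convention); categorical covariates partition by value.
    Per-fold pooled AUPRC is computed within each sub-cohort, aggregated as
    the cross-fold mean; folds where a sub-cohort is empty are skipped for
    it (counted), and a sub-cohort empty in every fold is an error.
    """
    all_values = [v for fold in fold_samples for (_, _, v) in fold]
    if not all_values:
        raise ValueError("no annotated samples provided")
    numeric = all(isinstance(v, (int, float, np.floating, np.integer))
                  for v in all_values)
    used_threshold: float | None = None
    if numeric:
        used_threshold = float(np.median(all_values)) if threshold is None \
            else float(threshold)

        def group_of(v):
            return (f"{group_variable}<={used_threshold:g}"
                    if v <= used_threshold else f"{group_variable}>{used_threshold:g}")
    else:
        def group_of(v):
            return str(v)

    groups = sorted({group_of(v) for v in all_values})
    if len(groups) < 2:
        raise ValueError(
            f"cut rule for {group_variable!r} yields a single sub-cohort")

    report = BiasReport(group_variable, threshold=used_threshold)
    means = {}
    for g in groups:
        per_fold, skipped = [], 0
        for fid, fold in enumerate(fold_samples):
            members = [(sc, m) for (sc, m, v) in fold if group_of(v) == g]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val = pooled_reliability(members, fold_id=fid)
            if val is None:
                skipped += 1
            else:
                per_fold.append(val)
        if not per_fold:
            raise ValueError(f"sub-cohort {g!r} empty in every fold")
        means[g] = float(np.mean(per_fold))
        report.per_subcohort[g] = {
            "per_fold": per_fold,
            "mean": means[g],
            "n_folds_skipped": skipped,
        }
    worst = min(means, key=means.get)
    report.worst_case = means[worst]
    report.worst_subcohort = worst
    report.bias_gap = max(means.values()) - min(means.values())
    return report


# ---------------------------------------------------------------------------
# classification and cross-fold summaries


def roc_auc(class_probs: np.ndarray, labels: Sequence[int]) -> float:
    """ROC AUC: P(random positive outranks random negative), ties ½.

    Binary uses the probability of class 1 (higher skill); multi-class uses
    macro-averaged one-vs-rest.
    """
    probs = np.asarray(class_probs, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("ROC AUC requires both classes present")
    if probs.ndim == 1 or probs.shape[1] == 2:
        score = probs if probs.ndim == 1 else probs[:, 1]
        return float(sklearn.metrics.roc_auc_score(y, score))
    return float(sklearn.metrics.roc_auc_score(
        y, probs, multi_class="ovr", average="macro"))


def fold_summary(per_fold_values: Sequence[float]) -> FoldSummary:
    """Mean, sample sd (n−1) and normal 95% CI across folds."""
    vals = np.asarray(per_fold_values, dtype=float)
    if vals.size < 2:
        raise ValueError("fold summary requires at least two folds")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    half = 1.96 * sd / np.sqrt(vals.size)
    return FoldSummary(mean, sd, (mean - half, mean + half))
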