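"""Cross-validation and multi-site deployment harness.

Implements the evaluation protocol around the classifier: repeated
Monte Carlo cross-validation with video-disjoint, class-balanced
train/validation/test splits on the training site; per-fold training with
and without explanation supervision; deployment of every fold's model to
held-out sites (inference only); reliability, fairness and classification
reports; and deterministic end-to-end reproduction from a single master
seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import heatmap_normalized_time, heatmap_to_csv
from .evaluation import (
    BiasReport,
    FoldSummary,
    ReliabilityReport,
    fold_summary,
    pooled_reliability,
    pr_curve,
    normalize_scores,
    roc_auc,
    stratify_by_cohort,
)
from .model import TwixSkillClassifier
from .synthetic import GeneratorConfig, SyntheticDataset, generate_dataset, generate_external_site

__all__ = [
    "FoldSplit",
    "ExperimentConfig",
    "ResultsBundle",
    "balance_classes",
    "make_monte_carlo_folds",
    "run_training_folds",
    "deploy_on_site",
    "run_full_experiment",
    "write_report",
]


@dataclass
class FoldSplit:
    """Video-disjoint, class-balanced sample-id sets for one fold."""

    fold_id: int
    train: list[str]
    val: list[str]
    test: list[str]


@dataclass
class ExperimentConfig:
    """One full study: training site, deployment sites, model, protocol.

    ``deploy_sites`` maps site name to a dict of generator-field overrides
    (distribution shift).  ``stratify`` lists (group_variable, threshold)
    pairs; threshold None means the median cut for numeric covariates.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    deploy_sites: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    n_folds: int = 10
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    stratify: list = field(default_factory=lambda: [("cohort", None)])
    twix_modes: tuple = (False, True)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.get("generator", {})
        if "event_counts" in gen:
            gen["event_counts"] = {int(k): tuple(v)
                                   for k, v in gen["event_counts"].items()}
        for key in ("duration_range", "event_length_range"):
            if key in gen:
                gen[key] = tuple(gen[key])
        exp = raw.get("experiment", {})
        return cls(
            generator=GeneratorConfig(**gen),
            deploy_sites=raw.get("sites", {}),
            model=raw.get("model", {}),
            n_folds=exp.get("n_folds", 10),
            fractions=tuple(exp.get("fractions", (0.7, 0.1, 0.2))),
            stratify=[tuple(s) for s in exp.get("stratify", [("cohort", None)])],
            twix_modes=tuple(bool(m) for m in exp.get("twix_modes", (False, True))),
            seed=exp.get("seed", 0),
        )


@dataclass
class ResultsBundle:
    metrics: pd.DataFrame
    pr_curves: pd.DataFrame
    reliability: dict
    bias: dict
    heatmap: object
    provenance: dict
    failures: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# splits


def balance_classes(sample_ids: Sequence[str], labels: Sequence[int],
                    seed: int | np.random.Generator) -> list[str]:
    """Random undersampling of majority classes down to the minority count."""
    ids = np.asarray(sample_ids)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("balancing requires at least two classes present")
    n_min = counts.min()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    keep: list[str] = []
    for k in classes:
        members = ids[y == k]
        if members.size > n_min:
            members = rng.choice(members, size=n_min, replace=False)
        keep.extend(members.tolist())
    order = {s: i for i, s in enumerate(sample_ids)}
    return sorted(keep, key=order.get)


def make_monte_carlo_folds(
    dataset: SyntheticDataset,
    n_folds: int = 10,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> list[FoldSplit]:
    """Independent random video-disjoint splits, class-balanced per set.

    Each fold shuffles the parent videos and partitions them by the given
    fractions into train/val/test; samples inherit their video's set, then
    each set is independently undersampled to class balance.  Folds are
    independent draws (Monte Carlo), not a rotating partition.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    videos = sorted({s.video_id for s in dataset.samples})
    if len(videos) < 3:
        raise ValueError("need at least three videos for disjoint splits")
    by_video: dict[str, list[str]] = {}
    for s in dataset.samples:
        by_video.setdefault(s.video_id, []).append(s.sample_id)
    rng = np.random.default_rng(seed)
    folds = []
    for fid in range(n_folds):
        perm = list(rng.permutation(videos))
        n_train = max(1, int(round(fractions[0] * len(videos))))
        n_val = max(1, int(round(fractions[1] * len(videos))))
        n_train = min(n_train, len(videos) - n_val - 1)
        sets = {
            "train": perm[:n_train],
            "val": perm[n_train:n_train + n_val],
            "test": perm[n_train + n_val:],
        }
        out = {}
        for name, vids in sets.items():
            sids = [sid for v in vids for sid in by_video[v]]
            labels = dataset.labels(sids)
            if np.unique(labels).size < dataset.config.n_classes:
                raise ValueError(
                    f"fold {fid}: {name} set is missing a class; "
                    "use a larger dataset or more videos")
            out[name] = balance_classes(sids, labels, rng)
        folds.append(FoldSplit(fid, out["train"], out["val"], out["test"]))
    return folds


# ---------------------------------------------------------------------------
# training and deployment


def _annotated(dataset: SyntheticDataset, sids: Sequence[str]):
    """(sample, mask, cohort) for the annotated low-skill samples among sids."""
    out = []
    for sid in sids:
        mask = dataset.rater_mask(sid)
        if mask is not None:
            out.append((dataset.sample(sid), mask,
                        dataset.sample(sid).cohort))
    return out


def _sources_for(twix: bool) -> tuple[str, ...]:
    return ("attention_with_twix", "twix") if twix else ("attention",)


def _scored(est: TwixSkillClassifier, annotated, source: str):
    kind = "twix" if source == "twix" else "attention"
    scores = est.explain([s for s, _, _ in annotated], kind)
    return [(sc, mask) for sc, (_, mask, _) in zip(scores, annotated)]


def _scored_with_cov(est, annotated, source: str, group_variable: str):
    kind = "twix" if source == "twix" else "attention"
    scores = est.explain([s for s, _, _ in annotated], kind)
    return [(sc, mask, cov[group_variable])
            for sc, (_, mask, cov) in zip(scores, annotated)]


def run_training_folds(
    dataset: SyntheticDataset,
    folds: Sequence[FoldSplit],
    twix: bool,
    model_kwargs: dict | None = None,
    seed: int = 0,
):
    """Train one model per fold; returns (estimators, in-site metric rows).

    Metric rows carry the fold's test-set classification AUC and, per
    explanation source, the pooled explanation AUPRC over annotated
    low-skill test samples.
    """
    model_kwargs = dict(model_kwargs or {})
    fold_seeds = np.random.SeedSequence(seed).spawn(len(folds))
    estimators, rows, curves = [], [], []
    for split, fseed in zip(folds, fold_seeds):
        X = [dataset.sample(s) for s in split.train]
        y = dataset.labels(split.train)
        masks = [dataset.rater_mask(s) for s in split.train]
        X_val = [dataset.sample(s) for s in split.val]
        y_val = dataset.labels(split.val)
        est = TwixSkillClassifier(
            twix=twix, random_state=int(fseed.generate_state(1)[0] % (2 ** 31)),
            **model_kwargs)
        est.fit(X, y, masks=masks, validation=(X_val, y_val))
        estimators.append(est)

        X_test = [dataset.sample(s) for s in split.test]
        y_test = dataset.labels(split.test)
        auc = roc_auc(est.predict_proba(X_test), y_test)
        annotated = _annotated(dataset, split.test)
        for source in _sources_for(twix):
            pairs = _scored(est, annotated, source)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                au = pooled_reliability(pairs, fold_id=split.fold_id)
            rows.append({"site": dataset.site, "explanation_source": source,
                         "group_variable": "all", "subcohort": "all",
                         "fold": split.fold_id, "auprc": au, "auc": auc})
            curves.append((dataset.site, source, split.fold_id, pairs))
    return estimators, rows, curves


def deploy_on_site(
    estimators: Sequence[TwixSkillClassifier],
    site_dataset: SyntheticDataset,
    twix: bool,
    seed: int = 0,
):
    """Inference-only evaluation of every fold model on a held-out site.

    Classification AUC uses a class-balanced draw of the site's samples
    (one draw per fold, seeded); explanation AUPRC pools all annotated
    low-skill site samples.  Site data never enter training.
    """
    rng = np.random.default_rng(seed)
    all_ids = [s.sample_id for s in site_dataset.samples]
    labels = site_dataset.labels(all_ids)
    annotated = _annotated(site_dataset, all_ids)
    rows, curves = [], []
    for fid, est in enumerate(estimators):
        balanced = balance_classes(all_ids, labels, rng)
        Xb = [site_dataset.sample(s) for s in balanced]
        yb = site_dataset.labels(balanced)
        auc = roc_auc(est.predict_proba(Xb), yb)
        for source in _sources_for(twix):
            pairs = _scored(est, annotated, source)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                au = pooled_reliability(pairs, fold_id=fid)
            rows.append({"site": site_dataset.site,
                         "explanation_source": source,
                         "group_variable": "all", "subcohort": "all",
                         "fold": fid, "auprc": au, "auc": auc})
            curves.append((site_dataset.site, source, fid, pairs))
    return rows, curves


# ---------------------------------------------------------------------------
# full experiment


def run_full_experiment(config: ExperimentConfig) -> ResultsBundle:
    """Generate all sites, train per fold with/without TWIX, deploy, report."""
    ss = np.random.SeedSequence(config.seed)
    s_gen, s_folds, s_train, s_deploy = (int(c.generate_state(1)[0] % (2 ** 31))
                                         for c in ss.spawn(4))
    train_ds = generate_dataset(
        dataclasses.replace(config.generator, seed=s_gen))
    site_datasets = {train_ds.site: train_ds}
    site_seeds = np.random.SeedSequence(s_gen).spawn(len(config.deploy_sites) + 1)
    for i, (site, shift) in enumerate(sorted(config.deploy_sites.items())):
        site_datasets[site] = generate_external_site(
            config.generator, shift, site=site,
            seed=int(site_seeds[i + 1].generate_state(1)[0] % (2 ** 31)))

    folds = make_monte_carlo_folds(train_ds, config.n_folds,
                                   config.fractions, s_folds)
    # protocol invariant: deployment sites never contribute training samples
    train_ids = {sid for f in folds for sid in f.train + f.val}
    for site, ds in site_datasets.items():
        if site != train_ds.site:
            assert train_ids.isdisjoint(s.sample_id for s in ds.samples)

    rows, curve_records, failures = [], [], []
    bias: dict = {}
    reliability: dict = {}
    for twix in config.twix_modes:
        try:
            # both modes share the training seed: per fold, the runs with
            # and without the importance head start from identical
            # initialization and batch order, so their comparison isolates
            # the effect of explanation supervision (a paired design)
            ests, in_rows, in_curves = run_training_folds(
                train_ds, folds, twix, config.model, seed=s_train)
        except Exception as exc:  # partial failure: mark and continue
            failures.append({"cell": f"train twix={twix}", "error": str(exc)})
            continue
        rows.extend(in_rows)
        curve_records.extend(in_curves)
        per_fold_annot = {train_ds.site: [
            (_annotated(train_ds, f.test), est)
            for f, est in zip(folds, ests)]}
        for site, ds in site_datasets.items():
            if site == train_ds.site:
                continue
            d_rows, d_curves = deploy_on_site(ests, ds, twix, seed=s_deploy)
            rows.extend(d_rows)
            curve_records.extend(d_curves)
            annotated = _annotated(ds, [s.sample_id for s in ds.samples])
            per_fold_annot[site] = [(annotated, est) for est in ests]

        # reliability summaries and stratified bias per site and source
        for site, fold_items in per_fold_annot.items():
            for source in _sources_for(twix):
                vals = [r["auprc"] for r in rows
                        if r["site"] == site and r["auprc"] is not None
                        and r["explanation_source"] == source
                        and r["group_variable"] == "all"]
                if len(vals) >= 2:
                    reliability[(site, source)] = ReliabilityReport(
                        vals, fold_summary(vals), source, site)
                for gvar, thr in config.stratify:
                    per_fold = []
                    for annotated, est in fold_items:
                        per_fold.append(
                            _scored_with_cov(est, annotated, source, gvar))
                    try:
                        report = stratify_by_cohort(per_fold, gvar, thr)
                    except ValueError as exc:
                        failures.append(
                            {"cell": f"bias {site}/{source}/{gvar}",
                             "error": str(exc)})
                        continue
                    bias[(site, source, gvar)] = report
                    for sub, rec in report.per_subcohort.items():
                        for pos, val in enumerate(rec["per_fold"]):
                            rows.append({
                                "site": site, "explanation_source": source,
                                "group_variable": gvar, "subcohort": sub,
                                "fold": pos, "auprc": val, "auc": np.nan})

    metrics = pd.DataFrame(rows)
    pr_rows = []
    for site, source, fid, pairs in curve_records:
        if not pairs:
            continue
        s = np.concatenate([normalize_scores(sc).values for sc, _ in pairs])
        y = np.concatenate([np.asarray(m.values) for _, m in pairs])
        if y.sum() == 0:
            continue
        curve = pr_curve(s, y)
        for thr, p, r in zip(curve.thresholds, curve.precision, curve.recall):
            pr_rows.append({"site": site, "source": source, "fold": fid,
                            "threshold": thr, "precision": p, "recall": r})
    heat_masks = [m for m in
                  (train_ds.rater_mask(s.sample_id) for s in train_ds.samples)
                  if m is not None]
    heatmap = heatmap_normalized_time(heat_masks) if heat_masks else None
    provenance = {
        "config": json.loads(json.dumps(dataclasses.asdict(config),
                                        default=str)),
        "seed": config.seed,
        "n_samples": {site: len(ds.samples)
                      for site, ds in site_datasets.items()},
    }
    return ResultsBundle(metrics, pd.DataFrame(pr_rows), reliability, bias,
                         heatmap, provenance, failures)


# ---------------------------------------------------------------------------
# cohort-bias replicate study


def run_bias_study(
    generator: GeneratorConfig | None = None,
    cohort_effect: dict | None = None,
    n_replicates: int = 10,
    n_folds: int = 3,
    model_kwargs: dict | None = None,
    group_variable: str = "cohort",
    modes: tuple = (True, False),
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated audit of explanation bias under an injected cohort effect.

    Each replicate regenerates a training site (with ``cohort_effect``
    applied to one sub-cohort, e.g. a rater-jitter multiplier degrading its
    annotation quality), trains fold models with and without explanation
    supervision, and stratifies each source's reliability by cohort.  One
    row per replicate: the bias gap and worst-case AUPRC for the TWIX and
    attention sources.  ``cohort_effect=None`` gives the no-effect control.

    The default three folds per replicate keep a ten-replicate study at
    desk scale while still averaging fold noise within each replicate.
    """
    generator = generator or GeneratorConfig(n_videos=10, samples_per_video=12)
    effect = dict(cohort_effect or {})
    rows = []
    rep_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    for rep, rseed in enumerate(rep_seeds):
        s_gen, s_fold, s_tw, s_no = (int(c.generate_state(1)[0] % (2 ** 31))
                                     for c in rseed.spawn(4))
        ds = generate_dataset(dataclasses.replace(
            generator, seed=s_gen, cohort_effect=effect))
        folds = make_monte_carlo_folds(ds, n_folds, seed=s_fold)
        rec = {"replicate": rep}
        for twix, tseed in ((True, s_tw), (False, s_no)):
            if twix not in modes:
                continue
            ests, _, _ = run_training_folds(ds, folds, twix, model_kwargs,
                                            seed=tseed)
            source = "twix" if twix else "attention"
            per_fold = [
                _scored_with_cov(est, _annotated(ds, f.test), source,
                                 group_variable)
                for f, est in zip(folds, ests)
            ]
            rep_bias = stratify_by_cohort(per_fold, group_variable)
            rec[f"bias_gap_{source}"] = rep_bias.bias_gap
            rec[f"worst_case_{source}"] = rep_bias.worst_case
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting


def write_report(bundle: ResultsBundle, out_dir: str | Path) -> None:
    """Write metrics.csv, pr_curves.csv, bias_report.json, heatmaps.csv,
    summary.md and a config echo under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.metrics.to_csv(out / "metrics.csv", index=False)
    bundle.pr_curves.to_csv(out / "pr_curves.csv", index=False)
    if bundle.heatmap is not None:
        heatmap_to_csv(bundle.heatmap, out / "heatmaps.csv")
    bias_payload = {}
    for (site, source, gvar), rep in bundle.bias.items():
        bias_payload[f"{site}/{source}/{gvar}"] = {
            "group_variable": rep.group_variable,
            "threshold": rep.threshold,
            "per_subcohort": rep.per_subcohort,
            "worst_case": rep.worst_case,
            "worst_subcohort": rep.worst_subcohort,
            "bias_gap": rep.bias_gap,
        }
    (out / "bias_report.json").write_text(
        json.dumps(bias_payload, indent=1, sort_keys=True))
    (out / "config.json").write_text(
        json.dumps(bundle.provenance, indent=1, sort_keys=True))

    lines = ["# Experiment summary", ""]
    if not bundle.metrics.empty:
        lines += ["## Reliability and classification (cross-fold means)", "",
                  "| site | source | AUPRC | AUC |", "|---|---|---|---|"]
        overall = bundle.metrics[bundle.metrics.group_variable == "all"]
        grouped = overall.groupby(["site", "explanation_source"])
        for (site, source), g in grouped:
            au = g.auprc.dropna().mean()
            lines.append(f"| {site} | {source} | {au:.3f} | "
                         f"{g.auc.mean():.3f} |")
        lines.append("")
    if bundle.bias:
        lines += ["## Explanation bias", "",
                  "| site | source | group | worst-case AUPRC | gap |",
                  "|---|---|---|---|---|"]
        for (site, source, gvar), rep in sorted(bundle.bias.items()):
            lines.append(f"| {site} | {source} | {gvar} | "
                         f"{rep.worst_case:.3f} | {rep.bias_gap:.3f} |")
        lines.append("")
    if bundle.failures:
        lines += ["## Failed cells", ""]
        lines += [f"- {f['cell']}: {f['error']}" for f in bundle.failures]
    (out / "summary.md").write_text("\n".join(lines) + "\n")
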