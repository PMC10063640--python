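"""Protocol harness: splits, balancing, deployment, reporting, CLI."""

import numpy as np
import pandas as pd
import pytest

from twix.experiment import (
    ExperimentConfig,
    balance_classes,
    deploy_on_site,
    make_monte_carlo_folds,
    run_full_experiment,
    run_training_folds,
    write_report,
)
from twix.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="module")
def dataset():
    return generate_dataset(GeneratorConfig(n_videos=6, samples_per_video=8,
                                            seed=17))


@pytest.fixture(scope="module")
def tiny_experiment_config():
    return ExperimentConfig(
        generator=GeneratorConfig(n_videos=6, samples_per_video=6, seed=3),
        deploy_sites={"site_b": {"event_amplitude": 2.0}},
        model={"n_epochs": 2},
        n_folds=2,
        seed=99,
    )


class TestBalanceClasses:
    def test_majority_undersampled(self):
        ids = [f"s{i}" for i in range(100)]
        labels = [0] * 40 + [1] * 60
        kept = balance_classes(ids, labels, seed=0)
        y = np.array([labels[int(s[1:])] for s in kept])
        assert len(kept) == 80
        assert (y == 0).sum() == 40 and (y == 1).sum() == 40

    def test_already_balanced_is_identity(self):
        ids = [f"s{i}" for i in range(10)]
        labels = [0, 1] * 5
        assert set(balance_classes(ids, labels, seed=1)) == set(ids)

    def test_three_class_minimum_rule(self):
        ids = [f"s{i}" for i in range(60)]
        labels = [0] * 10 + [1] * 20 + [2] * 30
        kept = balance_classes(ids, labels, seed=2)
        y = np.array([labels[int(s[1:])] for s in kept])
        assert len(kept) == 30
        assert all((y == k).sum() == 10 for k in range(3))

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            balance_classes(["a", "b"], [0, 0], seed=0)


class TestMonteCarloFolds:
    def test_video_disjoint(self, dataset):
        folds = make_monte_carlo_folds(dataset, 5, seed=0)
        for f in folds:
            vids = {name: {dataset.sample(s).video_id for s in getattr(f, name)}
                    for name in ("train", "val", "test")}
            assert not vids["train"] & vids["val"]
            assert not vids["train"] & vids["test"]
            assert not vids["val"] & vids["test"]

    def test_class_balanced_per_set(self, dataset):
        folds = make_monte_carlo_folds(dataset, 5, seed=0)
        for f in folds:
            for name in ("train", "val", "test"):
                labels = dataset.labels(getattr(f, name))
                counts = np.bincount(labels)
                assert counts.size == 2 and counts[0] == counts[1]

    def test_deterministic(self, dataset):
        a = make_monte_carlo_folds(dataset, 4, seed=7)
        b = make_monte_carlo_folds(dataset, 4, seed=7)
        for fa, fb in zip(a, b):
            assert fa.train == fb.train
            assert fa.val == fb.val
            assert fa.test == fb.test

    def test_folds_are_independent_draws(self, dataset):
        folds = make_monte_carlo_folds(dataset, 6, seed=1)
        test_sets = [frozenset(f.test) for f in folds]
        assert len(set(test_sets)) > 1

    def test_too_few_videos_rejected(self):
        ds = generate_dataset(GeneratorConfig(n_videos=2, samples_per_video=4,
                                              seed=0))
        with pytest.raises(ValueError):
            make_monte_carlo_folds(ds, 2, seed=0)


@pytest.fixture(scope="module")
def trained(dataset):
    folds = make_monte_carlo_folds(dataset, 2, seed=3)
    ests, rows, curves = run_training_folds(
        dataset, folds, twix=True, model_kwargs={"n_epochs": 2}, seed=5)
    return dataset, folds, ests, rows, curves


@pytest.fixture(scope="module")
def bundle(tiny_experiment_config):
    return run_full_experiment(tiny_experiment_config)


class TestTrainingAndDeployment:
    def test_one_model_and_metrics_per_fold(self, trained):
        _, folds, ests, rows, _ = trained
        assert len(ests) == len(folds)
        df = pd.DataFrame(rows)
        # twix mode contributes two explanation sources per fold
        assert len(df) == len(folds) * 2
        assert set(df.explanation_source) == {"attention_with_twix", "twix"}

    def test_deployment_rows_per_fold(self, trained):
        dataset, _, ests, _, _ = trained
        site = generate_dataset(GeneratorConfig(
            n_videos=4, samples_per_video=6, seed=77, site="site_b"))
        rows, _ = deploy_on_site(ests, site, twix=True, seed=0)
        df = pd.DataFrame(rows)
        assert (df.groupby("explanation_source").size() == len(ests)).all()
        assert (df.site == "site_b").all()

    def test_shifted_site_auc_degrades(self, dataset):
        # weaker event signal at the deployment site must lower mean AUC
        folds = make_monte_carlo_folds(dataset, 3, seed=3)
        ests, rows, _ = run_training_folds(
            dataset, folds, twix=False, model_kwargs={"n_epochs": 8}, seed=5)
        in_site = pd.DataFrame(rows).auc.mean()
        weak = generate_dataset(GeneratorConfig(
            n_videos=6, samples_per_video=8, seed=31, site="weak",
            event_amplitude=0.7))
        out_rows, _ = deploy_on_site(ests, weak, twix=False, seed=0)
        assert pd.DataFrame(out_rows).auc.mean() < in_site


class TestFullExperiment:
    def test_all_cells_present(self, bundle):
        df = bundle.metrics
        assert set(df.explanation_source) == {
            "attention", "attention_with_twix", "twix"}
        assert set(df.site) == {"site_a", "site_b"}
        # training/deployment cells must never fail; at this tiny scale a
        # bias cell may legitimately be marked skipped (a fold's test set
        # can miss one cohort entirely), but nothing else
        assert all(f["cell"].startswith("bias") for f in bundle.failures)

    def test_report_files_written(self, bundle, tmp_path):
        write_report(bundle, tmp_path / "report")
        out = tmp_path / "report"
        for name in ("metrics.csv", "pr_curves.csv", "bias_report.json",
                     "heatmaps.csv", "summary.md", "config.json"):
            assert (out / name).exists(), name
        # round trip: reloaded metrics equal bundle values
        reloaded = pd.read_csv(out / "metrics.csv")
        assert len(reloaded) == len(bundle.metrics)
        assert np.allclose(reloaded.auc, bundle.metrics.auc, equal_nan=True)

    def test_summary_has_row_per_site_and_source(self, bundle, tmp_path):
        write_report(bundle, tmp_path / "rep2")
        text = (tmp_path / "rep2" / "summary.md").read_text()
        for site in ("site_a", "site_b"):
            assert site in text
        for source in ("attention", "twix"):
            assert source in text


def test_experiment_config_yaml_round_trip(tmp_path):
    payload = """
generator:
  n_videos: 5
  samples_per_video: 4
  event_amplitude: 4.0
sites:
  site_b: {event_amplitude: 2.0}
model:
  n_epochs: 3
experiment:
  n_folds: 4
  seed: 11
  stratify: [[cohort, null]]
"""
    path = tmp_path / "cfg.yaml"
    path.write_text(payload)
    cfg = ExperimentConfig.from_yaml(path)
    assert cfg.generator.n_videos == 5
    assert cfg.deploy_sites == {"site_b": {"event_amplitude": 2.0}}
    assert cfg.n_folds == 4 and cfg.seed == 11
    assert cfg.stratify == [("cohort", None)]


def test_cli_generate_and_report(tmp_path):
    from click.testing import CliRunner

    from twix.cli import cli

    runner = CliRunner()
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text("generator:\n  n_videos: 3\n  samples_per_video: 2\n")
    out = tmp_path / "data"
    res = runner.invoke(cli, ["generate", "--config", str(cfg),
                              "--seed", "4", "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert (out / "annotations.json").exists()
    assert (out / "metadata.csv").exists()

    train_cfg = tmp_path / "train_cfg.yaml"
    train_cfg.write_text(
        "generator:\n  n_videos: 5\n  samples_per_video: 6\n"
        "model:\n  n_epochs: 2\nexperiment:\n  n_folds: 2\n")
    data2 = tmp_path / "data2"
    assert runner.invoke(cli, ["generate", "--config", str(train_cfg),
                               "--seed", "2", "--out", str(data2)]
                         ).exit_code == 0
    models = tmp_path / "models"
    res = runner.invoke(cli, ["train", "--config", str(train_cfg),
                              "--data", str(data2), "--seed", "2",
                              "--out", str(models)])
    assert res.exit_code == 0, res.output
    assert len(list(models.glob("fold_*.npz"))) == 2
    evald = tmp_path / "site_metrics.csv"
    res = runner.invoke(cli, ["evaluate", "--data", str(data2),
                              "--models", str(models), "--out", str(evald)])
    assert res.exit_code == 0, res.output
    assert len(pd.read_csv(evald)) > 0

    metrics = tmp_path / "metrics.csv"
    pd.DataFrame({
        "site": ["site_a"] * 2, "explanation_source": ["twix"] * 2,
        "group_variable": ["all"] * 2, "subcohort": ["all"] * 2,
        "fold": [0, 1], "auprc": [0.9, 0.8], "auc": [0.95, 0.85],
    }).to_csv(metrics, index=False)
    rep = tmp_path / "summary.md"
    res = runner.invoke(cli, ["report", "--metrics", str(metrics),
                              "--out", str(rep)])
    assert res.exit_code == 0, res.output
    assert "twix" in rep.read_text()
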