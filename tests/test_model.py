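"""Encoder, losses, explanations and the estimator contract."""

import math
import warnings

import numpy as np
import pytest

from twix.autograd import Tensor, grad_check
from twix.annotations import ExplanationMask
from twix.evaluation import ImportanceScores
from twix.model import (
    EncoderOutput,
    ModelConfig,
    ModelParams,
    TwixSkillClassifier,
    attention_explanation,
    encode,
    importance_loss,
    init_params,
    load_params,
    predict_batch,
    save_params,
    supervised_infonce_loss,
    total_loss,
    twix_importance,
)
from twix.synthetic import VideoSample


def toy_config(**kw):
    defaults = dict(feature_dim=4, n_streams=2, n_classes=2, model_dim=8,
                    n_layers=1, n_heads=2, ffn_dim=8, max_frames=12, seed=3)
    defaults.update(kw)
    return ModelConfig(**defaults)


def toy_sample(rng, T=6, D=4, M=2, sid="s0"):
    return VideoSample(sid, "v0", "site", [rng.normal(size=(T, D))
                                           for _ in range(M)], 1.0, float(T))


class TestInitAndEncode:
    def test_init_deterministic(self):
        cfg = toy_config()
        a, b = init_params(cfg), init_params(cfg)
        for k in a.tensors:
            assert np.array_equal(a.tensors[k].data, b.tensors[k].data)

    def test_no_importance_head_when_disabled(self):
        params = init_params(toy_config(twix_enabled=False))
        assert not params.omega
        assert params.theta

    def test_initial_importance_outputs_near_half(self, rng):
        params = init_params(toy_config())
        out = encode(toy_sample(rng), params)
        scores = twix_importance(out, params)
        assert np.all((scores.values > 0.4) & (scores.values < 0.6))

    def test_attention_sums_to_one_per_stream(self, rng):
        params = init_params(toy_config())
        out = encode(toy_sample(rng), params)
        for a in out.attention:
            assert a.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(a >= 0)

    def test_single_frame_attention(self, rng):
        params = init_params(toy_config())
        out = encode(toy_sample(rng, T=1), params)
        for a in out.attention:
            assert np.allclose(a, [1.0])

    def test_class_probs_simplex(self, rng):
        params = init_params(toy_config())
        out = encode(toy_sample(rng), params)
        assert out.class_probs.sum() == pytest.approx(1.0)

    def test_permutation_equivariance_without_positions(self, rng):
        cfg = toy_config(use_positions=False)
        params = init_params(cfg)
        sample = toy_sample(rng, T=6)
        perm = np.array([3, 1, 5, 0, 2, 4])
        permuted = VideoSample("s1", "v0", "site",
                               [X[perm] for X in sample.streams], 1.0, 6.0)
        a0 = encode(sample, params).attention
        a1 = encode(permuted, params).attention
        for x, y in zip(a0, a1):
            assert np.allclose(x[perm], y, atol=1e-12)

    def test_stream_mismatch_reported(self, rng):
        params = init_params(toy_config())
        bad = VideoSample("s", "v", "x", [rng.normal(size=(5, 7))] * 2,
                          1.0, 5.0)
        with pytest.raises(ValueError, match="stream 0"):
            encode(bad, params)


class TestExplanationReadouts:
    def test_minmax_endpoints_monotone(self):
        out = EncoderOutput([], np.zeros(2),
                            [np.array([0.1, 0.2, 0.3, 0.4]) / 1.0],
                            np.array([0.5, 0.5]), "attention")
        sc = attention_explanation(out)
        assert sc.values[0] == 0.0 and sc.values[-1] == 1.0
        assert np.all(np.diff(sc.values) > 0)

    def test_stream_mean_by_hand(self):
        out = EncoderOutput([], np.zeros(2),
                            [np.array([0.6, 0.3, 0.1]),
                             np.array([0.2, 0.3, 0.5])],
                            np.array([0.5, 0.5]), "attention")
        sc = attention_explanation(out)
        assert np.allclose(sc.values, [1.0, 0.0, 0.0])

    def test_constant_attention_warns(self):
        out = EncoderOutput([], np.zeros(2), [np.full(4, 0.25)],
                            np.array([0.5, 0.5]), "attention")
        with pytest.warns(UserWarning, match="constant"):
            sc = attention_explanation(out)
        assert np.allclose(sc.values, 0.5)

    def test_twix_disabled_is_error(self, rng):
        params = init_params(toy_config(twix_enabled=False))
        out = encode(toy_sample(rng), params)
        with pytest.raises(ValueError, match="disabled"):
            twix_importance(out, params)

    def test_twix_values_strictly_inside_unit_interval(self, rng):
        params = init_params(toy_config())
        params.tensors["imp_w"].data[:] = rng.normal(size=(8, 1)) * 5
        out = encode(toy_sample(rng), params)
        v = twix_importance(out, params).values
        assert np.all((v > 0) & (v < 1))

    def test_handcrafted_head_flags_event_frames(self):
        # frame reps are +1/-1 indicators in one coordinate; a head reading
        # that coordinate saturates toward 1 inside events
        reps = np.zeros((5, 8))
        reps[:, 0] = [1, 1, -1, -1, -1]
        params = init_params(toy_config())
        params.tensors["imp_w"].data[0, 0] = 6.0
        out = EncoderOutput([reps], np.zeros(8), [np.full(5, 0.2)],
                            np.array([0.5, 0.5]))
        v = twix_importance(out, params).values
        assert np.all(v[:2] > 0.99) and np.all(v[2:] < 0.01)


class TestLosses:
    def test_infonce_orthogonal_closed_form(self):
        V = np.array([[1, 0, 0, 0], [1, 0, 0, 0],
                      [0, 1, 0, 0], [0, 1, 0, 0]], float)
        loss = supervised_infonce_loss(V, [0, 0, 1, 1], 0.1)
        expected = -math.log(math.exp(10) / (math.exp(10) + 2))
        assert loss == pytest.approx(expected, abs=1e-6)

    def test_infonce_identical_reps(self):
        V = np.ones((4, 6))
        loss = supervised_infonce_loss(V, [0, 0, 1, 1], 0.1)
        assert loss == pytest.approx(math.log(3), abs=1e-6)

    def test_infonce_decreases_as_positives_align(self):
        def batch(cos):
            s = math.sqrt(max(1 - cos ** 2, 0.0))
            return np.array([[1, 0, 0], [cos, s, 0],
                             [0, 0, 1], [0, s, cos]], float)

        losses = [supervised_infonce_loss(batch(c), [0, 0, 1, 1], 0.5)
                  for c in (0.2, 0.6, 0.99)]
        assert losses[0] > losses[1] > losses[2]

    def test_infonce_needs_positives(self):
        with pytest.raises(ValueError, match="class-balanced"):
            supervised_infonce_loss(np.eye(3), [0, 1, 2], 0.1)

    def test_importance_loss_half_scores(self):
        T = 9
        loss = importance_loss(np.full(T, 0.5), np.arange(T) % 2)
        assert loss == pytest.approx(T * math.log(2), rel=1e-12)

    def test_importance_loss_perfect_prediction(self):
        y = np.array([1, 0, 0, 1, 0])
        assert importance_loss(y.astype(float), y) < 1e-5

    def test_importance_loss_hand_case(self):
        loss = importance_loss(np.array([0.9, 0.2, 0.1]), np.array([1, 0, 0]))
        assert loss == pytest.approx(0.4338, abs=1e-4)

    def test_importance_loss_requires_mask(self):
        with pytest.raises(ValueError, match="mask"):
            importance_loss(np.array([0.5]), None)
        with pytest.raises(ValueError, match="align"):
            importance_loss(np.array([0.5, 0.5]), np.array([1]))

    def test_total_loss_decomposition(self, rng):
        cfg = toy_config()
        params = init_params(cfg)
        batch = []
        for i in range(4):
            streams = [rng.normal(size=(5, 4)) for _ in range(2)]
            mask = ExplanationMask(np.array([1, 1, 0, 0, 0]), 1.0) \
                if i % 2 == 0 else None
            batch.append((streams, i % 2, mask))
        total, nce, imp = total_loss(batch, cfg, params)
        assert float(total.data) == pytest.approx(
            float(nce.data) + float(imp.data), abs=1e-10)
        assert float(total.data) > float(nce.data)
        assert float(total.data) > float(imp.data)

    def test_total_loss_without_twix_is_infonce(self, rng):
        cfg = toy_config(twix_enabled=False)
        params = init_params(cfg)
        batch = [([rng.normal(size=(5, 4)) for _ in range(2)], i % 2, None)
                 for i in range(4)]
        total, nce, imp = total_loss(batch, cfg, params)
        assert imp is None
        assert float(total.data) == float(nce.data)

    def test_total_loss_warns_without_annotated_samples(self, rng):
        cfg = toy_config()
        params = init_params(cfg)
        batch = [([rng.normal(size=(5, 4)) for _ in range(2)], i % 2, None)
                 for i in range(4)]
        with pytest.warns(UserWarning, match="importance"):
            total, _, imp = total_loss(batch, cfg, params)
        assert float(imp.data) == 0.0

    def test_gradients_match_finite_differences(self, rng):
        cfg = toy_config()
        params = init_params(cfg)
        batch = []
        for i in range(4):
            streams = [rng.normal(size=(5, 4)) for _ in range(2)]
            mask = np.array([1, 1, 0, 0, 0]) if i % 2 == 0 else None
            batch.append((streams, i % 2, mask))

        def fn(tensors):
            total, _, _ = total_loss(batch, cfg, ModelParams(tensors, cfg))
            return total

        assert grad_check(fn, params.tensors) < 1e-4


@pytest.fixture(scope="module")
def trained(small_dataset):
    ds = small_dataset
    vids = sorted({s.video_id for s in ds.samples})
    test_v = set(vids[-2:])
    Xtr = [s for s in ds.samples if s.video_id not in test_v]
    Xte = [s for s in ds.samples if s.video_id in test_v]
    ytr = [ds.truth_classes[s.sample_id] for s in Xtr]
    yte = [ds.truth_classes[s.sample_id] for s in Xte]
    masks = [ds.rater_mask(s.sample_id) for s in Xtr]
    est = TwixSkillClassifier(n_epochs=4, random_state=0).fit(
        Xtr, ytr, masks=masks)
    return ds, est, Xtr, ytr, Xte, yte, masks


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        est = TwixSkillClassifier(n_epochs=3, twix=False)
        params = est.get_params()
        assert params["n_epochs"] == 3 and params["twix"] is False
        est.set_params(n_epochs=5)
        assert est.n_epochs == 5

    def test_zero_epochs_keeps_initial_params(self, small_dataset):
        ds = small_dataset
        X = ds.samples[:8]
        y = [ds.truth_classes[s.sample_id] for s in X]
        est = TwixSkillClassifier(n_epochs=0, random_state=0).fit(X, y)
        ref = init_params(est.config_)
        for k in ref.tensors:
            assert np.array_equal(est.params_.tensors[k].data,
                                  ref.tensors[k].data)

    def test_fit_deterministic(self, small_dataset):
        ds = small_dataset
        X = ds.samples[:16]
        y = [ds.truth_classes[s.sample_id] for s in X]
        masks = [ds.rater_mask(s.sample_id) for s in X]
        a = TwixSkillClassifier(n_epochs=2, random_state=5).fit(
            X, y, masks=masks)
        b = TwixSkillClassifier(n_epochs=2, random_state=5).fit(
            X, y, masks=masks)
        for k in a.params_.tensors:
            assert np.array_equal(a.params_.tensors[k].data,
                                  b.params_.tensors[k].data)

    def test_inference_is_pure(self, trained):
        _, est, _, _, Xte, _, _ = trained
        p1 = est.predict_proba(Xte)
        p2 = est.predict_proba(Xte)
        assert np.array_equal(p1, p2)
        assert np.allclose(p1.sum(axis=1), 1.0)

    def test_predict_batch_contains_all_sources(self, trained):
        ds, est, _, _, Xte, _, _ = trained
        res = predict_batch(Xte[:3], est.params_)
        for rec in res:
            assert set(rec) == {"class_probs", "attention", "twix"}
            assert isinstance(rec["twix"], ImportanceScores)
            assert rec["twix"].source == "twix"

    def test_attention_changes_with_twix_training(self, trained):
        # explanation supervision reaches the encoder through θ, so the
        # attention read-out itself must differ between training modes
        ds, est, Xtr, ytr, Xte, _, masks = trained
        est_no = TwixSkillClassifier(n_epochs=4, twix=False,
                                     random_state=0).fit(Xtr, ytr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a_with = est.explain(Xte[:4], "attention")
            a_without = est_no.explain(Xte[:4], "attention")
        assert a_with[0].source == "attention_with_twix"
        assert a_without[0].source == "attention"
        assert any(not np.allclose(x.values, y.values)
                   for x, y in zip(a_with, a_without))

    def test_checkpoint_round_trip(self, trained, tmp_path):
        _, est, _, _, Xte, _, _ = trained
        path = tmp_path / "ckpt.npz"
        save_params(est.params_, path)
        back = load_params(path)
        assert back.config == est.params_.config
        for k in est.params_.tensors:
            assert np.array_equal(back.tensors[k].data,
                                  est.params_.tensors[k].data)
        assert np.array_equal(back.prototypes, est.params_.prototypes)

    def test_null_background_sample_classified_high_skill(self, small_dataset):
        # a sample with no events at all should look maximally high-skill
        # to a model trained in the easy regime
        from twix.synthetic import GeneratorConfig, generate_dataset

        ds = generate_dataset(GeneratorConfig(n_videos=8, samples_per_video=8,
                                              seed=21))
        X = ds.samples
        y = [ds.truth_classes[s.sample_id] for s in X]
        masks = [ds.rater_mask(s.sample_id) for s in X]
        est = TwixSkillClassifier(n_epochs=8, random_state=2).fit(
            X, y, masks=masks)
        rng = np.random.default_rng(0)
        base = rng.normal(0.0, 1.0, (25, ds.config.feature_dim))
        from twix.synthetic import derive_flow_stream

        null = VideoSample("null", "vX", "site",
                           [base, derive_flow_stream(base, 1.0, 0)], 1.0, 25.0)
        probs = est.predict_proba([null])[0]
        assert probs[1] > 0.5
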