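"""Attention-based skill classifier with explanation-supervised training.

The classifier is a compact transformer encoder over precomputed frame
features.  Each modality stream (base features and a flow-like derivative)
is projected into a shared model space, a learned classification token is
prepended, and ``n_layers`` self-attention encoder layers produce frame
representations ``h_t`` and a stream video representation (the token's
output).  Stream representations are averaged into the video representation
``v``, trained with a supervised contrastive (InfoNCE) loss so same-class
videos embed nearby.  Class probabilities come from a nearest-class-
prototype softmax over cosine similarities — the natural read-out for a
purely contrastive objective (prototypes are the normalized class means of
training representations and are stored with the fitted parameters).

Two explanation read-outs are available:

* **attention** — the final layer's classification-token attention over
  frames, head-averaged and renormalized; and
* **twix** — a per-frame importance head ``ŷ_t = σ(p_ω(h_t))`` trained with
  binary cross-entropy against human explanation masks (low-skill samples
  only), jointly with the contrastive loss::

      L = L_InfoNCE(θ) + L_importance(ω)

The importance loss is standard binary cross-entropy with ``ŷ`` as the
probability that a frame is important.  (The published formula's label
terms appear transposed — ``(1−y) log ŷ + y log(1−ŷ)`` — which would drive
``ŷ`` toward 0 on important frames, contradicting the stated use of ``ŷ``
as frame importance; the conventional orientation is implemented.)

Everything runs on the numpy autodiff engine in :mod:`twix.autograd`;
gradients are validated against finite differences in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .autograd import Tensor, concat, softmax
from .evaluation import ImportanceScores, roc_auc
from .synthetic import VideoSample

__all__ = [
    "ModelConfig",
    "ModelParams",
    "EncoderOutput",
    "TwixSkillClassifier",
    "init_params",
    "encode",
    "attention_explanation",
    "twix_importance",
    "supervised_infonce_loss",
    "importance_loss",
    "total_loss",
    "train_model",
    "predict_batch",
    "save_params",
    "load_params",
]


@dataclass
class ModelConfig:
    feature_dim: int
    n_streams: int = 2
    n_classes: int = 2
    model_dim: int = 16
    n_layers: int = 1
    n_heads: int = 2
    ffn_dim: int = 32
    temperature: float = 0.1
    twix_enabled: bool = True
    learning_rate: float = 0.015
    n_epochs: int = 12
    batch_size: int = 16
    max_frames: int = 64
    use_positions: bool = True
    importance_input: str = "first"  # "first" stream's h_t, or "mean"
    seed: int = 0

    def __post_init__(self):
        for name in ("feature_dim", "n_streams", "model_dim", "n_layers",
                     "n_heads", "ffn_dim", "batch_size", "max_frames"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least two skill classes")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.model_dim % self.n_heads:
            raise ValueError("model_dim must be divisible by n_heads")
        if self.importance_input not in ("first", "mean"):
            raise ValueError("importance_input must be 'first' or 'mean'")


@dataclass
class ModelParams:
    """Encoder parameters θ, importance-head parameters ω, prototypes."""

    tensors: dict[str, Tensor]
    config: ModelConfig
    prototypes: np.ndarray | None = None

    @property
    def theta(self) -> dict[str, Tensor]:
        return {k: t for k, t in self.tensors.items() if not k.startswith("imp_")}

    @property
    def omega(self) -> dict[str, Tensor]:
        return {k: t for k, t in self.tensors.items() if k.startswith("imp_")}

    def snapshot(self) -> dict:
        return {
            "tensors": {k: t.data.copy() for k, t in self.tensors.items()},
            "prototypes": None if self.prototypes is None else self.prototypes.copy(),
        }

    def restore(self, snap: dict) -> None:
        for k, t in self.tensors.items():
            t.data = snap["tensors"][k].copy()
        self.prototypes = snap["prototypes"]


@dataclass
class EncoderOutput:
    """Per-stream frame representations, attention, video rep, class probs."""

    frame_reps: list[np.ndarray]
    video_rep: np.ndarray
    attention: list[np.ndarray]
    class_probs: np.ndarray
    source_tag: str = "attention"


def init_params(config: ModelConfig) -> ModelParams:
    """Deterministic initialization; importance head starts at ŷ ≡ 0.5."""
    rng = np.random.default_rng(config.seed)
    d, f = config.model_dim, config.ffn_dim
    t: dict[str, Tensor] = {}

    def w(shape, fan_in):
        return Tensor(rng.normal(0.0, fan_in ** -0.5, shape))

    for m in range(config.n_streams):
        t[f"in_w{m}"] = w((config.feature_dim, d), config.feature_dim)
        t[f"in_b{m}"] = Tensor(np.zeros((1, d)))
    t["pos"] = Tensor(rng.normal(0.0, 0.02, (config.max_frames, d)))
    t["cls"] = Tensor(rng.normal(0.0, 0.02, (1, d)))
    for l in range(config.n_layers):
        for name in ("wq", "wk", "wv", "wo"):
            t[f"l{l}_{name}"] = w((d, d), d)
        for name in ("bq", "bk", "bv", "bo"):
            t[f"l{l}_{name}"] = Tensor(np.zeros((1, d)))
        t[f"l{l}_ln1g"] = Tensor(np.ones((1, d)))
        t[f"l{l}_ln1b"] = Tensor(np.zeros((1, d)))
        t[f"l{l}_w1"] = w((d, f), d)
        t[f"l{l}_b1"] = Tensor(np.zeros((1, f)))
        t[f"l{l}_w2"] = w((f, d), f)
        t[f"l{l}_b2"] = Tensor(np.zeros((1, d)))
        t[f"l{l}_ln2g"] = Tensor(np.ones((1, d)))
        t[f"l{l}_ln2b"] = Tensor(np.zeros((1, d)))
    if config.twix_enabled:
        t["imp_w"] = Tensor(np.zeros((d, 1)))
        t["imp_b"] = Tensor(np.zeros((1, 1)))
    return ModelParams(t, config)


# ---------------------------------------------------------------------------
# forward pass


def _layernorm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    m = x.mean(axis=1, keepdims=True)
    xc = x - m
    v = (xc * xc).mean(axis=1, keepdims=True)
    return xc * ((v + eps) ** -0.5) * g + b


def _mha(Z: Tensor, t: dict, l: int, n_heads: int):
    d = Z.shape[1]
    dh = d // n_heads
    Q = Z @ t[f"l{l}_wq"] + t[f"l{l}_bq"]
    K = Z @ t[f"l{l}_wk"] + t[f"l{l}_bk"]
    V = Z @ t[f"l{l}_wv"] + t[f"l{l}_bv"]
    outs, probs = [], []
    for h in range(n_heads):
        sl = (slice(None), slice(h * dh, (h + 1) * dh))
        A = softmax((Q[sl] @ K[sl].T) * (dh ** -0.5), axis=1)
        probs.append(A)
        outs.append(A @ V[sl])
    out = concat(outs, axis=1) @ t[f"l{l}_wo"] + t[f"l{l}_bo"]
    return out, probs


def _forward_stream(t: dict, X: np.ndarray, m: int, cfg: ModelConfig):
    """Returns (frame reps Tensor T×d, video rep Tensor 1×d, attention np (T,))."""
    T = X.shape[0]
    if T > cfg.max_frames:
        raise ValueError(f"sample has {T} frames; max_frames={cfg.max_frames}")
    H = Tensor(X) @ t[f"in_w{m}"] + t[f"in_b{m}"]
    if cfg.use_positions:
        H = H + t["pos"][:T]
    Z = concat([t["cls"], H], axis=0)
    attn_heads = None
    for l in range(cfg.n_layers):
        out, probs = _mha(Z, t, l, cfg.n_heads)
        Z = _layernorm(Z + out, t[f"l{l}_ln1g"], t[f"l{l}_ln1b"])
        F = (Z @ t[f"l{l}_w1"] + t[f"l{l}_b1"]).relu() @ t[f"l{l}_w2"] + t[f"l{l}_b2"]
        Z = _layernorm(Z + F, t[f"l{l}_ln2g"], t[f"l{l}_ln2b"])
        attn_heads = probs
    # classification-token query row, frame columns, head mean, renormalized
    rows = np.stack([A.data[0, 1:] for A in attn_heads])
    a = rows.mean(axis=0)
    a = a / a.sum()
    return Z[1:, :], Z[0:1, :], a


def _forward_sample(t: dict, cfg: ModelConfig, streams: Sequence[np.ndarray]):
    frames_list, vreps, attns = [], [], []
    for m, X in enumerate(streams):
        frames, vrep, a = _forward_stream(t, np.asarray(X, float), m, cfg)
        frames_list.append(frames)
        vreps.append(vrep)
        attns.append(a)
    v = vreps[0]
    for r in vreps[1:]:
        v = v + r
    v = v * (1.0 / len(vreps))
    return frames_list, v, attns


def _importance_input(frames_list: list[Tensor], cfg: ModelConfig) -> Tensor:
    if cfg.importance_input == "first":
        return frames_list[0]
    h = frames_list[0]
    for f in frames_list[1:]:
        h = h + f
    return h * (1.0 / len(frames_list))


def _twix_scores(t: dict, cfg: ModelConfig, frames_list: list[Tensor]) -> Tensor:
    h = _importance_input(frames_list, cfg)
    return (h @ t["imp_w"] + t["imp_b"]).sigmoid().reshape(-1)


def _streams_of(sample) -> list[np.ndarray]:
    if isinstance(sample, VideoSample):
        return sample.streams
    return [np.asarray(s, float) for s in sample]


def _validate_streams(streams, cfg: ModelConfig) -> None:
    if len(streams) != cfg.n_streams:
        raise ValueError(
            f"sample has {len(streams)} streams, model expects {cfg.n_streams}")
    for m, X in enumerate(streams):
        if X.ndim != 2 or X.shape[1] != cfg.feature_dim:
            raise ValueError(
                f"stream {m} has shape {X.shape}; expected "
                f"(T, {cfg.feature_dim})")


def _class_probs(v: np.ndarray, params: ModelParams) -> np.ndarray:
    K = params.config.n_classes
    if params.prototypes is None:
        return np.full(K, 1.0 / K)
    vn = v / (np.linalg.norm(v) + 1e-12)
    sims = params.prototypes @ vn / params.config.temperature
    e = np.exp(sims - sims.max())
    return e / e.sum()


def encode(sample, params: ModelParams) -> EncoderOutput:
    """Full inference pass for one sample (no state change)."""
    cfg = params.config
    streams = _streams_of(sample)
    _validate_streams(streams, cfg)
    frames_list, v, attns = _forward_sample(params.tensors, cfg, streams)
    vdata = v.data.ravel()
    return EncoderOutput(
        frame_reps=[f.data for f in frames_list],
        video_rep=vdata,
        attention=attns,
        class_probs=_class_probs(vdata, params),
        source_tag="attention_with_twix" if cfg.twix_enabled else "attention",
    )


def attention_explanation(output: EncoderOutput) -> ImportanceScores:
    """Stream-averaged attention, min–max rescaled to [0, 1]."""
    a = np.mean(output.attention, axis=0)
    lo, hi = a.min(), a.max()
    if hi == lo:
        warnings.warn("constant attention: scores set to 0.5", stacklevel=2)
        return ImportanceScores(np.full_like(a, 0.5), output.source_tag)
    return ImportanceScores((a - lo) / (hi - lo), output.source_tag)


def twix_importance(output: EncoderOutput, params: ModelParams) -> ImportanceScores:
    """Importance-head probabilities ŷ_t = σ(p_ω(h_t)) per frame."""
    cfg = params.config
    if not cfg.twix_enabled:
        raise ValueError("importance head is disabled (twix_enabled=False)")
    if cfg.importance_input == "first":
        h = output.frame_reps[0]
    else:
        h = np.mean(output.frame_reps, axis=0)
    z = h @ params.tensors["imp_w"].data + params.tensors["imp_b"].data
    return ImportanceScores(1.0 / (1.0 + np.exp(-z.ravel())), "twix")


# ---------------------------------------------------------------------------
# losses


def _infonce(V: Tensor, labels: np.ndarray, temperature: float) -> Tensor:
    B = V.shape[0]
    if B < 2:
        raise ValueError("InfoNCE needs a batch of at least two samples")
    Vn = V * (((V * V).sum(axis=1, keepdims=True) + 1e-12) ** -0.5)
    S = (Vn @ Vn.T) * (1.0 / temperature)
    same = (labels[:, None] == labels[None, :]) & ~np.eye(B, dtype=bool)
    n_pos = same.sum(axis=1)
    anchors = n_pos > 0
    if not anchors.any():
        raise ValueError(
            "no anchor has a same-class positive; use a larger or "
            "class-balanced batch")
    offdiag = (~np.eye(B, dtype=bool)).astype(float)
    # row-wise max over off-diagonal entries, detached, for stability
    masked = np.where(offdiag > 0, S.data, -np.inf)
    rowmax = masked.max(axis=1, keepdims=True)
    E = (S - rowmax).exp() * offdiag
    logden = E.sum(axis=1, keepdims=True).log() + rowmax
    logprob = S - logden
    weights = np.where(anchors[:, None],
                       same / np.maximum(n_pos, 1)[:, None], 0.0)
    weights = weights / anchors.sum()
    return -(logprob * weights).sum()


def supervised_infonce_loss(video_reps, labels, temperature: float = 0.1):
    """Supervised contrastive loss over a batch of video representations.

    Positives are same-class batch members; similarities are cosine (the
    representations are L2-normalized internally) scaled by ``temperature``.
    Accepts a numpy batch (returns a float) or a :class:`Tensor` (returns a
    differentiable scalar).
    """
    labels = np.asarray(labels)
    if isinstance(video_reps, Tensor):
        return _infonce(video_reps, labels, temperature)
    V = Tensor(np.asarray(video_reps, dtype=float))
    return float(_infonce(V, labels, temperature).data)


def importance_loss(scores, mask, eps: float = 1e-7):
    """Binary cross-entropy of frame importance, summed over frames.

    ``scores`` are importance-head probabilities ŷ_t (clipped to
    [eps, 1−eps]); ``mask`` is the human explanation mask.  Only annotated
    (low-skill) samples may be passed — calling without a mask is an error
    by contract.
    """
    if mask is None:
        raise ValueError(
            "importance loss requires an explanation mask; the caller must "
            "filter to annotated low-skill samples")
    y = np.asarray(mask.values if hasattr(mask, "values") else mask, dtype=float)
    if isinstance(scores, Tensor):
        p = scores.reshape(-1)
        if p.shape[0] != y.size:
            raise ValueError(
                f"scores ({p.shape[0]}) and mask ({y.size}) must align")
        pc = p.clip(eps, 1.0 - eps)
        return -((pc.log() * y) + ((1.0 - pc).log() * (1.0 - y))).sum()
    v = np.asarray(
        scores.values if isinstance(scores, ImportanceScores) else scores,
        dtype=float).ravel()
    if v.size != y.size:
        raise ValueError(f"scores ({v.size}) and mask ({y.size}) must align")
    pc = np.clip(v, eps, 1.0 - eps)
    return float(-np.sum(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


def total_loss(batch, config: ModelConfig, params: ModelParams):
    """Compound loss over a batch: InfoNCE + mean per-sample importance BCE.

    ``batch`` is a list of (streams, class index, mask-or-None) triples; the
    importance term is normalized per frame (so its scale is commensurate
    with the contrastive term regardless of clip length), averaged over the
    batch's annotated samples, and omitted entirely when the importance head
    is disabled.  Returns (total, infonce_term, importance_term) as
    differentiable scalars.
    """
    vs, labels, imp_terms = [], [], []
    for streams, label, mask in batch:
        frames_list, v, _ = _forward_sample(params.tensors, config, streams)
        vs.append(v)
        labels.append(label)
        if config.twix_enabled and mask is not None:
            sc = _twix_scores(params.tensors, config, frames_list)
            T = len(mask.values if hasattr(mask, "values") else mask)
            imp_terms.append(importance_loss(sc, mask) * (1.0 / T))
    nce = _infonce(concat(vs, axis=0), np.asarray(labels), config.temperature)
    if not config.twix_enabled:
        return nce, nce, None
    if not imp_terms:
        warnings.warn("batch has no annotated low-skill sample; "
                      "importance term is 0", stacklevel=2)
        return nce, nce, Tensor(0.0)
    imp = imp_terms[0]
    for term in imp_terms[1:]:
        imp = imp + term
    imp = imp * (1.0 / len(imp_terms))
    return nce + imp, nce, imp


# ---------------------------------------------------------------------------
# optimizer


class _Adam:
    def __init__(self, tensors: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.tensors = tensors
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(t.data) for k, t in tensors.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in tensors.items()}
        self.t = 0

    def zero_grad(self):
        for t in self.tensors.values():
            t.zero_grad()

    def step(self):
        self.t += 1
        for k, tensor in self.tensors.items():
            if tensor.grad is None:
                continue
            g = tensor.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            tensor.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# estimator


class TwixSkillClassifier(BaseEstimator, ClassifierMixin):
    """Sequence skill classifier with attention and TWIX explanations.

    scikit-learn style estimator over variable-length multi-stream frame
    features: ``X`` is a list of :class:`VideoSample` (or per-sample lists
    of T×D stream arrays), ``y`` the ordinal skill labels.  ``fit`` accepts
    per-sample explanation masks for the annotated (low-skill) samples and,
    when ``twix=True``, jointly trains the per-frame importance head.

    Parameters mirror :class:`ModelConfig`; fitted state lives in
    ``params_`` (encoder θ, importance head ω, class prototypes),
    ``classes_`` and ``history_``.
    """

    def __init__(self, model_dim=16, n_layers=1, n_heads=2, ffn_dim=32,
                 temperature=0.1, twix=True, learning_rate=0.015, n_epochs=12,
                 batch_size=16, max_frames=64, use_positions=True,
                 importance_input="first", random_state=0):
        self.model_dim = model_dim
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ffn_dim = ffn_dim
        self.temperature = temperature
        self.twix = twix
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.max_frames = max_frames
        self.use_positions = use_positions
        self.importance_input = importance_input
        self.random_state = random_state

    # -- fitting -------------------------------------------------------
    def fit(self, X, y, masks=None, validation=None):
        """Train on samples ``X`` with labels ``y``.

        ``masks`` aligns with ``X`` (None for unannotated samples);
        ``validation`` is an optional ``(X_val, y_val)`` pair used to select
        the best epoch by classification AUC.
        """
        streams = [_streams_of(x) for x in X]
        if not streams:
            raise ValueError("empty training set")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        cfg = ModelConfig(
            feature_dim=streams[0][0].shape[1],
            n_streams=len(streams[0]),
            n_classes=self.classes_.size,
            model_dim=self.model_dim, n_layers=self.n_layers,
            n_heads=self.n_heads, ffn_dim=self.ffn_dim,
            temperature=self.temperature, twix_enabled=self.twix,
            learning_rate=self.learning_rate, n_epochs=self.n_epochs,
            batch_size=self.batch_size, max_frames=self.max_frames,
            use_positions=self.use_positions,
            importance_input=self.importance_input, seed=self.random_state,
        )
        for s in streams:
            _validate_streams(s, cfg)
        if masks is None:
            masks = [None] * len(X)
        if len(masks) != len(X):
            raise ValueError("masks must align with X")

        params = init_params(cfg)
        opt = _Adam(params.tensors, cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed)
        n_per = max(2, cfg.batch_size // cfg.n_classes)
        by_class = [np.flatnonzero(y_idx == k) for k in range(cfg.n_classes)]
        for k, idxs in enumerate(by_class):
            if idxs.size < 2:
                raise ValueError(
                    f"class {self.classes_[k]!r} has fewer than two training "
                    "samples; contrastive batches need positives")

        history = {"loss": [], "val_auc": []}
        # model selection considers trained epochs only: the untrained
        # snapshot (constant importance head, arbitrary prototypes) is
        # recorded in the history but never a selection candidate
        best = None
        self._refresh_prototypes(params, streams, y_idx)
        if validation is not None:
            history["val_auc"].append(self._validation_auc(params, validation))

        for epoch in range(cfg.n_epochs):
            order = [rng.permutation(idxs) for idxs in by_class]
            n_batches = min(len(o) for o in order) // n_per
            epoch_loss = 0.0
            for b in range(n_batches):
                batch = []
                for k in range(cfg.n_classes):
                    for i in order[k][b * n_per:(b + 1) * n_per]:
                        batch.append((streams[i], int(y_idx[i]), masks[i]))
                opt.zero_grad()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    loss, _, _ = total_loss(batch, cfg, params)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"training diverged at epoch {epoch}")
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
            history["loss"].append(epoch_loss / max(n_batches, 1))
            self._refresh_prototypes(params, streams, y_idx)
            if validation is not None:
                auc = self._validation_auc(params, validation)
                history["val_auc"].append(auc)
                # >= : on small validation sets exact AUC ties are common;
                # prefer the later (more-trained) epoch among the best
                if best is None or auc >= best[0]:
                    best = (auc, params.snapshot())

        if validation is not None and best is not None:
            params.restore(best[1])
        self.params_ = params
        self.config_ = cfg
        self.history_ = history
        return self

    def _refresh_prototypes(self, params: ModelParams, streams, y_idx) -> None:
        reps = np.stack([
            _forward_sample(params.tensors, params.config, s)[1].data.ravel()
            for s in streams
        ])
        reps = reps / (np.linalg.norm(reps, axis=1, keepdims=True) + 1e-12)
        protos = np.stack([
            reps[y_idx == k].mean(axis=0)
            for k in range(params.config.n_classes)
        ])
        params.prototypes = protos / (
            np.linalg.norm(protos, axis=1, keepdims=True) + 1e-12)

    def _validation_auc(self, params: ModelParams, validation) -> float:
        X_val, y_val = validation
        probs = np.stack([encode(x, params).class_probs for x in X_val])
        y_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        return roc_auc(probs, y_idx)

    # -- inference -----------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return np.stack([encode(x, self.params_).class_probs for x in X])

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def explain(self, X, source: str = "twix") -> list[ImportanceScores]:
        """Per-frame importance scores for each sample.

        ``source='attention'`` returns the attention read-out (tagged
        ``attention_with_twix`` when the head was trained);
        ``source='twix'`` returns the importance head's probabilities.
        """
        self._check_fitted()
        out = []
        for x in X:
            enc = encode(x, self.params_)
            if source == "twix":
                out.append(twix_importance(enc, self.params_))
            elif source in ("attention", "attention_with_twix"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    out.append(attention_explanation(enc))
            else:
                raise ValueError(f"unknown explanation source {source!r}")
        return out


# ---------------------------------------------------------------------------
# functional wrappers and checkpoints


def train_model(dataset_split, config: ModelConfig) -> ModelParams:
    """Train from a split dict: {'X', 'y', 'masks', 'X_val', 'y_val'}."""
    est = TwixSkillClassifier(
        model_dim=config.model_dim, n_layers=config.n_layers,
        n_heads=config.n_heads, ffn_dim=config.ffn_dim,
        temperature=config.temperature, twix=config.twix_enabled,
        learning_rate=config.learning_rate, n_epochs=config.n_epochs,
        batch_size=config.batch_size, max_frames=config.max_frames,
        use_positions=config.use_positions,
        importance_input=config.importance_input,
        random_state=config.seed,
    )
    validation = None
    if dataset_split.get("X_val") is not None:
        validation = (dataset_split["X_val"], dataset_split["y_val"])
    est.fit(dataset_split["X"], dataset_split["y"],
            masks=dataset_split.get("masks"), validation=validation)
    return est.params_


def predict_batch(samples, params: ModelParams):
    """Pure inference: class probabilities plus every explanation source."""
    results = []
    for s in samples:
        enc = encode(s, params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            attn = attention_explanation(enc)
        rec = {"class_probs": enc.class_probs, "attention": attn}
        if params.config.twix_enabled:
            rec["twix"] = twix_importance(enc, params)
        results.append(rec)
    return results


def save_params(params: ModelParams, path: str | Path) -> None:
    arrays = {k: t.data for k, t in params.tensors.items()}
    if params.prototypes is not None:
        arrays["__prototypes"] = params.prototypes
    np.savez(path, __config=np.frombuffer(
        json.dumps(asdict(params.config)).encode(), dtype=np.uint8), **arrays)


def load_params(path: str | Path) -> ModelParams:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config"]).decode())
        cfg["importance_input"] = cfg.get("importance_input", "first")
        config = ModelConfig(**cfg)
        tensors = {k: Tensor(data[k]) for k in data.files
                   if not k.startswith("__")}
        prototypes = data["__prototypes"] if "__prototypes" in data.files else None
    return ModelParams(tensors, config, prototypes)
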