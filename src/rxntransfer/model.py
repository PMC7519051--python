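"""Encoder-decoder transformer for token-sequence translation, in NumPy.

A compact pre-LN transformer (sinusoidal positions, tied input/output
embeddings, Adam with the inverse-square-root warmup schedule) sized to
train on a single CPU in minutes.  Forward and backward passes are written
explicitly; gradients are verified against finite differences in the test
suite.

The pieces the transfer-learning workflow needs beyond plain training are:

* ``extend_vocab`` — grow a trained checkpoint's embedding table to a new
  vocabulary (e.g. adding stereocenter tokens absent from pretraining);
  rows of shared tokens are copied so behaviour on old-token inputs is
  unchanged until further training.
* ``fine_tune`` — short continued training on a small corpus with the
  learning-rate schedule restarted (fresh, shorter warmup) by default.
* ``beam_predict`` / ``predict_batch`` — beam (or batched greedy) decoding
  returning per-token probabilities, whose product is the prediction's
  confidence score.

Seeded runs are repeatable on one machine in single-threaded mode; across
BLAS builds results are reproducible only to numerical tolerance.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .chem_io import ReactionRecord, Vocabulary, detokenize, tokenize
from .chem_io import is_valid_smiles

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "Checkpoint",
    "Prediction",
    "init_model",
    "train",
    "fine_tune",
    "extend_vocab",
    "beam_predict",
    "predict_batch",
    "confidence",
    "evaluate_loss",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT = "rxntransfer-checkpoint-v1"
_NEG_INF = -1e9
_GRAD_CLIP = 1.0
_ADAM_BETAS = (0.9, 0.998)
_ADAM_EPS = 1e-9


# ---------------------------------------------------------------------------
# Configuration and checkpoint containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Transformer hyperparameters.

    The defaults are a desk-scale profile that trains in minutes on one CPU
    core; ``full_scale()`` returns a profile in the range used by
    GPU-trained reaction transformers.  Label smoothing defaults to 0 so
    that decoder token probabilities remain interpretable and the
    confidence score is a raw probability product.
    """

    num_layers: int = 2
    num_heads: int = 4
    model_dim: int = 64
    feedforward_dim: int = 128
    dropout: float = 0.1
    label_smoothing: float = 0.0
    max_src_len: int = 64
    max_tgt_len: int = 64
    warmup_steps: int = 500
    base_learning_rate_factor: float = 2.0
    batch_size: int = 24
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        for name in ("num_layers", "num_heads", "model_dim", "feedforward_dim",
                     "max_src_len", "max_tgt_len", "warmup_steps", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.model_dim % self.num_heads:
            raise ValueError("model_dim must be divisible by num_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must be in [0, 1)")

    @classmethod
    def full_scale(cls, **overrides) -> "ModelConfig":
        """GPU-scale profile (not used by the desk-scale experiments)."""
        base = dict(num_layers=4, num_heads=8, model_dim=256,
                    feedforward_dim=2048, dropout=0.1, label_smoothing=0.0,
                    max_src_len=512, max_tgt_len=512, warmup_steps=8000,
                    base_learning_rate_factor=2.0, batch_size=96)
        base.update(overrides)
        return cls(**base)


@dataclass
class Checkpoint:
    """Serialized model state: weights, vocabulary, config, step count."""

    params: dict[str, np.ndarray]
    vocab: Vocabulary
    config: ModelConfig
    step: int = 0
    opt_state: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.step < 0:
            raise ValueError("step must be >= 0")
        if self.params["emb"].shape[0] != len(self.vocab):
            raise ValueError("embedding row count does not match vocabulary size")

    def copy(self) -> "Checkpoint":
        return Checkpoint(
            {k: v.copy() for k, v in self.params.items()},
            self.vocab,
            self.config,
            self.step,
            None if self.opt_state is None
            else {k: v.copy() for k, v in self.opt_state.items()},
        )


@dataclass(frozen=True)
class Prediction:
    """One ranked beam candidate with its token-level probabilities.

    ``confidence`` is the product of ``token_probabilities`` (including the
    end-of-sequence token), computed in log space.
    """

    rank: int
    product_smiles: str
    token_probabilities: tuple[float, ...]
    confidence: float
    is_valid: bool

    def __post_init__(self) -> None:
        ref = confidence(self.token_probabilities)
        if not math.isclose(self.confidence, ref, rel_tol=0.0, abs_tol=1e-9):
            raise ValueError("confidence inconsistent with token probabilities")


def confidence(token_probabilities: Sequence[float]) -> float:
    """Product of per-token probabilities, accumulated in log space."""
    probs = list(token_probabilities)
    if not probs:
        raise ValueError("empty probability list")
    log_sum = 0.0
    for p in probs:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"token probability {p!r} outside (0, 1]")
        log_sum += math.log(p)
    return math.exp(log_sum)


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------

def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    std = math.sqrt(2.0 / (fan_in + fan_out))
    return (rng.standard_normal((fan_in, fan_out)) * std).astype(dtype)


def _embedding_rows(rng: np.random.Generator, n: int, dim: int, dtype) -> np.ndarray:
    return (rng.standard_normal((n, dim)) / math.sqrt(dim)).astype(dtype)


def _init_params(config: ModelConfig, vocab_size: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    d, f = config.model_dim, config.feedforward_dim
    dt = np.dtype(config.dtype)
    p: dict[str, np.ndarray] = {
        "emb": _embedding_rows(rng, vocab_size, d, dt),
        "out_b": np.zeros(vocab_size, dtype=dt),
    }

    def ln(name: str) -> None:
        p[f"{name}.g"] = np.ones(d, dtype=dt)
        p[f"{name}.b"] = np.zeros(d, dtype=dt)

    def attn(name: str) -> None:
        for w in ("Wq", "Wk", "Wv", "Wo"):
            p[f"{name}.{w}"] = _xavier(rng, d, d, dt)
        for b in ("bq", "bk", "bv", "bo"):
            p[f"{name}.{b}"] = np.zeros(d, dtype=dt)

    def ffn(name: str) -> None:
        p[f"{name}.W1"] = _xavier(rng, d, f, dt)
        p[f"{name}.b1"] = np.zeros(f, dtype=dt)
        p[f"{name}.W2"] = _xavier(rng, f, d, dt)
        p[f"{name}.b2"] = np.zeros(d, dtype=dt)

    for i in range(config.num_layers):
        ln(f"enc{i}.ln1"); attn(f"enc{i}.attn"); ln(f"enc{i}.ln2"); ffn(f"enc{i}.ff")
    ln("enc.lnf")
    for i in range(config.num_layers):
        ln(f"dec{i}.ln1"); attn(f"dec{i}.self")
        ln(f"dec{i}.ln2"); attn(f"dec{i}.cross")
        ln(f"dec{i}.ln3"); ffn(f"dec{i}.ff")
    ln("dec.lnf")
    return p


def init_model(config: ModelConfig, vocab: Vocabulary) -> Checkpoint:
    """Seeded deterministic initialization at step 0."""
    rng = np.random.default_rng(config.seed)
    return Checkpoint(_init_params(config, len(vocab), rng), vocab, config, step=0)


# ---------------------------------------------------------------------------
# Primitive ops (forward + backward)
# ---------------------------------------------------------------------------

def _layer_norm_fwd(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _layer_norm_bwd(dy, cache):
    xhat, inv, g = cache
    d = xhat.shape[-1]
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv / d * (d * dxhat - dxhat.sum(-1, keepdims=True)
                    - xhat * (dxhat * xhat).sum(-1, keepdims=True))
    return dx, dg, db


def _linear_fwd(x, W, b):
    return x @ W + b, x


def _linear_bwd(dy, x, W):
    din, dout = W.shape
    x2 = x.reshape(-1, din)
    dy2 = dy.reshape(-1, dout)
    dW = x2.T @ dy2
    db = dy2.sum(0)
    dx = (dy2 @ W.T).reshape(x.shape)
    return dx, dW, db


def _dropout_fwd(x, p, rng, train):
    if not train or p <= 0.0:
        return x, None
    mask = (rng.random(x.shape) >= p).astype(x.dtype) / (1.0 - p)
    return x * mask, mask


def _dropout_bwd(dy, mask):
    return dy if mask is None else dy * mask


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _split_heads(x, nh):
    B, T, d = x.shape
    return x.reshape(B, T, nh, d // nh).transpose(0, 2, 1, 3)


def _merge_heads(x):
    B, nh, T, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, nh * dh)


def _attention_fwd(p, name, x_q, x_kv, bias, nh, drop, rng, train):
    """Multi-head attention; ``bias`` is additive (0 / -1e9), broadcastable
    to (B, 1, Tq, Tk)."""
    q_l, _ = _linear_fwd(x_q, p[f"{name}.Wq"], p[f"{name}.bq"])
    k_l, _ = _linear_fwd(x_kv, p[f"{name}.Wk"], p[f"{name}.bk"])
    v_l, _ = _linear_fwd(x_kv, p[f"{name}.Wv"], p[f"{name}.bv"])
    q, k, v = _split_heads(q_l, nh), _split_heads(k_l, nh), _split_heads(v_l, nh)
    scale = 1.0 / math.sqrt(q.shape[-1])
    scores = (q @ k.transpose(0, 1, 3, 2)) * scale + bias
    A = _softmax(scores)
    Ad, dmask = _dropout_fwd(A, drop, rng, train)
    ctx = Ad @ v
    merged = _merge_heads(ctx)
    out, _ = _linear_fwd(merged, p[f"{name}.Wo"], p[f"{name}.bo"])
    cache = (x_q, x_kv, q, k, v, A, Ad, dmask, merged, scale, nh)
    return out, cache


def _attention_bwd(dy, p, name, cache, grads):
    x_q, x_kv, q, k, v, A, Ad, dmask, merged, scale, nh = cache
    dmerged, dWo, dbo = _linear_bwd(dy, merged, p[f"{name}.Wo"])
    grads[f"{name}.Wo"] += dWo
    grads[f"{name}.bo"] += dbo
    dctx = _split_heads(dmerged, nh)
    dAd = dctx @ v.transpose(0, 1, 3, 2)
    dv = Ad.transpose(0, 1, 3, 2) @ dctx
    dA = _dropout_bwd(dAd, dmask)
    dS = A * (dA - (dA * A).sum(-1, keepdims=True))
    dq = (dS @ k) * scale
    dk = (dS.transpose(0, 1, 3, 2) @ q) * scale
    dx_q, dWq, dbq = _linear_bwd(_merge_heads(dq), x_q, p[f"{name}.Wq"])
    dx_k, dWk, dbk = _linear_bwd(_merge_heads(dk), x_kv, p[f"{name}.Wk"])
    dx_v, dWv, dbv = _linear_bwd(_merge_heads(dv), x_kv, p[f"{name}.Wv"])
    grads[f"{name}.Wq"] += dWq; grads[f"{name}.bq"] += dbq
    grads[f"{name}.Wk"] += dWk; grads[f"{name}.bk"] += dbk
    grads[f"{name}.Wv"] += dWv; grads[f"{name}.bv"] += dbv
    return dx_q, dx_k + dx_v


def _ffn_fwd(p, name, x):
    h_pre, _ = _linear_fwd(x, p[f"{name}.W1"], p[f"{name}.b1"])
    h = np.maximum(h_pre, 0.0)
    out, _ = _linear_fwd(h, p[f"{name}.W2"], p[f"{name}.b2"])
    return out, (x, h_pre, h)


def _ffn_bwd(dy, p, name, cache, grads):
    x, h_pre, h = cache
    dh, dW2, db2 = _linear_bwd(dy, h, p[f"{name}.W2"])
    grads[f"{name}.W2"] += dW2; grads[f"{name}.b2"] += db2
    dh_pre = dh * (h_pre > 0)
    dx, dW1, db1 = _linear_bwd(dh_pre, x, p[f"{name}.W1"])
    grads[f"{name}.W1"] += dW1; grads[f"{name}.b1"] += db1
    return dx


_POS_CACHE: dict[tuple[int, int, str], np.ndarray] = {}


def _positional(max_len: int, d: int, dtype: str) -> np.ndarray:
    key = (max_len, d, dtype)
    if key not in _POS_CACHE:
        pos = np.arange(max_len)[:, None]
        i = np.arange(d // 2)[None, :]
        ang = pos / np.power(10000.0, 2 * i / d)
        pe = np.zeros((max_len, d))
        pe[:, 0::2] = np.sin(ang)
        pe[:, 1::2] = np.cos(ang)
        _POS_CACHE[key] = pe.astype(dtype)
    return _POS_CACHE[key]


# ---------------------------------------------------------------------------
# Full forward / backward
# ---------------------------------------------------------------------------

def _embed_fwd(p, idx, config, drop_rng, train):
    d = config.model_dim
    x = p["emb"][idx] * math.sqrt(d) + _positional(idx.shape[1], d, config.dtype)
    x = x.astype(p["emb"].dtype, copy=False)
    x, mask = _dropout_fwd(x, config.dropout, drop_rng, train)
    return x, mask


def _encoder_fwd(p, config, src, src_bias, drop_rng, train):
    x, emb_mask = _embed_fwd(p, src, config, drop_rng, train)
    caches = []
    for i in range(config.num_layers):
        h1, ln1c = _layer_norm_fwd(x, p[f"enc{i}.ln1.g"], p[f"enc{i}.ln1.b"])
        a, ac = _attention_fwd(p, f"enc{i}.attn", h1, h1, src_bias,
                               config.num_heads, config.dropout, drop_rng, train)
        a, am = _dropout_fwd(a, config.dropout, drop_rng, train)
        x = x + a
        h2, ln2c = _layer_norm_fwd(x, p[f"enc{i}.ln2.g"], p[f"enc{i}.ln2.b"])
        ff, fc = _ffn_fwd(p, f"enc{i}.ff", h2)
        ff, fm = _dropout_fwd(ff, config.dropout, drop_rng, train)
        x = x + ff
        caches.append((ln1c, ac, am, ln2c, fc, fm))
    out, lnfc = _layer_norm_fwd(x, p["enc.lnf.g"], p["enc.lnf.b"])
    return out, (emb_mask, caches, lnfc)


def _encoder_bwd(dy, p, config, src, cache, grads):
    emb_mask, caches, lnfc = cache
    dx, dg, db = _layer_norm_bwd(dy, lnfc)
    grads["enc.lnf.g"] += dg; grads["enc.lnf.b"] += db
    for i in reversed(range(config.num_layers)):
        ln1c, ac, am, ln2c, fc, fm = caches[i]
        dff = _dropout_bwd(dx, fm)
        dh2 = _ffn_bwd(dff, p, f"enc{i}.ff", fc, grads)
        dres, dg, db = _layer_norm_bwd(dh2, ln2c)
        grads[f"enc{i}.ln2.g"] += dg; grads[f"enc{i}.ln2.b"] += db
        dx = dx + dres
        da = _dropout_bwd(dx, am)
        dq, dkv = _attention_bwd(da, p, f"enc{i}.attn", ac, grads)
        dres, dg, db = _layer_norm_bwd(dq + dkv, ln1c)
        grads[f"enc{i}.ln1.g"] += dg; grads[f"enc{i}.ln1.b"] += db
        dx = dx + dres
    dx = _dropout_bwd(dx, emb_mask)
    np.add.at(grads["emb"], src.reshape(-1),
              (dx * math.sqrt(config.model_dim)).reshape(-1, config.model_dim))


def _decoder_fwd(p, config, tgt_in, enc_out, causal_bias, cross_bias,
                 drop_rng, train):
    x, emb_mask = _embed_fwd(p, tgt_in, config, drop_rng, train)
    caches = []
    for i in range(config.num_layers):
        h1, ln1c = _layer_norm_fwd(x, p[f"dec{i}.ln1.g"], p[f"dec{i}.ln1.b"])
        a, ac = _attention_fwd(p, f"dec{i}.self", h1, h1, causal_bias,
                               config.num_heads, config.dropout, drop_rng, train)
        a, am = _dropout_fwd(a, config.dropout, drop_rng, train)
        x = x + a
        h2, ln2c = _layer_norm_fwd(x, p[f"dec{i}.ln2.g"], p[f"dec{i}.ln2.b"])
        c, cc = _attention_fwd(p, f"dec{i}.cross", h2, enc_out, cross_bias,
                               config.num_heads, config.dropout, drop_rng, train)
        c, cm = _dropout_fwd(c, config.dropout, drop_rng, train)
        x = x + c
        h3, ln3c = _layer_norm_fwd(x, p[f"dec{i}.ln3.g"], p[f"dec{i}.ln3.b"])
        ff, fc = _ffn_fwd(p, f"dec{i}.ff", h3)
        ff, fm = _dropout_fwd(ff, config.dropout, drop_rng, train)
        x = x + ff
        caches.append((ln1c, ac, am, ln2c, cc, cm, ln3c, fc, fm))
    out, lnfc = _layer_norm_fwd(x, p["dec.lnf.g"], p["dec.lnf.b"])
    return out, (emb_mask, caches, lnfc)


def _decoder_bwd(dy, p, config, tgt_in, cache, grads):
    """Returns the gradient w.r.t. the encoder output."""
    emb_mask, caches, lnfc = cache
    dx, dg, db = _layer_norm_bwd(dy, lnfc)
    grads["dec.lnf.g"] += dg; grads["dec.lnf.b"] += db
    denc = None
    for i in reversed(range(config.num_layers)):
        ln1c, ac, am, ln2c, cc, cm, ln3c, fc, fm = caches[i]
        dff = _dropout_bwd(dx, fm)
        dh3 = _ffn_bwd(dff, p, f"dec{i}.ff", fc, grads)
        dres, dg, db = _layer_norm_bwd(dh3, ln3c)
        grads[f"dec{i}.ln3.g"] += dg; grads[f"dec{i}.ln3.b"] += db
        dx = dx + dres
        dc = _dropout_bwd(dx, cm)
        dq, dkv = _attention_bwd(dc, p, f"dec{i}.cross", cc, grads)
        denc = dkv if denc is None else denc + dkv
        dres, dg, db = _layer_norm_bwd(dq, ln2c)
        grads[f"dec{i}.ln2.g"] += dg; grads[f"dec{i}.ln2.b"] += db
        dx = dx + dres
        da = _dropout_bwd(dx, am)
        dq, dkv = _attention_bwd(da, p, f"dec{i}.self", ac, grads)
        dres, dg, db = _layer_norm_bwd(dq + dkv, ln1c)
        grads[f"dec{i}.ln1.g"] += dg; grads[f"dec{i}.ln1.b"] += db
        dx = dx + dres
    dx = _dropout_bwd(dx, emb_mask)
    np.add.at(grads["emb"], tgt_in.reshape(-1),
              (dx * math.sqrt(config.model_dim)).reshape(-1, config.model_dim))
    return denc


def _make_biases(src_pad: np.ndarray, tgt_len: int, dtype) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive attention biases: (encoder self, decoder causal, cross)."""
    src_bias = np.where(src_pad[:, None, None, :], _NEG_INF, 0.0).astype(dtype)
    causal = np.triu(np.full((tgt_len, tgt_len), _NEG_INF, dtype=dtype), k=1)
    return src_bias, causal[None, None], src_bias


def _loss_and_dlogits(logits, tgt_out, tgt_mask, pad_index, smoothing):
    """Masked cross-entropy (optionally label-smoothed over non-pad tokens)."""
    B, T, V = logits.shape
    z = logits.astype(np.float64)
    z -= z.max(-1, keepdims=True)
    lse = np.log(np.exp(z).sum(-1, keepdims=True))
    log_probs = z - lse
    n_tok = tgt_mask.sum()
    onehot_ll = np.take_along_axis(log_probs, tgt_out[..., None], axis=-1)[..., 0]
    if smoothing > 0.0:
        uniform = np.full(V, 1.0 / (V - 1))
        uniform[pad_index] = 0.0
        smooth_ll = log_probs @ uniform
        nll = -(1.0 - smoothing) * onehot_ll - smoothing * smooth_ll
        target = np.zeros_like(log_probs)
        np.put_along_axis(target, tgt_out[..., None], 1.0 - smoothing, axis=-1)
        target += smoothing * uniform
    else:
        nll = -onehot_ll
        target = np.zeros_like(log_probs)
        np.put_along_axis(target, tgt_out[..., None], 1.0, axis=-1)
    loss = float((nll * tgt_mask).sum() / n_tok)
    dlogits = (np.exp(log_probs) - target) * (tgt_mask[..., None] / n_tok)
    return loss, dlogits.astype(logits.dtype)


def _forward_backward(p, config, batch, drop_rng, train_mode=True,
                      compute_grads=True):
    src, src_pad, tgt_in, tgt_out, tgt_mask = batch
    dtype = p["emb"].dtype
    src_bias, causal_bias, cross_bias = _make_biases(src_pad, tgt_in.shape[1], dtype)
    enc_out, enc_cache = _encoder_fwd(p, config, src, src_bias, drop_rng, train_mode)
    dec_out, dec_cache = _decoder_fwd(p, config, tgt_in, enc_out, causal_bias,
                                      cross_bias, drop_rng, train_mode)
    logits = dec_out @ p["emb"].T + p["out_b"]
    loss, dlogits = _loss_and_dlogits(logits, tgt_out, tgt_mask,
                                      0, config.label_smoothing)
    if not compute_grads:
        return loss, None
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    d = config.model_dim
    grads["out_b"] += dlogits.sum((0, 1))
    grads["emb"] += dlogits.reshape(-1, logits.shape[-1]).T @ dec_out.reshape(-1, d)
    ddec = dlogits @ p["emb"]
    denc = _decoder_bwd(ddec, p, config, tgt_in, dec_cache, grads)
    _encoder_bwd(denc, p, config, src, enc_cache, grads)
    return loss, grads


# ---------------------------------------------------------------------------
# Batch encoding
# ---------------------------------------------------------------------------

def _record_token_indices(rec: ReactionRecord, vocab: Vocabulary,
                          strict: bool) -> tuple[list[int], list[int]]:
    src = vocab.encode(tokenize(".".join(rec.precursors)).tokens, strict=strict)
    tgt = vocab.encode(tokenize(".".join(rec.products)).tokens, strict=strict)
    return src, tgt


def encode_batch(records: Sequence[ReactionRecord], vocab: Vocabulary,
                 config: ModelConfig, strict: bool = True):
    """Pad a list of records into model input arrays.

    Out-of-vocabulary tokens raise in strict mode (training must never map
    silently to the unknown token); sequences beyond the configured maxima
    raise too.
    """
    srcs, tgts = [], []
    for rec in records:
        s, t = _record_token_indices(rec, vocab, strict)
        if len(s) > config.max_src_len or len(t) + 1 > config.max_tgt_len:
            raise ValueError(f"record exceeds configured max length: {rec}")
        srcs.append(s)
        tgts.append(t)
    B = len(records)
    S = max(len(s) for s in srcs)
    T = max(len(t) for t in tgts) + 1  # room for BOS / EOS shift
    pad, bos, eos = vocab.pad_index, vocab.bos_index, vocab.eos_index
    src = np.full((B, S), pad, dtype=np.int64)
    tgt_in = np.full((B, T), pad, dtype=np.int64)
    tgt_out = np.full((B, T), pad, dtype=np.int64)
    for i, (s, t) in enumerate(zip(srcs, tgts)):
        src[i, :len(s)] = s
        tgt_in[i, 0] = bos
        tgt_in[i, 1:len(t) + 1] = t
        tgt_out[i, :len(t)] = t
        tgt_out[i, len(t)] = eos
    src_pad = src == pad
    tgt_mask = np.zeros((B, T))
    for i, t in enumerate(tgts):
        tgt_mask[i, :len(t) + 1] = 1.0
    return src, src_pad, tgt_in, tgt_out, tgt_mask


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def noam_lr(schedule_step: int, config: ModelConfig) -> float:
    """Inverse-square-root schedule with linear warmup."""
    s = max(schedule_step, 1)
    return (config.base_learning_rate_factor * config.model_dim ** -0.5
            * min(s ** -0.5, s * config.warmup_steps ** -1.5))


def _clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = math.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                          for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale


def train(
    checkpoint: Checkpoint,
    stream: Iterator[Sequence[ReactionRecord]],
    steps: int,
    schedule_offset: int | None = None,
    checkpoint_dir: str | Path | None = None,
    checkpoint_every: int | None = None,
    log_every: int = 500,
) -> Checkpoint:
    """Run ``steps`` optimizer steps over batches drawn from ``stream``.

    The learning-rate schedule position is ``step - schedule_offset``
    (offset 0 by default, i.e. the schedule continues across calls).
    Returns a new checkpoint at ``checkpoint.step + steps``; the input
    checkpoint is not modified.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    ckpt = checkpoint.copy()
    if steps == 0:
        return ckpt
    config, vocab = ckpt.config, ckpt.vocab
    p = ckpt.params
    offset = 0 if schedule_offset is None else schedule_offset
    if ckpt.opt_state is None:
        ckpt.opt_state = {}
        for k, v in p.items():
            ckpt.opt_state[f"m.{k}"] = np.zeros_like(v)
            ckpt.opt_state[f"v.{k}"] = np.zeros_like(v)
    opt = ckpt.opt_state
    b1, b2 = _ADAM_BETAS
    drop_rng = np.random.default_rng([config.seed, ckpt.step, 7])
    for step_idx in range(steps):
        batch_records = next(stream)
        batch = encode_batch(batch_records, vocab, config, strict=True)
        loss, grads = _forward_backward(p, config, batch, drop_rng)
        _clip_grads(grads, _GRAD_CLIP)
        ckpt.step += 1
        t = ckpt.step - offset
        lr = noam_lr(t, config)
        bc1 = 1.0 - b1 ** t
        bc2 = 1.0 - b2 ** t
        for k, g in grads.items():
            m = opt[f"m.{k}"]
            v = opt[f"v.{k}"]
            m *= b1; m += (1 - b1) * g
            v *= b2; v += (1 - b2) * g * g
            p[k] -= (lr * (m / bc1) / (np.sqrt(v / bc2) + _ADAM_EPS)).astype(p[k].dtype)
        if log_every and ckpt.step % log_every == 0:
            logger.info("step %d  lr %.2e  loss %.4f", ckpt.step, lr, loss)
        if checkpoint_dir and checkpoint_every and ckpt.step % checkpoint_every == 0:
            save_checkpoint(ckpt, Path(checkpoint_dir) / f"step_{ckpt.step}.npz")
    return ckpt


def single_corpus_stream(records: Sequence[ReactionRecord], batch_size: int,
                         seed: int) -> Iterator[list[ReactionRecord]]:
    """Unbounded batch stream over one corpus, reshuffled each epoch."""
    if not records:
        raise ValueError("empty corpus")

    def stream() -> Iterator[list[ReactionRecord]]:
        rng = np.random.default_rng(seed)
        order: list[int] = []
        while True:
            batch = []
            while len(batch) < batch_size:
                if not order:
                    order = list(rng.permutation(len(records)))
                batch.append(records[order.pop()])
            yield batch

    return stream()


def fine_tune(
    checkpoint: Checkpoint,
    records: Sequence[ReactionRecord],
    steps: int,
    restart_schedule: bool = True,
    stream_seed: int | None = None,
    **config_overrides,
) -> Checkpoint:
    """Short continued training on a small corpus only.

    The default fine-tuning protocol differs from pretraining in four
    ways, all serving fast convergence within a small step budget on a
    small clean corpus: the learning-rate schedule is restarted with a
    fresh, short warmup (200 steps) and the optimizer state is reset;
    dropout is switched off (regularization noise costs more than it buys
    in a short adaptation); the batch size is doubled and the learning
    rate factor raised 1.5x (larger batches reduce gradient noise enough
    to support the higher rate).  Pass ``restart_schedule=False`` to
    continue the pretraining schedule, or override any of ``dropout``,
    ``batch_size``, ``base_learning_rate_factor``, ``warmup_steps``
    explicitly.  ``config_overrides`` update ModelConfig fields (training
    hyperparameters only; architecture fields must not change).
    """
    ckpt = checkpoint.copy()
    if steps == 0:
        return ckpt
    config_overrides.setdefault("dropout", 0.0)
    config_overrides.setdefault("batch_size", 2 * ckpt.config.batch_size)
    config_overrides.setdefault(
        "base_learning_rate_factor", 1.5 * ckpt.config.base_learning_rate_factor)
    if restart_schedule:
        config_overrides.setdefault("warmup_steps", 200)
    for name in ("num_layers", "num_heads", "model_dim", "feedforward_dim"):
        if name in config_overrides:
            raise ValueError(f"cannot override architecture field {name}")
    config = replace(ckpt.config, **config_overrides) if config_overrides else ckpt.config
    ckpt.config = config
    offset = ckpt.step if restart_schedule else 0
    if restart_schedule:
        ckpt.opt_state = None
    seed = stream_seed if stream_seed is not None else config.seed + 1
    stream = single_corpus_stream(records, config.batch_size, seed)
    return train(ckpt, stream, steps, schedule_offset=offset)


def extend_vocab(checkpoint: Checkpoint, new_vocab: Vocabulary) -> Checkpoint:
    """Grow a checkpoint to a superset vocabulary.

    Embedding (and tied output) rows of shared tokens are copied, so
    old-token logits — and hence decoded sequences on inputs containing
    only old tokens — are unchanged until further training (token
    probabilities renormalize over the enlarged vocabulary); rows for new
    tokens are drawn from the model's initializer distribution (seeded).
    The optimizer state is reset.
    """
    old_vocab = checkpoint.vocab
    missing = set(old_vocab.tokens) - set(new_vocab.tokens)
    if missing:
        raise ValueError(f"new vocabulary is missing old tokens: {sorted(missing)}")
    if new_vocab == old_vocab:
        return checkpoint.copy()
    config = checkpoint.config
    d = config.model_dim
    rng = np.random.default_rng([config.seed, len(new_vocab), 11])
    new_rows = _embedding_rows(rng, len(new_vocab), d, checkpoint.params["emb"].dtype)
    emb = new_rows
    out_b = np.zeros(len(new_vocab), dtype=checkpoint.params["out_b"].dtype)
    for tok in old_vocab.tokens:
        emb[new_vocab.index(tok)] = checkpoint.params["emb"][old_vocab.index(tok)]
        out_b[new_vocab.index(tok)] = checkpoint.params["out_b"][old_vocab.index(tok)]
    params = {k: v.copy() for k, v in checkpoint.params.items()}
    params["emb"] = emb
    params["out_b"] = out_b
    return Checkpoint(params, new_vocab, config, checkpoint.step, opt_state=None)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _encode_sources(sources: Sequence[list[int]], pad: int):
    B = len(sources)
    S = max(len(s) for s in sources)
    src = np.full((B, S), pad, dtype=np.int64)
    for i, s in enumerate(sources):
        src[i, :len(s)] = s
    return src, src == pad


def _infer_encoder(ckpt: Checkpoint, src, src_pad):
    dtype = ckpt.params["emb"].dtype
    src_bias = np.where(src_pad[:, None, None, :], _NEG_INF, 0.0).astype(dtype)
    enc_out, _ = _encoder_fwd(ckpt.params, ckpt.config, src, src_bias, None, False)
    return enc_out, src_bias


def _infer_decoder_logits(ckpt: Checkpoint, tgt_in, enc_out, cross_bias):
    """Logits for every position of the given target prefix (no dropout)."""
    config, p = ckpt.config, ckpt.params
    dtype = p["emb"].dtype
    T = tgt_in.shape[1]
    causal = np.triu(np.full((T, T), _NEG_INF, dtype=dtype), k=1)[None, None]
    dec_out, _ = _decoder_fwd(p, config, tgt_in, enc_out, causal, cross_bias,
                              None, False)
    return dec_out @ p["emb"].T + p["out_b"]


def _log_softmax64(logits):
    z = logits.astype(np.float64)
    z -= z.max(-1, keepdims=True)
    return z - np.log(np.exp(z).sum(-1, keepdims=True))


def _source_indices(precursors: Sequence[str], vocab: Vocabulary) -> list[int]:
    return vocab.encode(tokenize(".".join(precursors)).tokens, strict=False)


def _make_prediction(rank: int, token_idx: list[int], token_logps: list[float],
                     vocab: Vocabulary) -> Prediction:
    probs = tuple(math.exp(max(lp, -700.0)) for lp in token_logps)
    tokens = [vocab.token(i) for i in token_idx]
    smiles = detokenize(t for t in tokens if t not in Vocabulary.SPECIALS)
    return Prediction(
        rank=rank,
        product_smiles=smiles,
        token_probabilities=probs,
        confidence=confidence(probs),
        is_valid=is_valid_smiles(smiles),
    )


def beam_predict(
    checkpoint: Checkpoint,
    precursors: ReactionRecord | Sequence[str],
    beam_size: int = 5,
    n_best: int = 1,
) -> list[Prediction]:
    """Beam-search decode one source; candidates ordered by confidence.

    Token probabilities include the end-of-sequence token.  Unknown source
    tokens map to the unknown special (inference only).  ``beam_size == 1``
    is exactly greedy decoding.
    """
    if beam_size < 1:
        raise ValueError("beam_size must be >= 1")
    if n_best > beam_size:
        raise ValueError("n_best must be <= beam_size")
    vocab, config = checkpoint.vocab, checkpoint.config
    frags = precursors.precursors if isinstance(precursors, ReactionRecord) else precursors
    src_idx = _source_indices(frags, vocab)
    src, src_pad = _encode_sources([src_idx], vocab.pad_index)
    enc_out, cross_bias = _infer_encoder(checkpoint, src, src_pad)

    bos, eos = vocab.bos_index, vocab.eos_index
    # beams: (token indices after BOS, per-token logps, finished)
    beams: list[tuple[list[int], list[float], bool]] = [([], [], False)]
    for _ in range(config.max_tgt_len - 1):
        active = [b for b in beams if not b[2]]
        if not active:
            break
        T = len(active[0][0]) + 1
        tgt_in = np.array([[bos] + b[0] for b in active], dtype=np.int64)
        logits = _infer_decoder_logits(
            checkpoint, tgt_in,
            np.repeat(enc_out, len(active), axis=0),
            np.repeat(cross_bias, len(active), axis=0))
        logps = _log_softmax64(logits[:, -1, :])
        candidates: list[tuple[list[int], list[float], bool]] = [
            b for b in beams if b[2]]
        for bi, (toks, lps, _) in enumerate(active):
            top = np.argsort(logps[bi])[::-1][:beam_size]
            for tok in top:
                candidates.append(
                    (toks + [int(tok)], lps + [float(logps[bi, tok])],
                     int(tok) == eos))
        candidates.sort(key=lambda b: sum(b[1]), reverse=True)
        beams = candidates[:beam_size]
        if all(b[2] for b in beams):
            break
    beams.sort(key=lambda b: sum(b[1]), reverse=True)
    out = []
    for rank, (toks, lps, finished) in enumerate(beams[:n_best], start=1):
        body = toks[:-1] if finished else toks  # EOS excluded from the SMILES
        out.append(_make_prediction(rank, body, lps, vocab))
    return out


def predict_batch(
    checkpoint: Checkpoint,
    records: Sequence[ReactionRecord],
    beam_size: int = 1,
    n_best: int = 1,
) -> list[list[Prediction]]:
    """Decode many sources; greedy decoding is batched for speed."""
    if beam_size == 1:
        return _greedy_batch(checkpoint, records)
    return [beam_predict(checkpoint, rec, beam_size, n_best) for rec in records]


def _greedy_batch(checkpoint: Checkpoint, records: Sequence[ReactionRecord],
                  chunk: int = 256) -> list[list[Prediction]]:
    vocab, config = checkpoint.vocab, checkpoint.config
    out: list[list[Prediction]] = []
    for lo in range(0, len(records), chunk):
        batch = records[lo:lo + chunk]
        sources = [_source_indices(r.precursors, vocab) for r in batch]
        src, src_pad = _encode_sources(sources, vocab.pad_index)
        enc_out, cross_bias = _infer_encoder(checkpoint, src, src_pad)
        B = len(batch)
        bos, eos = vocab.bos_index, vocab.eos_index
        tgt = np.full((B, 1), bos, dtype=np.int64)
        finished = np.zeros(B, dtype=bool)
        tok_idx: list[list[int]] = [[] for _ in range(B)]
        tok_lps: list[list[float]] = [[] for _ in range(B)]
        for _ in range(config.max_tgt_len - 1):
            logits = _infer_decoder_logits(checkpoint, tgt, enc_out, cross_bias)
            logps = _log_softmax64(logits[:, -1, :])
            nxt = logps.argmax(-1)
            for i in range(B):
                if not finished[i]:
                    tok_idx[i].append(int(nxt[i]))
                    tok_lps[i].append(float(logps[i, nxt[i]]))
            finished |= nxt == eos
            if finished.all():
                break
            tgt = np.concatenate([tgt, nxt[:, None]], axis=1)
        for i in range(B):
            body = tok_idx[i][:-1] if (tok_idx[i] and tok_idx[i][-1] == eos) else tok_idx[i]
            out.append([_make_prediction(1, body, tok_lps[i], vocab)])
    return out


def evaluate_loss(checkpoint: Checkpoint, records: Sequence[ReactionRecord]) -> float:
    """Mean token cross-entropy on a held-out batch (no dropout)."""
    batch = encode_batch(records, checkpoint.vocab, checkpoint.config, strict=True)
    loss, _ = _forward_backward(checkpoint.params, checkpoint.config, batch,
                                None, train_mode=False, compute_grads=False)
    return loss


# ---------------------------------------------------------------------------
# Checkpoint serialization
# ---------------------------------------------------------------------------

def save_checkpoint(checkpoint: Checkpoint, path: str | Path) -> None:
    """Single-file bundle: weights + vocabulary + config + step, versioned."""
    meta = {
        "format": CHECKPOINT_FORMAT,
        "step": checkpoint.step,
        "config": asdict(checkpoint.config),
        "vocab": list(checkpoint.vocab.tokens[len(Vocabulary.SPECIALS):]),
    }
    arrays = {f"p.{k}": v for k, v in checkpoint.params.items()}
    if checkpoint.opt_state:
        arrays.update({f"o.{k}": v for k, v in checkpoint.opt_state.items()})
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> Checkpoint:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognized checkpoint format in {path}")
        params = {k[2:]: data[k] for k in data.files if k.startswith("p.")}
        opt = {k[2:]: data[k] for k in data.files if k.startswith("o.")}
    return Checkpoint(
        params,
        Vocabulary(meta["vocab"]),
        ModelConfig(**meta["config"]),
        meta["step"],
        opt_state=opt or None,
    )
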