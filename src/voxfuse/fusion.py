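"""Early-fusion residual + attention classifier.

The fused input ``x = [biomarkers ∥ embedding]`` (790-dimensional at the
default 22 + 768 configuration) passes through:

* **Block A** — a residual feedforward block: two dense layers
  (in → 512 → 512) with ReLU, dropout and batch normalisation, plus a
  learned linear skip projection from the input (the input and output
  widths differ, so an identity skip is not available);
* **Block B** — a transformer-inspired residual block: the 512-vector is
  reshaped into S tokens, passed through multi-head self-attention and a
  feedforward subnetwork (each with layer norm and dropout), flattened,
  and added back to its own input through a whole-block skip;
* a classification head (512 → 128 → 2) with ReLU, batch norm and
  dropout, ending in a softmax over the two classes (Healthy = 0,
  PD = 1).

Training minimises the 2-class categorical cross-entropy
``L = -sum_c y_c log(ŷ_c)`` (identical to binary cross-entropy for a
2-way softmax); a floor of 1e-12 is applied inside the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from voxfuse._autodiff import Tensor, softmax
from voxfuse.errors import ValidationError
from voxfuse.nn import (
    Adam,
    BatchNorm1d,
    Dropout,
    LayerNorm,
    Linear,
    Module,
    MultiHeadSelfAttention,
)

_LOG_FLOOR = 1e-12


class _Identity(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture of the fusion classifier.

    ``hidden_dim`` must be divisible by ``attn_tokens``: Block B reshapes
    the hidden vector into that many tokens for self-attention.
    """

    input_dim: int = 790             # 22 biomarkers + 768 embedding dims
    hidden_dim: int = 512
    attn_tokens: int = 8             # S
    attn_heads: int = 4
    ffn_dim: int = 256
    head_hidden: int = 128
    dropout: float = 0.5
    n_classes: int = 2
    use_batch_norm: bool = True      # ablation switch

    def __post_init__(self) -> None:
        if self.hidden_dim % self.attn_tokens != 0:
            raise ValidationError(
                f"hidden_dim {self.hidden_dim} not divisible by "
                f"attn_tokens {self.attn_tokens}"
            )
        if (self.hidden_dim // self.attn_tokens) % self.attn_heads != 0:
            raise ValidationError("token dim not divisible by attn_heads")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must be in [0, 1)")


def fuse(biomarkers: np.ndarray, embedding: np.ndarray) -> np.ndarray:
    """Early fusion: concatenate [biomarkers ∥ embedding].

    Both blocks are expected to be z-score standardized beforehand so
    neither modality dominates by scale.
    """
    b = np.atleast_2d(np.asarray(biomarkers, dtype=np.float64))
    e = np.atleast_2d(np.asarray(embedding, dtype=np.float64))
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(e))):
        raise ValidationError("non-finite values in fusion inputs")
    fused = np.concatenate([b, e], axis=1)
    return fused[0] if np.asarray(biomarkers).ndim == 1 else fused


class HybridFusionClassifier(Module):
    """Block A -> Block B -> softmax head (see module docstring)."""

    def __init__(self, cfg: ClassifierConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.dropout_rng = np.random.default_rng(seed + 1)
        h, p = cfg.hidden_dim, cfg.dropout
        # Block A
        self.a_fc1 = Linear(cfg.input_dim, h, rng)
        self.a_fc2 = Linear(h, h, rng)
        self.a_bn = BatchNorm1d(h) if cfg.use_batch_norm else _Identity()
        self.a_skip = Linear(cfg.input_dim, h, rng)  # learned skip projection
        self.a_drop1 = Dropout(p, self.dropout_rng)
        self.a_drop2 = Dropout(p, self.dropout_rng)
        # Block B
        d_tok = h // cfg.attn_tokens
        self.b_ln1 = LayerNorm(d_tok)
        self.b_attn = MultiHeadSelfAttention(d_tok, cfg.attn_heads, rng)
        self.b_ln2 = LayerNorm(d_tok)
        self.b_ff1 = Linear(d_tok, cfg.ffn_dim, rng)
        self.b_ff2 = Linear(cfg.ffn_dim, d_tok, rng)
        self.b_drop1 = Dropout(p, self.dropout_rng)
        self.b_drop2 = Dropout(p, self.dropout_rng)
        # head
        self.h_fc1 = Linear(h, cfg.head_hidden, rng)
        self.h_bn = BatchNorm1d(cfg.head_hidden) if cfg.use_batch_norm else _Identity()
        self.h_drop = Dropout(p, self.dropout_rng)
        self.h_fc2 = Linear(cfg.head_hidden, cfg.n_classes, rng)

    # ------------------------------------------------------------- blocks
    def block_a(self, x: Tensor) -> Tensor:
        """h_A = BN(Drop(ReLU(Dense2(Drop(ReLU(Dense1(x))))))) + P x."""
        h = self.a_drop1(self.a_fc1(x).relu())
        h = self.a_bn(self.a_drop2(self.a_fc2(h).relu()))
        return h + self.a_skip(x)

    def block_b(self, h_a: Tensor) -> Tensor:
        """Token-reshaped MHSA + FFN with a whole-block residual skip."""
        B = h_a.shape[0]
        S = self.cfg.attn_tokens
        d_tok = self.cfg.hidden_dim // S
        tokens = h_a.reshape(B, S, d_tok)
        u = self.b_drop1(self.b_attn(self.b_ln1(tokens)))
        v = self.b_drop2(self.b_ff2(self.b_ff1(self.b_ln2(u)).relu()))
        return v.reshape(B, S * d_tok) + h_a

    def head(self, h_b: Tensor) -> Tensor:
        """Softmax class probabilities from the 2-logit head."""
        z = self.h_drop(self.h_bn(self.h_fc1(h_b).relu()))
        return softmax(self.h_fc2(z), axis=-1)

    def forward_tensor(self, x: Tensor) -> Tensor:
        return self.head(self.block_b(self.block_a(x)))

    # ------------------------------------------------------ numpy surface
    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.cfg.input_dim:
            raise ValidationError(
                f"input dim {X.shape[1]} != configured {self.cfg.input_dim}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Eval-mode class probabilities, shape (n, n_classes)."""
        self.eval()
        return self.forward_tensor(Tensor(self._check_input(X))).data

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    # -------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Single-file checkpoint: parameters + config for shape checks."""
        state = self.state_dict()
        cfg = {f"__cfg_{k}": v for k, v in vars(self.cfg).items()}
        np.savez(path, **state, **cfg)

    @classmethod
    def load(cls, path) -> "HybridFusionClassifier":
        with np.load(path) as data:
            cfg_kwargs = {
                k[len("__cfg_"):]: v.item() for k, v in data.items()
                if k.startswith("__cfg_")
            }
            model = cls(ClassifierConfig(**cfg_kwargs))
            state = {k: v for k, v in data.items() if not k.startswith("__cfg_")}
        model.load_state_dict(state)
        return model


@dataclass(frozen=True)
class Prediction:
    """Class probabilities, argmax class and confidence for one sample."""

    probabilities: np.ndarray        # (n_classes,), sums to 1
    predicted_class: int
    confidence: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValidationError("probabilities must be >= 0 and sum to 1")
        object.__setattr__(self, "probabilities", p)


def predict_one(
    model: HybridFusionClassifier,
    biomarkers: np.ndarray,
    embedding: np.ndarray,
) -> Prediction:
    """Fuse one sample's modalities and classify it (eval mode)."""
    proba = model.predict_proba(fuse(biomarkers, embedding))[0]
    cls = int(np.argmax(proba))
    return Prediction(probabilities=proba, predicted_class=cls,
                      confidence=float(proba[cls]))


def cross_entropy(proba: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy -sum_c y_c log(ŷ_c) with one-hot y."""
    proba = np.atleast_2d(np.asarray(proba, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    picked = proba[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.maximum(picked, _LOG_FLOOR))))


def cross_entropy_tensor(proba: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable mean cross-entropy on predicted probabilities."""
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    onehot = np.eye(proba.shape[1])[labels]
    return -(Tensor(onehot) * (proba + _LOG_FLOOR).log()).sum() * (1.0 / len(labels))
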