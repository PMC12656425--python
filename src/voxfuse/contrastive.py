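"""Self-supervised contrastive speech embeddings (SimCLR-style, NT-Xent).

A strided convolutional feature encoder turns a raw 16 kHz waveform into
a token sequence (cumulative stride 320, about 50 tokens/s — the
familiar token rate of wav2vec-family models), followed by a small
transformer.  Utterance embeddings are temporal mean-pools of the token
matrix.  During pretraining, two independently augmented views of each
utterance are pushed together and all other views pushed apart by the
normalized temperature-scaled cross-entropy (NT-Xent) loss

    L_{i,j} = -log exp(sim(h_i, h_j)/tau) / sum_{k != i} exp(sim(h_i, h_k)/tau)

over projected views h, with cosine similarity and a learnable
temperature tau.  No labels are consumed anywhere in this module.

The default hidden size is 768 to match the published encoder family the
architecture emulates; a desk-scale configuration (d = 32) is used for
training experiments and tests.  Any external object mapping a Waveform
to a token matrix can be registered as an encoder adapter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Protocol, Sequence, Tuple

import numpy as np

from voxfuse._autodiff import Tensor, logsumexp
from voxfuse.audio import Waveform
from voxfuse.errors import EmptyInputError, ValidationError
from voxfuse.nn import Adam, ConvStack, Linear, Module, TransformerBlock


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the speech encoder and its projection head."""

    hidden_dim: int = 768            # d, token/embedding dimension
    conv_widths: Tuple[int, ...] = (10, 8, 8, 8)
    conv_strides: Tuple[int, ...] = (5, 4, 4, 4)   # cumulative 320
    attention_layers: int = 2
    heads: int = 4
    ffn_dim: int = 256
    projection_dim: int = 128        # d', contrastive head output
    temperature_init: float = 0.07   # tau_0, learnable

    def __post_init__(self) -> None:
        if self.hidden_dim < 8:
            raise ValidationError("hidden_dim must be >= 8")
        if self.projection_dim > self.hidden_dim:
            raise ValidationError("projection_dim must be <= hidden_dim")
        if self.temperature_init <= 0:
            raise ValidationError("temperature_init must be > 0")

    @property
    def token_rate(self) -> float:
        """Tokens per second at 16 kHz input."""
        return 16000.0 / float(np.prod(self.conv_strides))


@dataclass(frozen=True)
class AugmentationConfig:
    """Stochastic view-generation parameters for contrastive pretraining."""

    time_mask_max: float = 1.2       # s, masked segment replaced by silence
    noise_snr_range: Tuple[float, float] = (25.0, 30.0)  # dB
    shift_max_frac: float = 0.05     # circular shift, fraction of duration
    apply_prob: float = 0.5          # each augmentation, independently

    def __post_init__(self) -> None:
        if self.time_mask_max < 0:
            raise ValidationError("time_mask_max must be >= 0")
        if self.noise_snr_range[0] > self.noise_snr_range[1]:
            raise ValidationError("noise_snr_range must be (low, high)")
        if not (0.0 <= self.shift_max_frac < 1.0):
            raise ValidationError("shift_max_frac must be in [0, 1)")


class SpeechEncoder(Module):
    """Conv stack + transformer encoder with a 2-layer projection head."""

    def __init__(self, cfg: EncoderConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.conv = ConvStack(cfg.conv_widths, cfg.conv_strides, cfg.hidden_dim, rng)
        self.blocks = [
            TransformerBlock(cfg.hidden_dim, cfg.heads, cfg.ffn_dim, rng)
            for _ in range(cfg.attention_layers)
        ]
        self.proj1 = Linear(cfg.hidden_dim, cfg.hidden_dim, rng)
        self.proj2 = Linear(cfg.hidden_dim, cfg.projection_dim, rng)
        # learnable temperature, parameterized on the log scale for positivity
        self.log_tau = Tensor(np.array(math.log(cfg.temperature_init)), requires_grad=True)

    @property
    def tau(self) -> float:
        return float(np.exp(self.log_tau.data))

    def encode_tensor(self, x: Tensor) -> Tensor:
        """(B, T, 1) waveform batch -> (B, T', d) token batch."""
        h = self.conv(x)
        for block in self.blocks:
            h = block(h)
        return h

    def project_tensor(self, pooled: Tensor) -> Tensor:
        """(B, d) pooled embeddings -> (B, d') contrastive projections."""
        return self.proj2(self.proj1(pooled).relu())

    def save(self, path) -> None:
        """Single-file checkpoint with config for shape verification."""
        cfg = {}
        for k, v in vars(self.cfg).items():
            cfg[f"__cfg_{k}"] = np.asarray(v)
        np.savez(path, **self.state_dict(), **cfg)

    @classmethod
    def load(cls, path) -> "SpeechEncoder":
        with np.load(path) as data:
            kwargs = {}
            for k, v in data.items():
                if k.startswith("__cfg_"):
                    name = k[len("__cfg_"):]
                    kwargs[name] = tuple(int(x) for x in v) if v.ndim else v.item()
            enc = cls(EncoderConfig(**kwargs))
            state = {k: v for k, v in data.items() if not k.startswith("__cfg_")}
        enc.load_state_dict(state)
        enc.eval()
        return enc


class EncoderAdapter(Protocol):
    """Adapter protocol: anything mapping a Waveform to a (T', d) token matrix
    can stand in for the built-in encoder (e.g. a wrapper over published
    pretrained weights)."""

    def __call__(self, w: Waveform) -> np.ndarray: ...


def encode(w: Waveform, enc: "SpeechEncoder | EncoderAdapter") -> np.ndarray:
    """Token matrix z = f_theta(x), shape (T', d); deterministic in eval mode."""
    if not isinstance(enc, SpeechEncoder):
        return np.asarray(enc(w), dtype=np.float64)
    if len(w) < enc.conv.receptive_field:
        raise ValidationError(
            f"waveform of {len(w)} samples is shorter than the encoder "
            f"receptive field ({enc.conv.receptive_field} samples)"
        )
    enc.eval()
    x = Tensor(w.samples.reshape(1, -1, 1))
    return enc.encode_tensor(x).data[0]


def mean_pool(tokens: np.ndarray) -> np.ndarray:
    """Utterance embedding: temporal mean over the T' tokens."""
    tokens = np.asarray(tokens, dtype=np.float64)
    if tokens.ndim != 2 or tokens.shape[0] < 1:
        raise EmptyInputError("mean_pool requires a non-empty (T', d) token matrix")
    return tokens.mean(axis=0)


def project(embedding: np.ndarray, enc: SpeechEncoder) -> np.ndarray:
    """Projection-head output h = g_phi(z̄); a training-time quantity only
    (the downstream embedding is the un-projected mean pool)."""
    embedding = np.asarray(embedding, dtype=np.float64)
    if embedding.shape[-1] != enc.cfg.hidden_dim:
        raise ValidationError(
            f"embedding dim {embedding.shape[-1]} does not match encoder "
            f"hidden_dim {enc.cfg.hidden_dim}"
        )
    return enc.project_tensor(Tensor(embedding.reshape(1, -1))).data[0]


def embed_utterance(w: Waveform, enc: "SpeechEncoder | EncoderAdapter") -> np.ndarray:
    """Final utterance embedding: mean-pooled encoder tokens (dim d)."""
    return mean_pool(encode(w, enc))


# --------------------------------------------------------------------------
# augmentation

def augment_view(
    w: Waveform, cfg: AugmentationConfig, rng: np.random.Generator
) -> Waveform:
    """One stochastic view: time mask -> additive noise -> circular shift.

    Each step is applied independently with probability ``apply_prob``,
    in that fixed order; length and rate are preserved.
    """
    if len(w) == 0:
        raise EmptyInputError("cannot augment an empty waveform")
    x = w.samples.copy()
    n = x.size

    if cfg.time_mask_max > 0 and rng.random() < cfg.apply_prob:
        mask_len = int(rng.uniform(0.0, cfg.time_mask_max) * w.rate)
        # a positive view must retain content: never mask more than half
        mask_len = min(mask_len, n // 2)
        if mask_len > 0:
            start = int(rng.integers(0, n - mask_len))
            x[start : start + mask_len] = 0.0

    if rng.random() < cfg.apply_prob:
        snr_db = rng.uniform(*cfg.noise_snr_range)
        rms = math.sqrt(float(np.mean(x**2)))
        if rms > 0:
            noise_rms = rms * 10.0 ** (-snr_db / 20.0)
            x = x + rng.normal(0.0, noise_rms, n)

    if cfg.shift_max_frac > 0 and rng.random() < cfg.apply_prob:
        shift = int(rng.uniform(-cfg.shift_max_frac, cfg.shift_max_frac) * n)
        x = np.roll(x, shift)

    return Waveform(x, w.rate)


# --------------------------------------------------------------------------
# NT-Xent loss

@dataclass
class ContrastiveBatch:
    """2N projected views with a positive-pair index.

    ``projections`` has shape (2N, d'); ``pair_index[i]`` names the view
    forming a positive pair with view i (a fixed-point-free involution).
    The batch carries no labels: positives come from augmentation alone.
    """

    projections: np.ndarray
    pair_index: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.projections, dtype=np.float64)
        idx = np.asarray(self.pair_index, dtype=int)
        if P.shape[0] % 2 != 0:
            raise ValidationError("batch size must be even (two views per utterance)")
        ar = np.arange(P.shape[0])
        if idx.shape != ar.shape or np.any(idx[idx] != ar) or np.any(idx == ar):
            raise ValidationError("pair_index must be a fixed-point-free involution")
        self.projections = P
        self.pair_index = idx

    @classmethod
    def from_interleaved(cls, projections: np.ndarray) -> "ContrastiveBatch":
        """Views ordered (utt0-view0, utt0-view1, utt1-view0, ...)."""
        m = np.asarray(projections).shape[0]
        idx = np.arange(m) + np.where(np.arange(m) % 2 == 0, 1, -1)
        return cls(projections=np.asarray(projections), pair_index=idx)


def _nt_xent_tensor(P: Tensor, pair_index: np.ndarray, tau: Tensor) -> Tensor:
    """Differentiable NT-Xent over (2N, d') projections."""
    m = P.shape[0]
    norms = (P**2).sum(axis=1, keepdims=True) ** 0.5
    if np.any(norms.data <= 1e-12):
        raise ValidationError("zero-norm projection: cosine similarity undefined")
    Z = P / norms
    sim = (Z @ Z.swapaxes(0, 1)) / tau
    # exclude self-similarity from the denominator via a large negative mask
    mask = Tensor(np.where(np.eye(m, dtype=bool), -1e30, 0.0))
    denom = logsumexp(sim + mask, axis=1).reshape(m)
    pos = sim[np.arange(m), pair_index]
    return (denom - pos).mean()


def nt_xent_loss(batch: ContrastiveBatch, tau: float) -> float:
    """NT-Xent loss averaged over all 2N ordered positive pairs.

    With N = 1 the denominator contains only the positive term, so the
    loss is exactly 0 for any temperature.
    """
    if tau <= 0:
        raise ValidationError("temperature must be > 0")
    return float(
        _nt_xent_tensor(
            Tensor(batch.projections), batch.pair_index, Tensor(np.array(tau))
        ).data
    )


# --------------------------------------------------------------------------
# pretraining

@dataclass(frozen=True)
class PretrainConfig:
    """Desk-scale contrastive pretraining loop parameters."""

    epochs: int = 5
    batch_size: int = 8              # utterances per batch (2x views)
    lr: float = 1e-3
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)


def pretrain_contrastive(
    corpus: Sequence[Waveform],
    enc_cfg: EncoderConfig,
    train_cfg: Optional[PretrainConfig] = None,
    seed: int = 0,
) -> Tuple[SpeechEncoder, List[float]]:
    """Train an encoder with NT-Xent on an unlabeled waveform corpus.

    Returns the trained encoder (left in eval mode) and the per-epoch
    mean loss history.  The corpus type carries no labels, so the
    self-supervised stage cannot read them even by accident; the
    temperature is updated by gradient alongside the network weights.
    """
    train_cfg = train_cfg or PretrainConfig()
    if len(corpus) < train_cfg.batch_size:
        raise ValidationError(
            f"corpus of {len(corpus)} utterances is smaller than one batch "
            f"({train_cfg.batch_size})"
        )
    rng = np.random.default_rng(seed)
    enc = SpeechEncoder(enc_cfg, seed=seed)
    enc.train()
    opt = Adam(enc.parameters(), lr=train_cfg.lr)

    min_len = min(len(w) for w in corpus)
    history: List[float] = []
    order = np.arange(len(corpus))
    for _ in range(train_cfg.epochs):
        rng.shuffle(order)
        epoch_losses = []
        for b0 in range(0, len(order) - train_cfg.batch_size + 1, train_cfg.batch_size):
            idx = order[b0 : b0 + train_cfg.batch_size]
            views = []
            for i in idx:
                w = corpus[i]
                for _ in range(2):
                    v = augment_view(w, train_cfg.augmentation, rng)
                    views.append(v.samples[:min_len])
            x = Tensor(np.stack(views)[:, :, None])
            tokens = enc.encode_tensor(x)
            pooled = tokens.mean(axis=1)
            proj = enc.project_tensor(pooled)
            m = proj.shape[0]
            pair = np.arange(m) + np.where(np.arange(m) % 2 == 0, 1, -1)
            loss = _nt_xent_tensor(proj, pair, enc.log_tau.exp())
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))
    enc.eval()
    return enc, history
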