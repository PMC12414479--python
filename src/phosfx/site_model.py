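"""Task-1 model: functional phosphosite classification from the full
per-residue embedding of one protein.

Architecture: a linear projection of the D-dim embedding rows to the
model width, a stack of 1-D convolutional blocks (kernel 7, GELU, post-
block LayerNorm, residual) that widens the receptive field around every
residue, an attention decoder whose single query is the encoded row of
the target residue (self-attention over the query stream, then cross-
attention over all encoder rows), and a three-layer feed-forward
classifier with a softmax pair output.

The whole sequence is encoded end to end; no windowing is applied in this
task — convolutions provide the local receptive field and cross-attention
the global context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv1d, LayerNorm, Linear, Module, MultiHeadAttention, Tensor, softmax
from .nn.functional import gelu  # noqa: F401  (re-exported equation primitive)
from .types import EmbeddingMatrix, Prediction


@dataclass(frozen=True)
class SiteModelConfig:
    """Hyperparameters of the site classifier.

    ``input_dim`` is the embedding width D (1024 for ProtBERT, 1280 for
    ESM-2, arbitrary for the mock backend); features are projected to
    ``model_dim`` before the convolutional encoder.
    """

    input_dim: int
    model_dim: int = 64
    conv_layers: int = 3
    kernel_size: int = 7
    heads: int = 8
    decoder_blocks: int = 1
    classifier_hidden: int = 64

    def __post_init__(self) -> None:
        if self.model_dim % self.heads != 0:
            raise ValueError("model_dim must be divisible by heads")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")


class _ConvBlock(Module):
    """conv -> GELU -> LayerNorm, added back onto the input (post-norm)."""

    def __init__(self, dim: int, kernel: int, rng: np.random.Generator):
        self.conv = Conv1d(dim, dim, kernel, rng)
        self.norm = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.norm(self.conv(x).gelu())


class _DecoderBlock(Module):
    """Self-attention over the query stream, then cross-attention into the
    encoder memory; post-norm residual after each attention."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.cross_attn = MultiHeadAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)

    def __call__(self, query: Tensor, memory: Tensor, memory_mask=None) -> Tensor:
        query = query + self.norm1(self.self_attn(query, query))
        query = query + self.norm2(self.cross_attn(query, memory, key_mask=memory_mask))
        return query


class _Classifier(Module):
    """Three fully connected layers with GELU between; final width 2."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, hidden, rng)
        self.fc3 = Linear(hidden, 2, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc3(self.fc2(self.fc1(x).gelu()).gelu())


class SiteModel(Module):
    def __init__(self, cfg: SiteModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.project = Linear(cfg.input_dim, cfg.model_dim, rng)
        self.encoder_blocks = [
            _ConvBlock(cfg.model_dim, cfg.kernel_size, rng) for _ in range(cfg.conv_layers)
        ]
        self.decoder_blocks_ = [
            _DecoderBlock(cfg.model_dim, cfg.heads, rng) for _ in range(cfg.decoder_blocks)
        ]
        self.classifier = _Classifier(cfg.model_dim, cfg.classifier_hidden, rng)
        self._encoded_cache: dict[int, tuple] = {}

    def reset_cache(self) -> None:
        self._encoded_cache = {}

    # -- pieces ------------------------------------------------------------

    def encoder_forward(self, x: Tensor) -> Tensor:
        """Project D -> model_dim, then the convolutional residual stack."""
        if x.shape[-1] != self.cfg.input_dim:
            raise ValueError(
                f"expected {self.cfg.input_dim}-dim embedding rows, got {x.shape[-1]}"
            )
        h = self.project(x)
        for block in self.encoder_blocks:
            h = block(h)
        return h

    def decoder_forward(self, encoded: Tensor, site_index: int) -> Tensor:
        """Refine the target residue's encoded row (the 1-row query stream)
        against the full encoder output; returns a (1, model_dim) tensor."""
        query = encoded[site_index : site_index + 1]
        for block in self.decoder_blocks_:
            query = block(query, encoded)
        return query

    def logits(self, x: Tensor, site_index: int) -> Tensor:
        encoded = self.encoder_forward(x)
        feature = self.decoder_forward(encoded, site_index)
        return self.classifier(feature)

    # -- API ---------------------------------------------------------------

    def forward(self, sample: tuple) -> Tensor:
        """Training-loop interface: sample = (L x D array, 0-based site index).

        The encoder pass is memoised per input array (sites on the same
        protein share it within a batch); the cache is cleared by the
        training loop after every parameter update.
        """
        values, site_index = sample
        cached = self._encoded_cache.get(id(values))
        if cached is None or cached[0] is not values:
            encoded = self.encoder_forward(Tensor(values))
            self._encoded_cache[id(values)] = (values, encoded)
        else:
            encoded = cached[1]
        feature = self.decoder_forward(encoded, int(site_index))
        return self.classifier(feature)

    def predict(self, emb: EmbeddingMatrix | np.ndarray, position: int) -> Prediction:
        """Classify the residue at a 1-based ``position``."""
        values = (
            emb.values
            if isinstance(emb, EmbeddingMatrix)
            else np.asarray(emb, dtype=np.float64)
        )
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite embedding input")
        if not 1 <= position <= values.shape[0]:
            raise ValueError(f"position {position} out of range 1..{values.shape[0]}")
        logits = self.logits(Tensor(values), position - 1)
        probs = softmax(logits, axis=-1).data[0]
        return Prediction(probs=(probs[0], probs[1]))


def classify_site(feature: np.ndarray, classifier: _Classifier) -> Prediction:
    """Run the three-layer classifier head on a feature vector."""
    feature = np.asarray(feature, dtype=np.float64)
    if not np.all(np.isfinite(feature)):
        raise ValueError("non-finite classifier input")
    logits = classifier(Tensor(feature.reshape(1, -1)))
    probs = softmax(logits, axis=-1).data[0]
    return Prediction(probs=(probs[0], probs[1]))
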