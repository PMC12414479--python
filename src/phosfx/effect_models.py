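"""Task-2 submodels: does phosphorylation at a functional site enhance or
inhibit a given protein-protein interaction?

Both submodels consume the same three streams — the 31-residue local
window of protein A centred on the site, the full per-residue embedding
of protein A, and the full embedding of the partner protein B — and emit
an (inhibition, enhancement) probability pair.

* The attention-gated CNN pools each stream with a convolutional branch
  (kernel 7, GELU, LayerNorm, masked sum pooling) and fuses the three
  pooled vectors with a scalar sigmoid gate alpha:
  h = alpha*h_local + alpha*h_globalA + (1-alpha)*h_globalB.
  The gate's weights are deliberately left unnormalised (they need not
  sum to 1); a config switch offers the convex variant for ablation.
* The Transformer submodel projects each stream to the model width,
  refines the global streams with conv + gated-linear-unit residual
  blocks, concatenates the two encoded globals into a cross-attention
  memory, and runs three decoder blocks (masked self-attention over the
  31 local positions, cross-attention into the memory, position-wise
  feed-forward), mean-pooling the unmasked local positions at the end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Conv1d,
    FeedForward,
    GroupNorm,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    Tensor,
    concat,
    softmax,
)
from .nn.functional import glu  # noqa: F401  (re-exported equation primitive)
from .types import EmbeddingMatrix, Prediction
from .windowing import SiteWindow


@dataclass(frozen=True)
class EffectInput:
    """One Task-2 sample: local window of A (with embedding attached),
    global embeddings of A and B. All three must share the embedding
    dimension, and the window must come from protein A."""

    local_a: SiteWindow
    global_a: EmbeddingMatrix
    global_b: EmbeddingMatrix

    def __post_init__(self) -> None:
        if self.local_a.window_emb is None:
            raise ValueError("local window has no embedding attached")
        d = self.local_a.window_emb.shape[1]
        if not (d == self.global_a.dim == self.global_b.dim):
            raise ValueError(
                f"embedding dims differ: window {d}, A {self.global_a.dim}, "
                f"B {self.global_b.dim}"
            )
        if self.local_a.protein_id != self.global_a.protein_id:
            raise ValueError("local window must be cut from protein A")

    @property
    def dim(self) -> int:
        return self.global_a.dim


@dataclass(frozen=True)
class EffectModelConfig:
    input_dim: int
    model_dim: int = 64
    kernel_size: int = 7
    heads: int = 8
    decoder_blocks: int = 3
    groupnorm_groups: int = 8
    ffn_hidden: int = 128
    normalize_fusion: bool = False
    #: Transformer decoder readout: masked mean over the window positions
    #: ("mean", default; scale independent of pad count) or the centre
    #: (site) position's row ("center").
    decoder_readout: str = "mean"

    def __post_init__(self) -> None:
        if self.model_dim % self.heads != 0:
            raise ValueError("model_dim must be divisible by heads")
        if self.model_dim % self.groupnorm_groups != 0:
            raise ValueError("model_dim must be divisible by groupnorm_groups")
        if self.decoder_readout not in ("center", "mean"):
            raise ValueError("decoder_readout must be 'center' or 'mean'")


# ---------------------------------------------------------------------------
# attention-gated CNN
# ---------------------------------------------------------------------------


class ConvPoolBranch(Module):
    """conv1d -> GELU -> LayerNorm -> masked sum pooling -> fixed vector."""

    def __init__(self, in_dim: int, out_dim: int, kernel: int, rng: np.random.Generator):
        self.conv = Conv1d(in_dim, out_dim, kernel, rng)
        self.norm = LayerNorm(out_dim)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        if mask is not None:
            mask = np.asarray(mask, dtype=np.float64)
            if mask.sum() == 0:
                raise ValueError("conv-pool branch: mask excludes every position")
        h = self.norm(self.conv(x).gelu())
        if mask is not None:
            h = h * mask.reshape(-1, 1)
        return h.sum(axis=0, keepdims=True)


class AttentionFusion(Module):
    """Scalar sigmoid gate over the concatenated pooled streams.

    alpha = sigmoid(W [h_l; h_gA; h_gB] + b); the fused vector is
    alpha*h_l + alpha*h_gA + (1-alpha)*h_gB (weights unnormalised by
    design; ``normalize`` divides by their sum for the convex variant).
    """

    def __init__(self, dim: int, rng: np.random.Generator, normalize: bool = False):
        self.weight = Tensor(
            rng.uniform(-1, 1, size=(3 * dim, 1)) * np.sqrt(1.0 / (3 * dim)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(1), requires_grad=True)
        self.normalize = normalize

    def __call__(self, h_l: Tensor, h_ga: Tensor, h_gb: Tensor) -> tuple[Tensor, Tensor]:
        if not (h_l.shape == h_ga.shape == h_gb.shape):
            raise ValueError("fusion inputs must share their length")
        stacked = concat([h_l, h_ga, h_gb], axis=-1)
        alpha = (stacked @ self.weight + self.bias).sigmoid()
        fused = alpha * h_l + alpha * h_ga + (1.0 - alpha) * h_gb
        if self.normalize:
            fused = fused / (alpha + alpha + (1.0 - alpha))
        return alpha, fused


def attention_fusion(h_l, h_ga, h_gb, weight, bias, normalize: bool = False):
    """Functional form of the gate (arrays in, (alpha, fused) arrays out)."""
    module = AttentionFusion.__new__(AttentionFusion)
    module.weight = Tensor(np.asarray(weight, dtype=np.float64).reshape(-1, 1))
    module.bias = Tensor(np.atleast_1d(np.asarray(bias, dtype=np.float64)))
    module.normalize = normalize
    alpha, fused = module(
        Tensor(np.atleast_2d(h_l)), Tensor(np.atleast_2d(h_ga)), Tensor(np.atleast_2d(h_gb))
    )
    return float(alpha.data.ravel()[0]), fused.data.ravel()


class _EffectClassifier(Module):
    """Three fully connected layers; GELU + GroupNorm after the hidden ones."""

    def __init__(self, dim: int, groups: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, dim, rng)
        self.gn1 = GroupNorm(groups, dim)
        self.fc2 = Linear(dim, dim, rng)
        self.gn2 = GroupNorm(groups, dim)
        self.fc3 = Linear(dim, 2, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.gn1(self.fc1(x).gelu())
        h = self.gn2(self.fc2(h).gelu())
        return self.fc3(h)


class AttCNNEffectModel(Module):
    """The attention-gated CNN submodel."""

    def __init__(self, cfg: EffectModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        k = cfg.kernel_size
        self.local_branch = ConvPoolBranch(cfg.input_dim, cfg.model_dim, k, rng)
        self.global_a_branch = ConvPoolBranch(cfg.input_dim, cfg.model_dim, k, rng)
        self.global_b_branch = ConvPoolBranch(cfg.input_dim, cfg.model_dim, k, rng)
        self.fusion = AttentionFusion(cfg.model_dim, rng, normalize=cfg.normalize_fusion)
        self.classifier = _EffectClassifier(cfg.model_dim, cfg.groupnorm_groups, rng)
        self._pool_cache: dict[tuple[str, int], tuple] = {}

    def reset_cache(self) -> None:
        self._pool_cache = {}

    def _pooled(self, branch: ConvPoolBranch, tag: str, values: np.ndarray) -> Tensor:
        # global streams repeat across samples; memoise per input array
        key = (tag, id(values))
        cached = self._pool_cache.get(key)
        if cached is not None and cached[0] is values:
            return cached[1]
        out = branch(Tensor(values))
        self._pool_cache[key] = (values, out)
        return out

    def logits(self, sample: EffectInput) -> Tensor:
        h_l = self.local_branch(Tensor(sample.local_a.window_emb), mask=sample.local_a.mask)
        h_ga = self._pooled(self.global_a_branch, "a", sample.global_a.values)
        h_gb = self._pooled(self.global_b_branch, "b", sample.global_b.values)
        _, fused = self.fusion(h_l, h_ga, h_gb)
        return self.classifier(fused)

    forward = logits

    def predict(self, sample: EffectInput) -> Prediction:
        probs = softmax(self.logits(sample), axis=-1).data[0]
        return Prediction(probs=(probs[0], probs[1]))


# ---------------------------------------------------------------------------
# Transformer submodel
# ---------------------------------------------------------------------------


class _GLUConvBlock(Module):
    """conv1d -> gated linear unit, residual onto the input, LayerNorm."""

    def __init__(self, dim: int, kernel: int, rng: np.random.Generator):
        self.conv = Conv1d(dim, dim, kernel, rng)
        self.w1 = Linear(dim, dim, rng)
        self.w2 = Linear(dim, dim, rng)
        self.norm = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        c = self.conv(x)
        gated = self.w1(c) * self.w2(c).sigmoid()
        return self.norm(x + gated)


class _TransformerDecoderBlock(Module):
    def __init__(self, dim: int, heads: int, ffn_hidden: int, rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.cross_attn = MultiHeadAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_hidden, rng)
        self.norm3 = LayerNorm(dim)

    def __call__(
        self,
        local: Tensor,
        memory_kv: tuple[Tensor, Tensor],
        local_mask: np.ndarray,
    ) -> Tensor:
        local = local + self.norm1(self.self_attn(local, local, key_mask=local_mask))
        local = local + self.norm2(self.cross_attn.attend(local, memory_kv))
        local = local + self.norm3(self.ffn(local))
        return local

    def batched(
        self,
        local: Tensor,
        memory_kv: tuple[Tensor, Tensor],
        local_mask: np.ndarray,
        memory_mask: np.ndarray,
    ) -> Tensor:
        self_kv = self.self_attn.project_kv_batched(local)
        local = local + self.norm1(
            self.self_attn.attend_batched(local, self_kv, key_mask=local_mask)
        )
        local = local + self.norm2(
            self.cross_attn.attend_batched(local, memory_kv, key_mask=memory_mask)
        )
        local = local + self.norm3(self.ffn(local))
        return local


class TransformerEffectModel(Module):
    """The Transformer submodel with cross-attention over both proteins."""

    def __init__(self, cfg: EffectModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        d, k = cfg.model_dim, cfg.kernel_size
        self.local_proj = Linear(cfg.input_dim, d, rng)
        self.global_a_proj = Linear(cfg.input_dim, d, rng)
        self.global_b_proj = Linear(cfg.input_dim, d, rng)
        self.global_a_block = _GLUConvBlock(d, k, rng)
        self.global_b_block = _GLUConvBlock(d, k, rng)
        self.decoder_blocks_ = [
            _TransformerDecoderBlock(d, cfg.heads, cfg.ffn_hidden, rng)
            for _ in range(cfg.decoder_blocks)
        ]
        self.fc1 = Linear(d, d, rng)
        self.fc2 = Linear(d, d, rng)
        self.fc3 = Linear(d, 2, rng)
        self._enc_cache: dict[tuple[str, int], tuple] = {}

    def reset_cache(self) -> None:
        self._enc_cache = {}

    def _encode_stream(self, tag: str, values: np.ndarray) -> Tensor:
        # proteins recur across pairs; memoise the heavy global encoding
        key = (tag, id(values))
        cached = self._enc_cache.get(key)
        if cached is not None and cached[0] is values:
            return cached[1]
        proj = self.global_a_proj if tag == "a" else self.global_b_proj
        block = self.global_a_block if tag == "a" else self.global_b_block
        out = block(proj(Tensor(values)))
        self._enc_cache[key] = (values, out)
        return out

    def encoder_forward(self, global_a: Tensor, global_b: Tensor) -> Tensor:
        """Encode both global streams; the concatenated rows (L_A + L_B)
        form the cross-attention memory."""
        enc_a = self.global_a_block(self.global_a_proj(global_a))
        enc_b = self.global_b_block(self.global_b_proj(global_b))
        return concat([enc_a, enc_b], axis=0)

    def _stream_kv(self, tag: str, values: np.ndarray) -> list[tuple[Tensor, Tensor]]:
        """Per-decoder-block cross-attention K/V of one encoded stream,
        memoised per protein (projections are row-wise, so concatenating
        cached per-stream K/V equals projecting the concatenated memory)."""
        key = ("kv", tag, id(values))
        cached = self._enc_cache.get(key)
        if cached is not None and cached[0] is values:
            return cached[1]
        encoded = self._encode_stream(tag, values)
        kv = [block.cross_attn.project_kv(encoded) for block in self.decoder_blocks_]
        self._enc_cache[key] = (values, kv)
        return kv

    def _run_decoder(
        self,
        local: Tensor,
        memory_kvs: list[tuple[Tensor, Tensor]],
        mask: np.ndarray,
    ) -> Tensor:
        mask = np.asarray(mask, dtype=np.float64)
        if mask.sum() == 0:
            raise ValueError("decoder: the local window is entirely padding")
        h = local
        for block, kv in zip(self.decoder_blocks_, memory_kvs):
            h = block(h, kv, mask.astype(bool))
        if self.cfg.decoder_readout == "center":
            centre = (h.shape[0] - 1) // 2
            return h[centre : centre + 1]
        return (h * mask.reshape(-1, 1)).sum(axis=0, keepdims=True) * (1.0 / mask.sum())

    def decoder_forward(self, local: Tensor, memory: Tensor, mask: np.ndarray) -> Tensor:
        """Run the decoder stack over the 31 local positions and mean-pool
        the unmasked ones into a single feature vector."""
        kvs = [block.cross_attn.project_kv(memory) for block in self.decoder_blocks_]
        return self._run_decoder(local, kvs, mask)

    def logits(self, sample: EffectInput) -> Tensor:
        local = self.local_proj(Tensor(sample.local_a.window_emb))
        kv_a = self._stream_kv("a", sample.global_a.values)
        kv_b = self._stream_kv("b", sample.global_b.values)
        memory_kvs = [
            (concat([ka, kb], axis=1), concat([va, vb], axis=1))
            for (ka, va), (kb, vb) in zip(kv_a, kv_b)
        ]
        pooled = self._run_decoder(local, memory_kvs, sample.local_a.mask)
        return self.fc3(self.fc2(self.fc1(pooled).gelu()).gelu())

    def forward_batch(self, samples: list[EffectInput]) -> Tensor:
        """Vectorised forward over a minibatch: (B, 2) logits.

        Local windows share the fixed window length, so they stack into a
        dense (B, 2w+1, D) block; the per-protein encoded memories (cached)
        are padded to the batch's longest memory and masked.
        """
        B = len(samples)
        locals_np = np.stack([s.local_a.window_emb for s in samples])
        local_masks = np.stack([s.local_a.mask for s in samples]).astype(bool)
        if not local_masks.any(axis=1).all():
            raise ValueError("decoder: a local window is entirely padding")
        local = self.local_proj(Tensor(locals_np))

        kv_a = [self._stream_kv("a", s.global_a.values) for s in samples]
        kv_b = [self._stream_kv("b", s.global_b.values) for s in samples]
        mem_lens = [
            s.global_a.length + s.global_b.length for s in samples
        ]
        L_max = max(mem_lens)
        memory_mask = np.zeros((B, L_max), dtype=bool)
        for i, n in enumerate(mem_lens):
            memory_mask[i, :n] = True

        def stack_kv(block_idx: int, part: int) -> Tensor:
            pieces = []
            for i, s in enumerate(samples):
                merged = concat(
                    [kv_a[i][block_idx][part], kv_b[i][block_idx][part]], axis=1
                )
                pad = L_max - mem_lens[i]
                if pad:
                    merged = (
                        merged.transpose(1, 0, 2).pad_rows(0, pad).transpose(1, 0, 2)
                    )
                pieces.append(merged.reshape(1, *merged.shape))
            return concat(pieces, axis=0)

        h = local
        for bi, block in enumerate(self.decoder_blocks_):
            memory_kv = (stack_kv(bi, 0), stack_kv(bi, 1))
            h = block.batched(h, memory_kv, local_masks, memory_mask)
        if self.cfg.decoder_readout == "center":
            centre = (h.shape[1] - 1) // 2
            pooled = h[:, centre]
        else:
            weights = local_masks.astype(np.float64)[:, :, None]
            pooled = (h * weights).sum(axis=1) * (1.0 / weights.sum(axis=1))
        return self.fc3(self.fc2(self.fc1(pooled).gelu()).gelu())

    forward = logits

    def predict(self, sample: EffectInput) -> Prediction:
        probs = softmax(self.logits(sample), axis=-1).data[0]
        return Prediction(probs=(probs[0], probs[1]))


def conv_pool_branch(x: np.ndarray, mask, branch: ConvPoolBranch) -> np.ndarray:
    """Functional form of a pooled convolutional branch (arrays in/out)."""
    out = branch(Tensor(np.asarray(x, dtype=np.float64)), mask=mask)
    return out.data.ravel()


def make_effect_input(
    window: SiteWindow, emb_a: EmbeddingMatrix, emb_b: EmbeddingMatrix
) -> EffectInput:
    from .windowing import window_embedding

    if window.window_emb is None:
        window = window_embedding(window, emb_a)
    return EffectInput(local_a=window, global_a=emb_a, global_b=emb_b)
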