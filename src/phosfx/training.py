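"""Losses, the training loop, ensemble voting, and checkpoints.

Both tasks train with minibatch gradient descent using RAdam wrapped in
Lookahead. Task 1 (balanced site data) uses plain cross-entropy; Task 2
(~70/30 enhancement/inhibition) uses a batch-weighted cross-entropy whose
class weights are recomputed from each batch's label counts, so minority
samples are up-weighted exactly as much as the batch is imbalanced. On a
balanced batch the weighted loss reduces to plain cross-entropy.

The ensemble combines the two Task-2 submodels by soft voting (mean of
the probability pairs, the default), hard voting (per-model thresholded
labels, ties broken by the soft probability), or max-confidence voting
(the more confident submodel wins, ties fall back to soft voting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .nn import Lookahead, Module, RAdam, Tensor
from .types import Prediction

_CLAMP = 1e-12


# ---------------------------------------------------------------------------
# losses (array level)
# ---------------------------------------------------------------------------


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class.

    ``probs`` is (n, 2) with rows summing to 1; probabilities are clamped
    at 1e-12 before the log.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValueError("probs must be an (n, 2) array")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    p_true = np.clip(probs[np.arange(len(labels)), labels], _CLAMP, None)
    return float(np.mean(-np.log(p_true)))


def batch_weighted_ce(probs: np.ndarray, labels: np.ndarray) -> float:
    """Cross-entropy with inverse in-batch class-frequency weights.

    Per-class weight w_c = n_batch / (2 * n_c) from THIS batch's label
    counts (a class absent from the batch contributes nothing); the loss
    is the w-weighted mean of -log p(true class), normalised by the sum
    of the sample weights. Equals :func:`cross_entropy` exactly whenever
    the batch is balanced, and also on single-class batches.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(labels) < 1:
        raise ValueError("batch must contain at least one sample")
    n = len(labels)
    weights = np.empty(n, dtype=np.float64)
    for c in (0, 1):
        mask = labels == c
        if mask.any():
            weights[mask] = n / (2.0 * mask.sum())
    p_true = np.clip(probs[np.arange(n), labels], _CLAMP, None)
    return float(np.sum(weights * -np.log(p_true)) / np.sum(weights))


def _log_softmax_row(logits: Tensor) -> Tensor:
    """Row-stable log-softmax for a (1, 2) logits tensor."""
    shift = logits.data.max()  # constant
    z = logits - shift
    return z - z.exp().sum(axis=-1, keepdims=True).log()


def _batched_nll(logits: Tensor, labels: np.ndarray, weights: np.ndarray) -> Tensor:
    """Weighted mean negative log-likelihood from (B, 2) logits."""
    z = logits - logits.data.max(axis=-1, keepdims=True)
    logp = z - z.exp().sum(axis=-1, keepdims=True).log()
    picked = logp[np.arange(len(labels)), labels]
    return (picked * (-weights)).sum() * (1.0 / weights.sum())


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings shared by both tasks.

    ``loss`` selects plain cross-entropy (Task 1) or the batch-weighted
    variant (Task 2). Lookahead defaults follow the standard k=5,
    alpha=0.5.
    """

    epochs: int
    learning_rate: float = 5e-4
    batch_size: int = 128
    seed: int = 0
    task: str = "site"  # "site" | "effect"
    loss: str = "cross_entropy"  # "cross_entropy" | "batch_weighted"
    lookahead_k: int = 5
    lookahead_alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss not in ("cross_entropy", "batch_weighted"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.loss == "batch_weighted" and self.batch_size < 2:
            raise ValueError("batch_weighted loss needs batch_size >= 2")
        if self.task not in ("site", "effect"):
            raise ValueError(f"unknown task {self.task!r}")


def predict_proba(model: Module, samples: Sequence) -> np.ndarray:
    """(n, 2) probability matrix for a sequence of model samples."""
    model.reset_cache()
    out = np.empty((len(samples), 2), dtype=np.float64)
    if hasattr(model, "forward_batch"):
        for start in range(0, len(samples), 64):
            chunk = list(samples[start : start + 64])
            logits = model.forward_batch(chunk).data
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            out[start : start + len(chunk)] = e / e.sum(axis=1, keepdims=True)
        return out
    for i, sample in enumerate(samples):
        logits = model.forward(sample).data.ravel()
        shifted = logits - logits.max()
        e = np.exp(shifted)
        out[i] = e / e.sum()
    return out


def train(
    model: Module,
    dataset: Sequence[tuple],
    cfg: TrainConfig,
    validation: Sequence[tuple] | None = None,
    callback: Callable[[dict], None] | None = None,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Minibatch training; returns (best params, per-epoch history).

    ``dataset`` holds (sample, label) pairs, where ``sample`` is whatever
    the model's ``forward`` accepts. With a validation split the returned
    parameters are those of the best validation-loss epoch; otherwise the
    final parameters. Deterministic for a fixed config (single-threaded).
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    params = model.parameters()
    optimizer = Lookahead(
        RAdam(params, lr=cfg.learning_rate),
        k=cfg.lookahead_k,
        alpha=cfg.lookahead_alpha,
    )
    rng = np.random.default_rng(cfg.seed)
    weighted = cfg.loss == "batch_weighted"
    history: list[dict] = []
    best_val = np.inf
    best_state = None
    n = len(dataset)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            batch_idx = order[start : start + cfg.batch_size]
            labels = np.array([dataset[i][1] for i in batch_idx], dtype=int)
            if weighted:
                w = np.empty(len(labels), dtype=np.float64)
                for c in (0, 1):
                    m = labels == c
                    if m.any():
                        w[m] = len(labels) / (2.0 * m.sum())
            else:
                w = np.ones(len(labels), dtype=np.float64)
            optimizer.zero_grad()
            model.reset_cache()  # parameters changed since the last batch
            if hasattr(model, "forward_batch"):
                logits = model.forward_batch([dataset[i][0] for i in batch_idx])
                loss = _batched_nll(logits, labels, w)
            else:
                terms = []
                for i, wi in zip(batch_idx, w):
                    sample, label = dataset[i]
                    logp = _log_softmax_row(model.forward(sample))
                    terms.append(logp[0, int(label)] * (-wi))
                total = terms[0]
                for t in terms[1:]:
                    total = total + t
                loss = total * (1.0 / w.sum())
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training aborted: non-finite loss at epoch {epoch} "
                    f"(batch starting at {start}); try a lower learning rate"
                )
            loss.backward()
            optimizer.step()
            epoch_loss += value
            n_batches += 1
        entry = {"epoch": epoch, "train_loss": epoch_loss / n_batches}
        if validation is not None and len(validation) > 0:
            val_probs = predict_proba(model, [s for s, _ in validation])
            val_labels = np.array([y for _, y in validation], dtype=int)
            loss_fn = batch_weighted_ce if weighted else cross_entropy
            entry["val_loss"] = loss_fn(val_probs, val_labels)
            if entry["val_loss"] < best_val:
                best_val = entry["val_loss"]
                best_state = model.state_dict()
        history.append(entry)
        if callback is not None:
            callback(entry)
    if best_state is not None:
        model.load_state_dict(best_state)
        return best_state, history
    return model.state_dict(), history


# ---------------------------------------------------------------------------
# voting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoteConfig:
    mechanism: str = "soft"  # "soft" | "hard" | "max_confidence"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.mechanism not in ("soft", "hard", "max_confidence"):
            raise ValueError(f"unknown voting mechanism {self.mechanism!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


def _as_pair(p) -> np.ndarray:
    if isinstance(p, Prediction):
        return np.asarray(p.probs, dtype=np.float64)
    arr = np.asarray(p, dtype=np.float64).ravel()
    if arr.shape != (2,):
        raise ValueError("expected a probability pair")
    if abs(arr.sum() - 1.0) > 1e-6:
        raise ValueError("probability pair must sum to 1")
    return arr


def soft_vote(p1, p2) -> Prediction:
    """Elementwise arithmetic mean of the two probability pairs."""
    mean = 0.5 * (_as_pair(p1) + _as_pair(p2))
    return Prediction(probs=(mean[0], mean[1]))


def hard_vote(p1, p2, threshold: float = 0.5) -> int:
    """Each submodel casts its thresholded label (positive when the
    enhancement probability strictly exceeds the threshold; a tie at the
    threshold votes 0). Agreement wins; a 1-1 split falls back to the
    soft-vote label."""
    v1 = int(_as_pair(p1)[1] > threshold)
    v2 = int(_as_pair(p2)[1] > threshold)
    if v1 == v2:
        return v1
    return soft_vote(p1, p2).label


def max_confidence_vote(p1, p2) -> Prediction:
    """Return the pair of the submodel with the larger maximum class
    probability; an exact tie falls back to soft voting."""
    a, b = _as_pair(p1), _as_pair(p2)
    ca, cb = a.max(), b.max()
    if ca > cb:
        return Prediction(probs=(a[0], a[1]))
    if cb > ca:
        return Prediction(probs=(b[0], b[1]))
    return soft_vote(p1, p2)


def vote(p1, p2, cfg: VoteConfig) -> Prediction | int:
    if cfg.mechanism == "soft":
        return soft_vote(p1, p2)
    if cfg.mechanism == "hard":
        return hard_vote(p1, p2, threshold=cfg.threshold)
    return max_confidence_vote(p1, p2)


def ensemble_scores(probs1: np.ndarray, probs2: np.ndarray) -> np.ndarray:
    """Soft-vote enhancement scores for whole prediction matrices."""
    probs1 = np.asarray(probs1, dtype=np.float64)
    probs2 = np.asarray(probs2, dtype=np.float64)
    return 0.5 * (probs1[:, 1] + probs2[:, 1])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: Module, config: dict, path: str | Path) -> None:
    """Flat named-parameter .npz archive plus a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(config, indent=2, sort_keys=True))


def load_checkpoint(model: Module, path: str | Path) -> dict:
    path = Path(path)
    with np.load(path) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    sidecar = path.with_suffix(path.suffix + ".json")
    return json.loads(sidecar.read_text()) if sidecar.exists() else {}
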