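"""High-level experiment plumbing: records -> features -> models -> metrics.

These helpers connect the data layer (protein/site/pair records), the
embedding backends, the two model families and the evaluation metrics
into runnable experiments. They are what the command-line layer and the
examples call; each returns plain dictionaries/arrays so results are easy
to serialise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .effect_models import (
    AttCNNEffectModel,
    EffectInput,
    EffectModelConfig,
    TransformerEffectModel,
)
from .embedding import EmbeddingBackend, EmbeddingCache, embed_sequence
from .io import split_train_test
from .metrics import full_report
from .site_model import SiteModel, SiteModelConfig
from .training import TrainConfig, ensemble_scores, predict_proba, train
from .types import EmbeddingMatrix, PPIEffectRecord, ProteinRecord, SiteRecord
from .windowing import extract_window, window_embedding


def embed_all(
    proteins: Sequence[ProteinRecord],
    backend: EmbeddingBackend,
    cache: EmbeddingCache | None = None,
) -> dict[str, EmbeddingMatrix]:
    return {p.id: embed_sequence(backend, p, cache=cache) for p in proteins}


def build_site_samples(
    sites: Sequence[SiteRecord],
    embeddings: dict[str, EmbeddingMatrix],
) -> list[tuple[tuple[np.ndarray, int], int]]:
    """Task-1 samples: ((L x D matrix, 0-based site index), label)."""
    samples = []
    for rec in sites:
        emb = embeddings[rec.protein_id]
        if rec.position > emb.length:
            raise ValueError(
                f"site {rec.protein_id}:{rec.position} lies beyond the "
                f"embedded prefix ({emb.length} rows)"
            )
        samples.append(((emb.values, rec.position - 1), rec.label))
    return samples


def build_effect_samples(
    pairs: Sequence[PPIEffectRecord],
    proteins: dict[str, ProteinRecord],
    embeddings: dict[str, EmbeddingMatrix],
    half_width: int = 15,
) -> list[tuple[EffectInput, int]]:
    """Task-2 samples: (EffectInput, label)."""
    samples = []
    for rec in pairs:
        window = extract_window(proteins[rec.protein_a_id], rec.position, half_width)
        window = window_embedding(window, embeddings[rec.protein_a_id])
        sample = EffectInput(
            local_a=window,
            global_a=embeddings[rec.protein_a_id],
            global_b=embeddings[rec.protein_b_id],
        )
        samples.append((sample, rec.label))
    return samples


@dataclass
class ExperimentResult:
    metrics: dict[str, float]
    scores: np.ndarray
    labels: np.ndarray
    history: list[dict]
    model: object


def run_site_experiment(
    sites: Sequence[SiteRecord],
    embeddings: dict[str, EmbeddingMatrix],
    *,
    split_ratio: float = 0.8,
    model_cfg: SiteModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Train and evaluate the site classifier on a stratified split."""
    dim = next(iter(embeddings.values())).dim
    model_cfg = model_cfg or SiteModelConfig(input_dim=dim)
    train_cfg = train_cfg or TrainConfig(epochs=150, seed=seed, task="site")
    train_recs, test_recs = split_train_test(sites, split_ratio, seed=seed)
    train_set = build_site_samples(train_recs, embeddings)
    test_set = build_site_samples(test_recs, embeddings)
    model = SiteModel(model_cfg, seed=seed)
    _, history = train(model, train_set, train_cfg)
    probs = predict_proba(model, [s for s, _ in test_set])
    labels = np.array([y for _, y in test_set], dtype=int)
    return ExperimentResult(
        metrics=full_report(labels, probs[:, 1]),
        scores=probs[:, 1],
        labels=labels,
        history=history,
        model=model,
    )


def run_effect_experiment(
    pairs: Sequence[PPIEffectRecord],
    proteins: Sequence[ProteinRecord],
    embeddings: dict[str, EmbeddingMatrix],
    *,
    split_ratio: float = 0.8,
    model_cfg: EffectModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    half_width: int = 15,
    seed: int = 0,
) -> dict[str, ExperimentResult | dict[str, float]]:
    """Train both effect submodels on the same split and soft-vote them.

    Returns per-submodel :class:`ExperimentResult` objects under
    ``"attcnn"`` and ``"transformer"`` plus the ensemble's metric report
    under ``"ensemble"``.
    """
    dim = next(iter(embeddings.values())).dim
    model_cfg = model_cfg or EffectModelConfig(input_dim=dim)
    train_cfg = train_cfg or TrainConfig(
        epochs=150, seed=seed, task="effect", loss="batch_weighted"
    )
    index = {p.id: p for p in proteins}
    train_recs, test_recs = split_train_test(pairs, split_ratio, seed=seed)
    train_set = build_effect_samples(train_recs, index, embeddings, half_width)
    test_set = build_effect_samples(test_recs, index, embeddings, half_width)
    labels = np.array([y for _, y in test_set], dtype=int)
    test_inputs = [s for s, _ in test_set]

    results: dict[str, ExperimentResult | dict[str, float]] = {}
    probs = {}
    for name, cls in (("attcnn", AttCNNEffectModel), ("transformer", TransformerEffectModel)):
        model = cls(model_cfg, seed=seed)
        _, history = train(model, train_set, train_cfg)
        p = predict_proba(model, test_inputs)
        probs[name] = p
        results[name] = ExperimentResult(
            metrics=full_report(labels, p[:, 1]),
            scores=p[:, 1],
            labels=labels,
            history=history,
            model=model,
        )
    fused = ensemble_scores(probs["attcnn"], probs["transformer"])
    results["ensemble"] = full_report(labels, fused)
    return results


def run_benchmark(
    seed: int,
    *,
    dim: int = 32,
    site_epochs: int = 60,
    effect_epochs: int = 60,
    effect_lr: float = 1e-3,
    batch_size: int = 32,
    synth_cfg=None,
) -> dict:
    """The package's standard synthetic benchmark, end to end.

    Generates the default synthetic dataset (200 proteins, 400 balanced
    sites, 400 pairs at ~70/30, noiseless planted signal), embeds with
    the mock backend (D=32), trains the site classifier and both effect
    submodels on stratified 80/20 splits, and reports held-out metrics
    for every model plus the soft-voted ensemble. Everything is seeded;
    the batch size and epoch counts are the package's standard settings
    for this problem size.
    """
    from .synthetic import SynthConfig, simulate

    cfg = synth_cfg or SynthConfig(seed=seed)
    data = simulate(cfg)
    backend_seed = seed % (2**31)
    from .embedding import MockBackend

    backend = MockBackend(dim=dim, seed=backend_seed)
    index = {p.id: p for p in data.proteins}
    site_prots = [index[i] for i in data.site_pool]
    pair_prots = [index[i] for i in data.pair_pool]

    site_emb = embed_all(site_prots, backend)
    site_res = run_site_experiment(
        data.sites,
        site_emb,
        seed=seed,
        train_cfg=TrainConfig(
            epochs=site_epochs, seed=seed, task="site", batch_size=batch_size
        ),
    )

    pair_emb = embed_all(pair_prots, backend)
    effect_res = run_effect_experiment(
        data.pairs,
        pair_prots,
        pair_emb,
        seed=seed,
        train_cfg=TrainConfig(
            epochs=effect_epochs,
            learning_rate=effect_lr,
            seed=seed,
            task="effect",
            loss="batch_weighted",
            batch_size=batch_size,
        ),
    )
    return {
        "site": site_res.metrics,
        "attcnn": effect_res["attcnn"].metrics,
        "transformer": effect_res["transformer"].metrics,
        "ensemble": effect_res["ensemble"],
        "n": {"sites": len(data.sites), "pairs": len(data.pairs)},
    }
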