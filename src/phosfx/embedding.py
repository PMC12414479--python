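"""Per-residue embedding backends.

Two kinds of backend produce L x D matrices whose rows align 1:1 with
residues:

* a deterministic, download-free mock backend whose row for residue i is
  a hashed function of the local trigram (residues i-1, i, i+1) — context
  sensitive like a protein language model, identical trigrams give
  identical rows;
* adapters for real protein language models (ProtBERT, ESM-2), which are
  optional: they require torch plus the respective weights and raise
  :class:`BackendUnavailableError` when those are not installed.

Embeddings can be cached on disk keyed by (backend name, sequence hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np

from .types import EmbeddingMatrix, ProteinRecord

logger = logging.getLogger(__name__)

#: Row assigned to the '*' pad symbol by every backend: all zeros, so pads
#: are inert under sum pooling and maskable in attention.
def pad_vector(dim: int) -> np.ndarray:
    if dim <= 0:
        raise ValueError("embedding dimension must be positive")
    return np.zeros(dim, dtype=np.float64)


class BackendUnavailableError(RuntimeError):
    """Raised when a real PLM backend's dependencies/weights are missing."""


class EmbeddingBackend:
    """Interface: name, output dimension, max sequence length."""

    name: str
    dim: int
    max_length: int  # sequences longer than this are truncated (with warning)

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class MockBackend(EmbeddingBackend):
    """Deterministic trigram embedding (no downloads, any dimension).

    Row i depends only on (residue i-1, residue i, residue i+1, seed):
    each of the three slots contributes a hashed letter vector and the
    row is their normalised sum, so rows have unit variance, identical
    trigrams map to identical rows, and — like real protein language
    model embeddings — the identity of the residue at each slot is
    linearly decodable from the row. Sequence boundaries use '^'/'$'
    marker letters.
    """

    def __init__(self, dim: int = 32, seed: int = 0):
        if dim < 4:
            raise ValueError("mock embedding dimension must be >= 4")
        self.name = f"mock{dim}-s{seed}"
        self.dim = dim
        self.seed = int(seed)
        self.max_length = np.iinfo(np.int64).max  # effectively unlimited
        self._slot_cache: dict[tuple[int, str], np.ndarray] = {}

    def _slot_vector(self, slot: int, letter: str) -> np.ndarray:
        key = (slot, letter)
        vec = self._slot_cache.get(key)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}:{slot}:{letter}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.dim)
            self._slot_cache[key] = vec
        return vec

    def embed(self, sequence: str) -> np.ndarray:
        padded = "^" + sequence + "$"
        inv_sqrt3 = 1.0 / np.sqrt(3.0)
        rows = np.empty((len(sequence), self.dim), dtype=np.float64)
        for i in range(len(sequence)):
            rows[i] = (
                self._slot_vector(0, padded[i])
                + self._slot_vector(1, padded[i + 1])
                + self._slot_vector(2, padded[i + 2])
            ) * inv_sqrt3
        return rows


class _TorchPLMBackend(EmbeddingBackend):
    """Shared plumbing for real PLM adapters (requires torch + weights)."""

    max_length = 1022  # model context minus the two special tokens

    def _load(self):  # pragma: no cover - requires heavyweight downloads
        raise NotImplementedError

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover
        model = self._load()
        return model(sequence)


class ProtBertBackend(_TorchPLMBackend):
    """ProtBERT adapter: 1024-dim rows, special tokens stripped."""

    name = "protbert"
    dim = 1024

    def _load(self):  # pragma: no cover - requires downloaded weights
        try:
            import torch  # noqa: F401
            from transformers import BertModel, BertTokenizer
        except ImportError as exc:
            raise BackendUnavailableError(
                "backend unavailable: ProtBERT requires torch and transformers "
                "(install the 'plm' extra and download Rostlab/prot_bert)"
            ) from exc

        tokenizer = BertTokenizer.from_pretrained("Rostlab/prot_bert", do_lower_case=False)
        model = BertModel.from_pretrained("Rostlab/prot_bert").eval()

        def run(sequence: str) -> np.ndarray:
            import torch

            spaced = " ".join(sequence)
            inputs = tokenizer(spaced, return_tensors="pt")
            with torch.no_grad():
                out = model(**inputs).last_hidden_state[0]
            return out[1 : 1 + len(sequence)].numpy().astype(np.float64)

        return run


class ESM2Backend(_TorchPLMBackend):
    """ESM-2 adapter: 1280-dim rows (esm2_t33_650M), special tokens stripped."""

    name = "esm2"
    dim = 1280

    def _load(self):  # pragma: no cover - requires downloaded weights
        try:
            import esm
            import torch  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                "backend unavailable: ESM-2 requires torch and fair-esm "
                "(install the 'plm' extra)"
            ) from exc

        model, alphabet = esm.pretrained.esm2_t33_650M_UR50D()
        model = model.eval()
        converter = alphabet.get_batch_converter()

        def run(sequence: str) -> np.ndarray:
            import torch

            _, _, tokens = converter([("query", sequence)])
            with torch.no_grad():
                out = model(tokens, repr_layers=[33])["representations"][33][0]
            return out[1 : 1 + len(sequence)].numpy().astype(np.float64)

        return run


_BACKENDS = {"mock": MockBackend, "protbert": ProtBertBackend, "esm2": ESM2Backend}


def get_backend(name: str, *, dim: int = 32, seed: int = 0) -> EmbeddingBackend:
    """Backend factory used by the command-line layer."""
    if name == "mock":
        return MockBackend(dim=dim, seed=seed)
    if name in _BACKENDS:
        return _BACKENDS[name]()
    raise ValueError(f"unknown backend {name!r}; choose from {sorted(_BACKENDS)}")


def _sequence_hash(sequence: str) -> str:
    return hashlib.sha256(sequence.encode()).hexdigest()[:32]


class EmbeddingCache:
    """On-disk store of embeddings: one .npy per (backend, sequence hash),
    plus a JSON index mapping keys to file names."""

    def __init__(self, directory: str | Path):
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.index_path = self.dir / "index.json"
        self._index: dict[str, str] = {}
        if self.index_path.exists():
            self._index = json.loads(self.index_path.read_text())

    def _key(self, backend_name: str, sequence: str) -> str:
        return f"{backend_name}:{_sequence_hash(sequence)}"

    def get(self, backend_name: str, sequence: str) -> np.ndarray | None:
        key = self._key(backend_name, sequence)
        fname = self._index.get(key)
        if fname is None:
            return None
        return np.load(self.dir / fname)

    def put(self, backend_name: str, sequence: str, values: np.ndarray) -> None:
        key = self._key(backend_name, sequence)
        fname = key.replace(":", "_") + ".npy"
        np.save(self.dir / fname, values)
        self._index[key] = fname
        self.index_path.write_text(json.dumps(self._index, indent=0, sort_keys=True))


def embed_sequence(
    backend: EmbeddingBackend,
    protein: ProteinRecord,
    cache: EmbeddingCache | None = None,
) -> EmbeddingMatrix:
    """Embed one protein: L x D matrix with rows aligned 1:1 to residues.

    Sequences longer than the backend's ``max_length`` are truncated to
    the N-terminal prefix with a logged warning (downstream site lookups
    beyond the truncation point fail loudly there).
    """
    sequence = protein.sequence
    if len(sequence) == 0:
        raise ValueError("cannot embed an empty sequence")
    if len(sequence) > backend.max_length:
        warnings.warn(
            f"sequence {protein.id!r} (L={len(sequence)}) exceeds backend "
            f"{backend.name!r} max_length={backend.max_length}; truncating "
            "to the N-terminal prefix",
            stacklevel=2,
        )
        logger.warning("truncating %s to %d residues", protein.id, backend.max_length)
        sequence = sequence[: backend.max_length]
    if cache is not None:
        hit = cache.get(backend.name, sequence)
        if hit is not None:
            return EmbeddingMatrix(protein_id=protein.id, values=hit)
    values = np.asarray(backend.embed(sequence), dtype=np.float64)
    if values.shape != (len(sequence), backend.dim):
        raise RuntimeError(
            f"backend {backend.name!r} returned shape {values.shape}, "
            f"expected {(len(sequence), backend.dim)}"
        )
    if cache is not None:
        cache.put(backend.name, sequence, values)
    return EmbeddingMatrix(protein_id=protein.id, values=values)
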