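"""Text-to-vector backends and the cosine comparison primitive.

The backend contract is deliberately tiny — text in, fixed-length vector
out, deterministically — so that heavyweight sentence-transformer or remote
API models plug in behind the same interface as the self-contained hash
n-gram backend used throughout the test suite.  Cosine similarity of the
vectors is the pair score used everywhere downstream (the
sentence-embedding score, SES).
"""

from __future__ import annotations

import abc
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CapabilityError
from .items import ItemSet, normalize_text


class EmbeddingBackend(abc.ABC):
    """Deterministic text → vector map of fixed dimension.

    Contract: same ``(name, config, text)`` always yields the same vector,
    and ``dimension`` is constant across calls.
    """

    name: str
    dimension: int

    @property
    def config(self) -> dict:
        return {}

    @abc.abstractmethod
    def embed(self, text: str) -> np.ndarray:
        """Return a 1-D float vector of length ``dimension``."""

    def embed_many(self, texts: list[str]) -> np.ndarray:
        return np.vstack([self.embed(t) for t in texts])

    def config_digest(self) -> str:
        payload = json.dumps(
            {"name": self.name, "dimension": self.dimension, **self.config},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def _stable_hash(token: str) -> int:
    digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big")


def hash_ngram_embed(text: str, dim: int = 256, n: int = 3) -> np.ndarray:
    """Embed one text by signed hashing of its character n-grams.

    The lower-cased, whitespace-normalized text is scanned with a sliding
    window of length ``n``; each n-gram is hashed into one of ``dim``
    buckets with a ±1 sign taken from an independent hash bit, and the
    resulting count vector is L2-normalized.  Fully deterministic — no
    randomness, no model download.

    Texts shorter than ``n`` after trimming yield the zero vector (with a
    warning), which downstream cosine handles as similarity 0.
    """
    if dim < 8:
        raise ValueError(f"dim must be >= 8, got {dim}")
    if n < 2:
        raise ValueError(f"n-gram length must be >= 2, got {n}")
    vec = np.zeros(dim, dtype=np.float64)
    clean = normalize_text(text).lower()
    if len(clean) < n:
        warnings.warn(f"text {text!r} too short for {n}-grams; zero vector", stacklevel=2)
        return vec
    for i in range(len(clean) - n + 1):
        h = _stable_hash(clean[i : i + n])
        sign = 1.0 if (h >> 63) & 1 == 0 else -1.0
        vec[h % dim] += sign
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


class HashNgramBackend(EmbeddingBackend):
    """Offline deterministic backend: signed character n-gram hashing.

    Default ``dim=256, n=3`` is small but collision-light for desk-scale
    corpora; near-paraphrases share most of their character trigrams and
    score high, unrelated texts hash into mostly disjoint buckets.
    """

    def __init__(self, dim: int = 256, n: int = 3):
        if dim < 8:
            raise ValueError(f"dim must be >= 8, got {dim}")
        if n < 2:
            raise ValueError(f"n-gram length must be >= 2, got {n}")
        self.name = "hash-ngram"
        self.dimension = dim
        self.n = n

    @property
    def config(self) -> dict:
        return {"n": self.n}

    def embed(self, text: str) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return hash_ngram_embed(text, dim=self.dimension, n=self.n)


class SentenceTransformerBackend(EmbeddingBackend):
    """Adapter for sentence-transformers models (optional dependency).

    Wraps a model such as
    ``sentence-transformers/paraphrase-multilingual-MiniLM-L12-v2`` behind
    the same contract as the hash backend.  Never required by the test
    suite: pair scores from third-party models are data, not part of the
    method's correctness.
    """

    def __init__(self, model_name: str = "sentence-transformers/paraphrase-multilingual-MiniLM-L12-v2"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional path
            raise CapabilityError(
                "sentence-transformers is not installed; use HashNgramBackend "
                "or install the 'models' extra"
            ) from exc
        self._model = SentenceTransformer(model_name)  # pragma: no cover
        self.name = "sentence-transformers"  # pragma: no cover
        self._model_name = model_name  # pragma: no cover
        self.dimension = int(self._model.get_sentence_embedding_dimension())  # pragma: no cover

    @property
    def config(self) -> dict:  # pragma: no cover - optional path
        return {"model": self._model_name}

    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - optional path
        return np.asarray(self._model.encode([text])[0], dtype=np.float64)


def make_backend(name: str, **params) -> EmbeddingBackend:
    """Instantiate a backend by name ('hash-ngram' or 'sentence-transformers')."""
    if name == "hash-ngram":
        return HashNgramBackend(
            dim=int(params.get("dim", 256)), n=int(params.get("n", 3))
        )
    if name == "sentence-transformers":
        return SentenceTransformerBackend(**params)
    raise CapabilityError(f"unknown embedding backend {name!r}")


@dataclass
class EmbeddingSet:
    """Per-item vectors aligned with an ItemSet, plus backend provenance."""

    item_ids: list[str]
    vectors: np.ndarray
    backend_name: str
    backend_config: dict = field(default_factory=dict)
    normalized: bool = False
    zero_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.item_ids):
            raise ValueError(
                f"vectors shape {self.vectors.shape} does not match "
                f"{len(self.item_ids)} item ids"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding matrix contains non-finite entries")
        if self.normalized:
            norms = np.linalg.norm(self.vectors, axis=1)
            nonzero = norms > 0
            if not np.allclose(norms[nonzero], 1.0, atol=1e-9):
                raise ValueError("normalized=True but rows are not unit vectors")

    def __len__(self) -> int:
        return len(self.item_ids)

    @property
    def dimension(self) -> int:
        return int(self.vectors.shape[1])

    def row(self, item_id: str) -> np.ndarray:
        return self.vectors[self.item_ids.index(item_id)]


class EmbeddingCache:
    """On-disk vector cache keyed by (backend digest, text digest).

    One CSV per backend configuration under ``directory``; each row is
    ``key,v0,...,v{d-1}``.  Purely an optimization for slow backends.
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, backend: EmbeddingBackend) -> Path:
        return self.directory / f"{backend.name}-{backend.config_digest()}.csv"

    @staticmethod
    def _key(text: str) -> str:
        return hashlib.sha256(normalize_text(text).encode("utf-8")).hexdigest()[:32]

    def load(self, backend: EmbeddingBackend) -> dict[str, np.ndarray]:
        path = self._path(backend)
        if not path.exists():
            return {}
        out: dict[str, np.ndarray] = {}
        with path.open() as fh:
            for line in fh:
                key, _, rest = line.partition(",")
                out[key] = np.array([float(x) for x in rest.split(",")], dtype=np.float64)
        return out

    def store(self, backend: EmbeddingBackend, texts: list[str], vectors: np.ndarray) -> None:
        known = self.load(backend)
        with self._path(backend).open("a") as fh:
            for text, vec in zip(texts, vectors):
                key = self._key(text)
                if key not in known:
                    fh.write(key + "," + ",".join(f"{x:.17g}" for x in vec) + "\n")
                    known[key] = vec


def embed_items(
    items: ItemSet,
    backend: EmbeddingBackend,
    normalize: bool = True,
    cache: EmbeddingCache | None = None,
) -> EmbeddingSet:
    """Embed every item text, optionally unit-normalizing rows.

    Normalization is the default because it turns cosine into a plain dot
    product and makes inner-product k-NN equivalent to cosine k-NN.  Zero
    vectors (possible for degenerate texts under the hash backend) are left
    as zeros and recorded in ``zero_ids``.
    """
    texts = items.texts
    cached = cache.load(backend) if cache is not None else {}
    rows: list[np.ndarray] = []
    fresh_texts: list[str] = []
    for item, text in zip(items, texts):
        key = EmbeddingCache._key(text)
        if key in cached:
            vec = cached[key]
        else:
            try:
                vec = np.asarray(backend.embed(text), dtype=np.float64)
            except Exception as exc:
                raise RuntimeError(
                    f"backend {backend.name!r} failed on item {item.item_id!r}"
                ) from exc
            fresh_texts.append(text)
        if vec.ndim != 1 or vec.shape[0] != backend.dimension:
            raise RuntimeError(
                f"backend {backend.name!r} returned shape {vec.shape} for item "
                f"{item.item_id!r}, expected ({backend.dimension},)"
            )
        rows.append(vec)
    matrix = np.vstack(rows)
    norms = np.linalg.norm(matrix, axis=1)
    zero_ids = [iid for iid, nrm in zip(items.item_ids, norms) if nrm == 0.0]
    if zero_ids:
        warnings.warn(f"{len(zero_ids)} item(s) embedded to the zero vector", stacklevel=2)
    if normalize:
        nonzero = norms > 0
        matrix[nonzero] /= norms[nonzero, None]
    if cache is not None and fresh_texts:
        fresh_rows = np.vstack([matrix[texts.index(t)] for t in fresh_texts])
        cache.store(backend, fresh_texts, fresh_rows)
    return EmbeddingSet(
        item_ids=items.item_ids,
        vectors=matrix,
        backend_name=backend.name,
        backend_config=dict(backend.config),
        normalized=normalize,
        zero_ids=zero_ids,
    )


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity dot(u,v)/(‖u‖‖v‖), defined as 0 for a zero vector.

    Symmetric and invariant to positive rescaling of either argument.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        warnings.warn("cosine with a zero vector is defined as 0", stacklevel=2)
        return 0.0
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))
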