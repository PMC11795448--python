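"""Topic inspection of an embedded corpus: clustering, c-TF-IDF labels, 2-D maps.

Topic building here is a defined, deterministic pipeline — centroid
clustering of the embedding vectors followed by class-based TF-IDF term
weighting over the clustered texts — so that every number it produces is
reproducible from a seed.  The per-cluster weight of a term t is

    weight(t, c) = (count of t in c / total tokens in c) * log(1 + A / f_t)

with f_t the total corpus count of t and A the average token count per
cluster: terms concentrated in one cluster rise, ubiquitous terms sink.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.feature_extraction.text import CountVectorizer

from .embedding import EmbeddingSet
from .errors import CapabilityError


@dataclass
class ClusterAssignment:
    """Integer cluster label per item, reproducible from (params, seed)."""

    item_ids: list[str]
    labels: np.ndarray
    k: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.item_ids):
            raise ValueError("one label per item required")
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError(f"labels must lie in 0..{self.k - 1}")

    def members(self, label: int) -> list[str]:
        return [iid for iid, lab in zip(self.item_ids, self.labels) if lab == label]


def cluster_embeddings(embeddings: EmbeddingSet, k: int, seed: int = 0) -> ClusterAssignment:
    """Centroid (k-means) clustering of the embedding vectors, seed-fixed."""
    n = len(embeddings)
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n_items={n}, got {k}")
    km = KMeans(n_clusters=k, random_state=int(seed), n_init=10)
    labels = km.fit_predict(embeddings.vectors)
    return ClusterAssignment(
        item_ids=list(embeddings.item_ids),
        labels=labels,
        k=k,
        params={"algorithm": "kmeans", "n_init": 10, "seed": int(seed)},
    )


@dataclass
class TopicTerms:
    """Ranked (term, c-TF-IDF weight) lists per cluster."""

    terms: dict[int, list[tuple[str, float]]]

    def top(self, cluster: int) -> list[tuple[str, float]]:
        return self.terms[cluster]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster": c, "rank": r + 1, "term": t, "weight": w}
            for c, ranked in sorted(self.terms.items())
            for r, (t, w) in enumerate(ranked)
        ]
        return pd.DataFrame(rows, columns=["cluster", "rank", "term", "weight"])


def _tokenizer() -> CountVectorizer:
    # lower-case, split on non-alphanumerics, drop length-1 tokens — the
    # default scikit-learn token pattern does exactly this
    return CountVectorizer(lowercase=True, token_pattern=r"(?u)\b\w\w+\b")


def ctfidf_terms(
    texts: list[str],
    assignment: ClusterAssignment,
    top_n: int = 10,
    stop_words: list[str] | None = None,
) -> TopicTerms:
    """Class-based TF-IDF term ranking per cluster.

    ``texts`` must align positionally with ``assignment.item_ids``.  No
    stop-word list is applied by default: the inverse-frequency factor
    already down-weights ubiquitous terms.
    """
    if len(texts) != len(assignment.item_ids):
        raise ValueError("texts must align with the cluster assignment")
    vectorizer = _tokenizer()
    if stop_words:
        vectorizer.set_params(stop_words=list(stop_words))
    counts = vectorizer.fit_transform(texts)  # items × vocab
    vocab = np.asarray(vectorizer.get_feature_names_out())

    k = assignment.k
    # aggregate token counts per cluster
    cluster_counts = np.zeros((k, counts.shape[1]), dtype=np.float64)
    for c in range(k):
        mask = assignment.labels == c
        if mask.any():
            cluster_counts[c] = np.asarray(counts[mask].sum(axis=0)).ravel()

    tokens_per_cluster = cluster_counts.sum(axis=1)  # total tokens in c
    f_t = cluster_counts.sum(axis=0)  # corpus count of each term
    avg_tokens = tokens_per_cluster.sum() / k  # A

    terms: dict[int, list[tuple[str, float]]] = {}
    for c in range(k):
        if tokens_per_cluster[c] == 0:
            warnings.warn(f"cluster {c} is empty; no terms", stacklevel=2)
            terms[c] = []
            continue
        tf = cluster_counts[c] / tokens_per_cluster[c]
        idf = np.log1p(avg_tokens / f_t)  # f_t > 0 for every vocabulary term
        weight = tf * idf
        present = np.flatnonzero(cluster_counts[c] > 0)
        order = present[np.lexsort((vocab[present], -weight[present]))]
        terms[c] = [(str(vocab[i]), float(weight[i])) for i in order[:top_n]]
    return TopicTerms(terms=terms)


def project_2d(embeddings: EmbeddingSet, method: str = "pca", seed: int = 0) -> pd.DataFrame:
    """Project item vectors to 2-D for inspection.

    ``pca`` is the deterministic reference method; ``umap`` is optional,
    seed-controlled, and intended for visual exploration only (its
    coordinates carry no correctness guarantees).
    Returns a DataFrame (item_id, x, y).
    """
    if len(embeddings) < 3:
        raise ValueError("projection requires at least 3 items")
    if method == "pca":
        coords = PCA(n_components=2, svd_solver="full").fit_transform(embeddings.vectors)
    elif method == "umap":
        try:
            import umap
        except ImportError as exc:
            raise CapabilityError(
                "umap-learn is not installed; use method='pca'"
            ) from exc
        reducer = umap.UMAP(n_components=2, random_state=int(seed))
        coords = reducer.fit_transform(embeddings.vectors)
    else:
        raise CapabilityError(f"unknown projection method {method!r}; try 'pca'")
    return pd.DataFrame(
        {"item_id": embeddings.item_ids, "x": coords[:, 0], "y": coords[:, 1]}
    )
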