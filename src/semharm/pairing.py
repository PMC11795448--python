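"""Candidate pair enumeration, cosine scoring, k-NN retrieval, score summaries.

Pairs are held in a pandas DataFrame, one row per unordered pair, with the
two item ids stored canonically (``item_a < item_b`` lexicographically) so
that the same physical pair always has the same identity regardless of the
order items arrived in.  The ``score`` column is the cosine similarity of
the pair's embeddings — the sentence-embedding score (SES) used by every
downstream stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import EmbeddingSet
from .errors import EmptyInputError
from .items import ItemSet

PAIR_COLUMNS = [
    "pair_id",
    "item_a",
    "item_b",
    "instrument_a",
    "instrument_b",
    "cross_instrument",
]


def _canonicalize(
    id_x: np.ndarray, id_y: np.ndarray, inst_x: np.ndarray, inst_y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    swap = id_x > id_y
    item_a = np.where(swap, id_y, id_x)
    item_b = np.where(swap, id_x, id_y)
    inst_a = np.where(swap, inst_y, inst_x)
    inst_b = np.where(swap, inst_x, inst_y)
    return item_a, item_b, inst_a, inst_b


def enumerate_pairs(items: ItemSet, scope: str = "all") -> pd.DataFrame:
    """Enumerate all unordered item pairs (no self-pairs).

    ``scope='all'`` yields every one of the n(n-1)/2 pairs;
    ``scope='cross_instrument_only'`` keeps only pairs whose items belong
    to different instruments.  Within-instrument pairs carry
    ``cross_instrument=False`` so downstream coverage can ignore them
    without re-enumerating.
    """
    if scope not in ("all", "cross_instrument_only"):
        raise ValueError(f"unknown scope {scope!r}")
    n = len(items)
    if n < 2:
        raise EmptyInputError("pair enumeration requires at least 2 items")
    ids = np.asarray(items.item_ids, dtype=object)
    insts = np.asarray([it.instrument for it in items], dtype=object)
    ii, jj = np.triu_indices(n, k=1)
    item_a, item_b, inst_a, inst_b = _canonicalize(ids[ii], ids[jj], insts[ii], insts[jj])
    cross = inst_a != inst_b
    frame = pd.DataFrame(
        {
            "pair_id": [f"{a}|{b}" for a, b in zip(item_a, item_b)],
            "item_a": item_a,
            "item_b": item_b,
            "instrument_a": inst_a,
            "instrument_b": inst_b,
            "cross_instrument": cross.astype(bool),
        },
        columns=PAIR_COLUMNS,
    )
    if scope == "cross_instrument_only":
        frame = frame[frame["cross_instrument"]].reset_index(drop=True)
    return frame


def score_pairs(pairs: pd.DataFrame, embeddings: EmbeddingSet) -> pd.DataFrame:
    """Attach the cosine similarity of each pair's vectors as ``score``.

    Pair order is preserved.  Zero-vector items yield score 0 (consistent
    with the cosine convention for zero vectors).
    """
    index = {iid: k for k, iid in enumerate(embeddings.item_ids)}
    missing = [
        iid
        for iid in pd.unique(pd.concat([pairs["item_a"], pairs["item_b"]]))
        if iid not in index
    ]
    if missing:
        raise KeyError(f"no embedding for item_id(s): {missing[:5]}")
    mat = embeddings.vectors
    norms = np.linalg.norm(mat, axis=1)
    unit = np.where(norms[:, None] > 0, mat / np.where(norms[:, None] == 0, 1, norms[:, None]), 0.0)
    ia = pairs["item_a"].map(index).to_numpy()
    ib = pairs["item_b"].map(index).to_numpy()
    scores = np.einsum("ij,ij->i", unit[ia], unit[ib])
    out = pairs.copy()
    out["score"] = np.clip(scores, -1.0, 1.0)
    return out


def build_scored_pairs(
    items: ItemSet, embeddings: EmbeddingSet, scope: str = "all"
) -> pd.DataFrame:
    """Convenience: enumerate + score in one call."""
    return score_pairs(enumerate_pairs(items, scope=scope), embeddings)


def top_k_neighbors(
    embeddings: EmbeddingSet,
    k: int,
    mode: str = "exact",
    n_cells: int | None = None,
    n_probe: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-item k nearest neighbors by cosine, self excluded.

    Exact mode scans the full similarity matrix and is the reference path;
    ties are broken by higher score first, then smaller item_id.
    Approximate mode uses an IVF-style coarse quantizer (k-means cells,
    searching the ``n_probe`` nearest cells) and may miss neighbors; use
    :func:`approximate_recall` to measure its recall against exact mode.

    Returns a DataFrame (item_id, rank, neighbor_id, score) with rank 1..k.
    """
    n = len(embeddings)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_items={n}, got {k}")
    if mode not in ("exact", "approximate"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = np.asarray(embeddings.item_ids, dtype=object)
    order_rank = np.empty(n, dtype=np.int64)
    order_rank[np.argsort(ids, kind="stable")] = np.arange(n)

    mat = embeddings.vectors
    norms = np.linalg.norm(mat, axis=1)
    unit = np.divide(mat, np.where(norms[:, None] == 0, 1.0, norms[:, None]))

    if mode == "exact":
        candidates = [np.delete(np.arange(n), i) for i in range(n)]
    else:
        from sklearn.cluster import KMeans

        n_cells = n_cells or max(1, int(np.sqrt(n)))
        km = KMeans(n_clusters=n_cells, random_state=seed, n_init=4).fit(unit)
        cell_of = km.labels_
        cell_members = [np.flatnonzero(cell_of == c) for c in range(n_cells)]
        cell_sims = unit @ km.cluster_centers_.T
        candidates = []
        for i in range(n):
            probe = np.argsort(-cell_sims[i], kind="stable")[: min(n_probe, n_cells)]
            cand = np.concatenate([cell_members[c] for c in probe])
            candidates.append(cand[cand != i])

    records: list[tuple[str, int, str, float]] = []
    for i in range(n):
        cand = candidates[i]
        sims = np.clip(unit[cand] @ unit[i], -1.0, 1.0)
        # tie-break: score desc, then lexicographically smaller item_id
        order = np.lexsort((order_rank[cand], -sims))[: min(k, len(cand))]
        for rank, j in enumerate(order, start=1):
            records.append((ids[i], rank, ids[cand[j]], float(sims[j])))
    return pd.DataFrame(records, columns=["item_id", "rank", "neighbor_id", "score"])


def approximate_recall(approx: pd.DataFrame, exact: pd.DataFrame) -> float:
    """Fraction of exact k-NN edges recovered by the approximate search."""
    key = ["item_id", "neighbor_id"]
    exact_edges = set(map(tuple, exact[key].itertuples(index=False)))
    approx_edges = set(map(tuple, approx[key].itertuples(index=False)))
    if not exact_edges:
        raise EmptyInputError("exact neighbor table is empty")
    return len(exact_edges & approx_edges) / len(exact_edges)


@dataclass
class ScoreSummary:
    """Descriptive summary of a pair-score distribution."""

    n_pairs: int
    mean: float
    sd: float
    bin_edges: np.ndarray
    histogram: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "mean": self.mean,
            "sd": self.sd,
            "bin_edges": [float(x) for x in self.bin_edges],
            "histogram": [int(x) for x in self.histogram],
        }


def summarize_scores(pairs: pd.DataFrame, n_bins: int = 40) -> ScoreSummary:
    """Mean, population SD, and an equal-width histogram over [-1, 1].

    The SD convention is population SD (ddof=0): the summary describes the
    complete pair population, not a sample from it.  The right edge of the
    last bin is inclusive.
    """
    if len(pairs) == 0:
        raise EmptyInputError("cannot summarize an empty pair list")
    scores = pairs["score"].to_numpy(dtype=np.float64)
    hist, edges = np.histogram(scores, bins=n_bins, range=(-1.0, 1.0))
    return ScoreSummary(
        n_pairs=len(scores),
        mean=float(scores.mean()),
        sd=float(scores.std(ddof=0)),
        bin_edges=edges,
        histogram=hist,
    )


def export_pairs_csv(pairs: pd.DataFrame, path) -> None:
    """Write scored pairs sorted by descending score (canonical export)."""
    cols = [c for c in PAIR_COLUMNS + ["score", "class"] if c in pairs.columns]
    ordered = pairs.sort_values(
        ["score", "pair_id"], ascending=[False, True], kind="mergesort"
    )
    ordered.to_csv(path, index=False, columns=cols, encoding="utf-8")
    if len(ordered) == 0:
        warnings.warn(f"exported an empty pair table to {path}", stacklevel=2)
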