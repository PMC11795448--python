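"""Pair filtering, confidence-band classification, coverage, network export.

The harmonization stage turns raw pair scores into decisions: which pairs
are worth a researcher's attention (threshold filtering), which can be
auto-classified as positive or negative without human review (confidence
bands derived from an expert pre-test), and how much of each instrument is
semantically covered by the rest of the corpus.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .items import ItemSet

#: Default candidate threshold: the lower bound of the expert pre-test
#: confidence interval for positive candidates.
DEFAULT_TAU = 0.751


@dataclass(frozen=True)
class ClassificationBands:
    """Closed score intervals inside which pairs are auto-classified.

    ``positive`` and ``negative`` are ``(lo, hi)`` intervals within
    [-1, 1]; a score inside exactly one interval takes that class, anything
    else (outside both, or inside an overlap) stays *uncertain* and goes to
    human review.
    """

    positive: tuple[float, float]
    negative: tuple[float, float]
    source: str = ""

    def __post_init__(self) -> None:
        for label, (lo, hi) in (("positive", self.positive), ("negative", self.negative)):
            if not (-1.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{label} band ({lo}, {hi}) must satisfy -1 <= lo <= hi <= 1")


#: Expert pre-test bands for the multilingual MiniLM sentence-transformer
#: scores.  Note the printed negative band is nested inside the positive
#: one; the overlap region is routed to "uncertain" (human review).
SBERT_BANDS = ClassificationBands(
    positive=(0.676, 0.912), negative=(0.737, 0.800), source="expert pre-test (SBERT)"
)


@dataclass
class AutomationReport:
    """Positive / negative / uncertain partition of a pair pool.

    The positive+negative share is the *automation potential*: the fraction
    of candidate decisions an embedding model can take without a human.
    """

    n_total: int
    n_positive: int
    n_negative: int
    n_uncertain: int

    def __post_init__(self) -> None:
        if self.n_positive + self.n_negative + self.n_uncertain != self.n_total:
            raise ValueError("class counts do not sum to total")

    @property
    def pct_positive(self) -> float:
        return 100.0 * self.n_positive / self.n_total if self.n_total else 0.0

    @property
    def pct_negative(self) -> float:
        return 100.0 * self.n_negative / self.n_total if self.n_total else 0.0

    @property
    def pct_uncertain(self) -> float:
        return 100.0 * self.n_uncertain / self.n_total if self.n_total else 0.0

    @property
    def pct_automatable(self) -> float:
        return self.pct_positive + self.pct_negative

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_uncertain": self.n_uncertain,
            "pct_positive": self.pct_positive,
            "pct_negative": self.pct_negative,
            "pct_uncertain": self.pct_uncertain,
            "pct_automatable": self.pct_automatable,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def filter_by_threshold(pairs: pd.DataFrame, tau: float = DEFAULT_TAU) -> pd.DataFrame:
    """Keep exactly the pairs with score strictly greater than ``tau``.

    Strict inequality: a pair scoring exactly ``tau`` is dropped.  Original
    row order is preserved.
    """
    if not -1.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [-1, 1], got {tau}")
    return pairs[pairs["score"] > tau].reset_index(drop=True)


def classify_bands(
    pairs: pd.DataFrame, bands: ClassificationBands, rule: str = "exclusive_bands"
) -> tuple[pd.DataFrame, AutomationReport]:
    """Partition pairs into positive / negative / uncertain.

    Under ``exclusive_bands``, a score inside the positive interval only is
    positive, inside the negative interval only is negative, and inside
    both or neither is uncertain.  Returns the pair table with a ``class``
    column plus the aggregate :class:`AutomationReport`.
    """
    if rule != "exclusive_bands":
        raise ValueError(f"unknown classification rule {rule!r}")
    scores = pairs["score"].to_numpy(dtype=np.float64)
    in_pos = (scores >= bands.positive[0]) & (scores <= bands.positive[1])
    in_neg = (scores >= bands.negative[0]) & (scores <= bands.negative[1])
    labels = np.where(
        in_pos & ~in_neg, "positive", np.where(in_neg & ~in_pos, "negative", "uncertain")
    )
    out = pairs.copy()
    out["class"] = labels
    report = AutomationReport(
        n_total=len(out),
        n_positive=int(np.sum(labels == "positive")),
        n_negative=int(np.sum(labels == "negative")),
        n_uncertain=int(np.sum(labels == "uncertain")),
    )
    return out, report


@dataclass
class CoverageReport:
    """Per-instrument semantic coverage and the inter-instrument match matrix.

    An item is *covered* iff it participates in at least one
    cross-instrument pair scoring above the threshold; within-instrument
    similarity is not a harmonization opportunity between questionnaires
    and never counts.
    """

    tau: float
    table: pd.DataFrame  # columns: instrument, n_items, n_covered, coverage_percent
    matrix: pd.DataFrame  # symmetric instrument × instrument match counts
    warnings: list[str] = field(default_factory=list)

    def coverage_of(self, instrument: str) -> float:
        row = self.table.loc[self.table["instrument"] == instrument]
        if row.empty:
            raise KeyError(f"unknown instrument {instrument!r}")
        return float(row["coverage_percent"].iloc[0])


def coverage(pairs: pd.DataFrame, items: ItemSet, tau: float = DEFAULT_TAU) -> CoverageReport:
    """Per-instrument coverage from cross-instrument pairs above ``tau``."""
    above = pairs[(pairs["score"] > tau) & pairs["cross_instrument"]]
    covered_ids = set(above["item_a"]) | set(above["item_b"])

    instruments = items.instruments()
    rows = []
    for inst in instruments:
        inst_items = [it.item_id for it in items if it.instrument == inst]
        n_items = len(inst_items)
        n_covered = sum(1 for iid in inst_items if iid in covered_ids)
        rows.append(
            {
                "instrument": inst,
                "n_items": n_items,
                "n_covered": n_covered,
                "coverage_percent": 100.0 * n_covered / n_items,
            }
        )
    table = pd.DataFrame(rows, columns=["instrument", "n_items", "n_covered", "coverage_percent"])

    matrix = pd.DataFrame(0, index=instruments, columns=instruments, dtype=int)
    if len(above):
        counts = above.groupby(["instrument_a", "instrument_b"]).size()
        for (ia, ib), c in counts.items():
            matrix.loc[ia, ib] += int(c)
            matrix.loc[ib, ia] += int(c)
    return CoverageReport(tau=tau, table=table, matrix=matrix)


def export_network(
    pairs: pd.DataFrame,
    items: ItemSet,
    path: str | Path,
    format: str = "graphml",
) -> Path:
    """Export the similarity network: items as nodes, candidate pairs as edges.

    ``format`` is ``'graphml'`` or ``'json'`` (node-link).  Node attributes
    carry instrument and text; edge attribute ``score`` carries the pair's
    cosine similarity.
    """
    graph = build_network(pairs, items)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "json":
        payload = nx.node_link_data(graph, edges="links")
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown network format {format!r} (graphml or json)")
    return path


def build_network(pairs: pd.DataFrame, items: ItemSet) -> nx.Graph:
    """In-memory similarity graph (undirected, scores as edge weights)."""
    if len(pairs) == 0:
        warnings.warn("building a network with no candidate edges", stacklevel=2)
    graph = nx.Graph()
    for it in items:
        graph.add_node(it.item_id, instrument=it.instrument, text=it.text)
    for row in pairs.itertuples(index=False):
        graph.add_edge(row.item_a, row.item_b, score=float(row.score))
    return graph
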