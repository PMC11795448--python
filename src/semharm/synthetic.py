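"""Synthetic multi-instrument questionnaire corpora with known paraphrase links.

Real multi-cohort item corpora are licensed and not shareable, so every
pipeline stage is exercised on generated corpora instead: filler items are
drawn from a small set of health-survey-like sentence frames over a
synthetic vocabulary, and a configurable number of *paraphrase links* are
planted by copying a source item into another instrument and substituting a
fraction of its tokens with designated synonyms.  The planted links are the
ground truth against which retrieval quality (precision, recall, score
separation) is measured.

Everything is reproducible from a single seed.  An optional second
"language" maps all tokens of chosen instruments through a bijective token
dictionary — a deterministic stand-in for translation that exercises the
multilingual plumbing (language codes, link bookkeeping) without a
cross-lingual model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError
from .items import Item, ItemSet

# Sentence frames with {} slots for vocabulary words.  Shared frames give
# unrelated items a realistic baseline similarity; slot words carry the
# distinguishing content (and make c-TF-IDF topic labels interpretable).
_FRAMES = [
    "how often during the past year did you {} about {} or {}",
    "have you ever {} because of {} problems with your {}",
    "in the last month how many times did your {} make you feel {}",
    "do you agree that {} people usually {} when facing {}",
    "how much did {} interfere with your {} during the past week",
    "when you think about {} do you feel {} or rather {}",
    "how difficult was it to {} your {} in everyday situations",
    "did a doctor ever tell you that your {} was related to {}",
    "on how many days did you {} more than you planned because of {}",
    "to what extent does {} describe the way you handle {}",
    "how satisfied are you with your {} when dealing with {}",
    "were you unable to stop {} once you had started thinking about {}",
]

_CONSONANTS = list("bdfgklmnprstvz")
_VOWELS = list("aeiou")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of a generated corpus."""

    n_instruments: int = 31
    items_per_instrument: int = 15
    n_paraphrase_links: int = 30
    vocab_size: int = 300
    paraphrase_intensity: float = 0.3
    second_language: bool = False
    second_language_instruments: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments < 2:
            raise ConfigurationError("need at least 2 instruments")
        if self.items_per_instrument < 1:
            raise ConfigurationError("need at least 1 item per instrument")
        if not 0.0 <= self.paraphrase_intensity <= 1.0:
            raise ConfigurationError("paraphrase_intensity must lie in [0, 1]")
        if self.vocab_size < 10:
            raise ConfigurationError("vocab_size must be at least 10")
        max_links = self.n_instruments * self.items_per_instrument // 2
        if self.n_paraphrase_links > max_links:
            raise ConfigurationError(
                f"{self.n_paraphrase_links} links infeasible: at most {max_links} "
                "with one link per item"
            )


@dataclass
class GroundTruth:
    """The planted cross-instrument paraphrase links (unordered id pairs)."""

    links: set[tuple[str, str]] = field(default_factory=set)

    @staticmethod
    def canonical(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    def add(self, a: str, b: str) -> None:
        self.links.add(self.canonical(a, b))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.canonical(*pair) in self.links

    def __len__(self) -> int:
        return len(self.links)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.links)
        return pd.DataFrame(rows, columns=["item_a", "item_b"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, encoding="utf-8")


def _make_words(rng: np.random.Generator, count: int, n_syllables: int, taken: set[str]) -> list[str]:
    words: list[str] = []
    while len(words) < count:
        word = "".join(
            rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syllables)
        )
        if word not in taken:
            taken.add(word)
            words.append(word)
    return words


def generate_corpus(config: SynthConfig) -> tuple[ItemSet, GroundTruth]:
    """Generate an (ItemSet, GroundTruth) pair under ``config``.

    Filler items fill every instrument; each paraphrase link then copies a
    randomly chosen source item into a different instrument, substituting
    ``round(intensity × n_tokens)`` token positions through the synonym
    dictionary (intensity 0 plants verbatim copies; intensity 1 with the
    disjoint synonym set leaves no shared token).  Each item takes part in
    at most one link.
    """
    rng = np.random.default_rng(config.seed)
    taken: set[str] = set()
    # every frame token and every vocabulary word gets a designated synonym
    frame_tokens = sorted({tok for f in _FRAMES for tok in f.split() if tok != "{}"})
    taken.update(frame_tokens)
    vocab = _make_words(rng, config.vocab_size, 2, taken)
    all_base = frame_tokens + vocab
    synonyms_list = _make_words(rng, len(all_base), 3, taken)
    synonym = dict(zip(all_base, synonyms_list))
    second_lang_list = _make_words(rng, len(all_base) + len(synonyms_list), 2, taken)
    second_lang = dict(zip(all_base + synonyms_list, second_lang_list))

    instruments = [f"INST{i + 1:02d}" for i in range(config.n_instruments)]
    if config.second_language:
        l2_set = set(
            config.second_language_instruments
            if config.second_language_instruments is not None
            else instruments[config.n_instruments // 2 :]
        )
        unknown = l2_set - set(instruments)
        if unknown:
            raise ConfigurationError(f"unknown second-language instruments: {sorted(unknown)}")
    else:
        l2_set = set()

    # token lists per (instrument, slot); realized lazily into texts
    tokens_of: dict[str, list[list[str]]] = {}
    for inst in instruments:
        rows = []
        for _ in range(config.items_per_instrument):
            frame = _FRAMES[rng.integers(0, len(_FRAMES))]
            n_slots = frame.count("{}")
            slot_words = [vocab[rng.integers(0, len(vocab))] for _ in range(n_slots)]
            rows.append(frame.format(*slot_words).split())
        tokens_of[inst] = rows

    truth = GroundTruth()
    linked: set[tuple[str, int]] = set()  # (instrument, row) already in a link
    for _ in range(config.n_paraphrase_links):
        for _attempt in range(1000):
            src_i, dst_i = rng.choice(config.n_instruments, size=2, replace=False)
            src_inst, dst_inst = instruments[src_i], instruments[dst_i]
            src_row = int(rng.integers(0, config.items_per_instrument))
            dst_row = int(rng.integers(0, config.items_per_instrument))
            if (src_inst, src_row) in linked or (dst_inst, dst_row) in linked:
                continue
            tokens = list(tokens_of[src_inst][src_row])
            n_sub = int(round(config.paraphrase_intensity * len(tokens)))
            positions = rng.choice(len(tokens), size=n_sub, replace=False)
            for pos in positions:
                tokens[pos] = synonym[tokens[pos]]
            tokens_of[dst_inst][dst_row] = tokens
            linked.add((src_inst, src_row))
            linked.add((dst_inst, dst_row))
            truth.add(f"{src_inst}#Q{src_row + 1}", f"{dst_inst}#Q{dst_row + 1}")
            break
        else:  # pragma: no cover - config validation makes this unreachable
            raise ConfigurationError("could not place all paraphrase links")

    items: list[Item] = []
    for inst in instruments:
        lang = "x-l2" if inst in l2_set else "en"
        for row, tokens in enumerate(tokens_of[inst]):
            if inst in l2_set:
                tokens = [second_lang[t] for t in tokens]
            items.append(
                Item(
                    item_id=f"{inst}#Q{row + 1}",
                    instrument=inst,
                    variable=f"Q{row + 1}",
                    study="SYNTH",
                    text=" ".join(tokens),
                    language=lang,
                )
            )
    itemset = ItemSet(items, provenance={"generator": "synthetic", "config": repr(config)})
    return itemset, truth


def with_intensity(config: SynthConfig, intensity: float) -> SynthConfig:
    """Copy of ``config`` at a different paraphrase intensity (same seed)."""
    return replace(config, paraphrase_intensity=intensity)


@dataclass
class GroundTruthMetrics:
    """Retrieval quality of thresholded pairs against the planted links."""

    tau: float
    n_truth: int
    n_predicted: int
    n_hit: int
    precision: float
    recall: float
    separation: float

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "n_truth": self.n_truth,
            "n_predicted": self.n_predicted,
            "n_hit": self.n_hit,
            "precision": self.precision,
            "recall": self.recall,
            "separation": self.separation,
        }


def ground_truth_eval(
    pairs: pd.DataFrame, truth: GroundTruth, tau: float
) -> GroundTruthMetrics:
    """Precision/recall at ``tau`` plus the true-link score separation.

    ``separation`` is the mean score of true links minus the mean score of
    all other pairs — the margin by which the embedding separates
    harmonizable from unrelated pairs.
    """
    if len(truth) == 0:
        raise EmptyInputError("ground truth is empty")
    keys = set(zip(pairs["item_a"], pairs["item_b"]))
    missing = [lk for lk in truth.links if lk not in keys]
    if missing:
        raise ValueError(f"scored pairs do not cover truth link(s): {missing[:3]}")

    is_true = np.array(
        [(a, b) in truth.links for a, b in zip(pairs["item_a"], pairs["item_b"])]
    )
    scores = pairs["score"].to_numpy(dtype=np.float64)
    predicted = scores > tau
    n_hit = int(np.sum(predicted & is_true))
    n_pred = int(np.sum(predicted))
    return GroundTruthMetrics(
        tau=float(tau),
        n_truth=len(truth),
        n_predicted=n_pred,
        n_hit=n_hit,
        precision=n_hit / n_pred if n_pred else float("nan"),
        recall=n_hit / len(truth),
        separation=float(scores[is_true].mean() - scores[~is_true].mean()),
    )
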