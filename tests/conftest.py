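import numpy as np
import pytest

import semharm as sh


@pytest.fixture
def toy_items() -> sh.ItemSet:
    """Two instruments, three items each, with one near-duplicate across them."""
    return sh.ItemSet(
        [
            sh.Item("A#1", "A", "How often did you drink alcohol last year"),
            sh.Item("A#2", "A", "Do you feel nervous in social situations"),
            sh.Item("A#3", "A", "How many hours do you sleep at night"),
            sh.Item("B#1", "B", "How often did you drink alcohol last year"),
            sh.Item("B#2", "B", "Are you satisfied with your daily routine"),
            sh.Item("B#3", "B", "Did you smoke cigarettes during the past month"),
        ]
    )


@pytest.fixture
def toy_embeddings(toy_items) -> sh.EmbeddingSet:
    return sh.embed_items(toy_items, sh.HashNgramBackend(), normalize=True)


@pytest.fixture
def toy_pairs(toy_items, toy_embeddings):
    return sh.build_scored_pairs(toy_items, toy_embeddings)


@pytest.fixture(scope="session")
def small_corpus():
    """Generated 8x8 corpus with 6 links at moderate paraphrase intensity."""
    config = sh.SynthConfig(
        n_instruments=8,
        items_per_instrument=8,
        n_paraphrase_links=6,
        paraphrase_intensity=0.3,
        seed=11,
    )
    return sh.generate_corpus(config)


@pytest.fixture(scope="session")
def small_scored(small_corpus):
    items, truth = small_corpus
    emb = sh.embed_items(items, sh.HashNgramBackend(), normalize=True)
    return items, truth, emb, sh.build_scored_pairs(items, emb)


def random_unit_rows(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    mat = rng.standard_normal((n, d))
    return mat / np.linalg.norm(mat, axis=1, keepdims=True)
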