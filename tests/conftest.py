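import numpy as np
import pytest

from fluencynet.estimate import SemanticNetwork, SimilarityMatrix
from fluencynet.preprocess import (
    CleaningDictionary,
    FluencyDataset,
    FluencyRecord,
    ResponseMatrix,
)


def random_similarity(n: int, rng: np.random.Generator) -> SimilarityMatrix:
    """Random symmetric similarity matrix with entries in (0, 1)."""
    A = rng.uniform(0.01, 0.99, size=(n, n))
    W = np.triu(A, 1)
    W = W + W.T
    return SimilarityMatrix(tuple(f"w{i:03d}" for i in range(n)), W)


def random_binary_matrix(
    n_participants: int, n_words: int, rng: np.random.Generator, p: float = 0.4
) -> ResponseMatrix:
    """Random response matrix guaranteed to have >= 1 producer per word."""
    while True:
        vals = (rng.random((n_participants, n_words)) < p).astype(np.int8)
        if vals.sum(axis=0).min() >= 1:
            return ResponseMatrix(
                tuple(f"p{i}" for i in range(n_participants)),
                tuple(f"w{j:03d}" for j in range(n_words)),
                vals,
            )


@pytest.fixture
def toy_dictionary() -> CleaningDictionary:
    return CleaningDictionary(
        category_lexicon=frozenset({"dog", "cat", "emu", "yak", "bat"}),
        variant_map={"dogs": "dog", "cats": "cat", "katt": "cat"},
    )


@pytest.fixture
def toy_dataset() -> FluencyDataset:
    return FluencyDataset(
        (
            FluencyRecord("p1", "HC", ("dog", "cat")),
            FluencyRecord("p2", "HC", ("cat", "emu")),
            FluencyRecord("p3", "PWA", ("dog", "bat")),
        )
    )


@pytest.fixture
def triangle_network() -> SemanticNetwork:
    adj = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])
    return SemanticNetwork(("a", "b", "c"), adj)
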