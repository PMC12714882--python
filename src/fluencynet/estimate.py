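"""Semantic network estimation: cosine similarity + TMFG sparsification.

The binary response matrix is turned into a word-by-word cosine similarity
matrix (co-producer count over the geometric mean of producer counts) and
then sparsified with the triangulated maximally filtered graph (TMFG): a
greedy planar filter that keeps exactly ``3n - 6`` of the strongest
consistent edges, yielding connected, planar, equally-sized networks whose
edge weights are the retained similarities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigurationError, TooFewNodesError
from .preprocess import ResponseMatrix

__all__ = [
    "SimilarityMatrix",
    "SemanticNetwork",
    "cosine_similarity",
    "tmfg_filter",
    "estimate_network",
]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric word-by-word cosine similarity with a zero diagonal."""

    words: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.words)
        if vals.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(vals, vals.T):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("cosine similarities must lie in [0, 1]")
        vals = np.clip(vals, 0.0, 1.0)
        np.fill_diagonal(vals, 0.0)
        object.__setattr__(self, "values", vals)

    @property
    def n_words(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class SemanticNetwork:
    """Weighted undirected network over a word lexicon.

    ``adjacency`` is symmetric with a zero diagonal; ``mask`` marks which
    pairs are edges (a retained similarity may be exactly 0, which is still a
    structural edge of the TMFG backbone).  When ``mask`` is omitted it is
    taken to be the nonzero entries of ``adjacency``.  After TMFG filtering
    the network is planar, connected, and has exactly ``3n - 6`` edges for
    ``n >= 3``.
    """

    words: tuple[str, ...]
    adjacency: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        n = len(self.words)
        if adj.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if not np.allclose(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(adj < 0):
            raise ValueError("edge weights must be non-negative")
        if self.mask is None:
            mask = adj != 0
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != adj.shape:
                raise ValueError("mask shape mismatch")
            if not (mask == mask.T).all() or np.any(np.diag(mask)):
                raise ValueError("mask must be symmetric with empty diagonal")
            if np.any(adj[~mask] != 0):
                raise ValueError("non-edges must have zero weight")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "mask", mask)

    @property
    def n_nodes(self) -> int:
        return len(self.words)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.mask, 1)))

    def edges(self) -> Iterator[tuple[int, int, float]]:
        rows, cols = np.nonzero(np.triu(self.mask, 1))
        for i, j in zip(rows, cols):
            yield int(i), int(j), float(self.adjacency[i, j])

    def backbone(self) -> np.ndarray:
        """Unweighted 0/1 adjacency of the structural edges."""
        return self.mask.astype(np.int8)

    def strengths(self) -> np.ndarray:
        """Weighted degree (sum of incident edge weights) per node."""
        return self.adjacency.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.words)
        for i, j, w in self.edges():
            g.add_edge(self.words[i], self.words[j], weight=w)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, words: Sequence[str] | None = None) -> "SemanticNetwork":
        words = tuple(words) if words is not None else tuple(sorted(g.nodes))
        index = {w: i for i, w in enumerate(words)}
        adj = np.zeros((len(words), len(words)))
        mask = np.zeros((len(words), len(words)), dtype=bool)
        for u, v, data in g.edges(data=True):
            w = float(data.get("weight", 1.0))
            adj[index[u], index[v]] = adj[index[v], index[u]] = w
            mask[index[u], index[v]] = mask[index[v], index[u]] = True
        return cls(words, adj, mask)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def read_graphml(cls, path: str | Path) -> "SemanticNetwork":
        return cls.from_networkx(nx.read_graphml(path))

    def write_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("word_a,word_b,weight\n")
            for i, j, w in self.edges():
                fh.write(f"{self.words[i]},{self.words[j]},{w!r}\n")

    @classmethod
    def read_edgelist(cls, path: str | Path) -> "SemanticNetwork":
        import pandas as pd

        frame = pd.read_csv(path, float_precision="round_trip")
        g = nx.Graph()
        for _, row in frame.iterrows():
            g.add_edge(str(row["word_a"]), str(row["word_b"]), weight=float(row["weight"]))
        return cls.from_networkx(g)


def cosine_similarity(matrix: ResponseMatrix) -> SimilarityMatrix:
    """Cosine similarity between word occurrence columns.

    For binary columns this is the co-producer count over the geometric mean
    of the producer counts: ``sim(i, j) = n_ij / sqrt(n_i * n_j)``.  Values
    lie in [0, 1]; 0 means the words never co-occur across participants; the
    diagonal is set to 0.
    """
    X = matrix.values.astype(float)
    counts = X.sum(axis=0)
    if np.any(counts == 0):
        dead = [w for w, c in zip(matrix.words, counts) if c == 0]
        raise ConfigurationError(f"words with zero producers: {dead[:5]}")
    co = X.T @ X
    sim = co / np.sqrt(np.outer(counts, counts))
    np.fill_diagonal(sim, 0.0)
    return SimilarityMatrix(matrix.words, sim)


def _best_seed_clique_numpy(W: np.ndarray) -> tuple[int, int, int, int]:
    """Exhaustive max-total-weight 4-clique; ties -> lexicographically
    smallest node tuple.  O(n^2) vectorized scans over the O(n^2) pairs."""
    n = W.shape[0]
    best_score = -np.inf
    best: tuple[int, int, int, int] | None = None
    for i in range(n - 3):
        for j in range(i + 1, n - 2):
            v = W[i] + W[j]
            # candidates k < l with k, l > j keep the tuple sorted and unique
            vv = v[j + 1 :]
            sub = W[j + 1 :, j + 1 :] + vv[:, None] + vv[None, :] + W[i, j]
            ku, lu = np.triu_indices(sub.shape[0], 1)
            if ku.size == 0:
                continue
            flat = sub[ku, lu]
            arg = int(np.argmax(flat))
            s = float(flat[arg])
            cand = (i, j, j + 1 + int(ku[arg]), j + 1 + int(lu[arg]))
            if s > best_score or (s == best_score and (best is None or cand < best)):
                best_score = s
                best = cand
    assert best is not None
    return best


try:  # numba gives a ~30x faster exact seed search; results are identical
    from numba import njit

    @njit(cache=True)
    def _best_seed_clique_jit(W: np.ndarray) -> tuple[int, int, int, int]:  # pragma: no cover
        n = W.shape[0]
        best = -np.inf
        bi = bj = bk = bl = 0
        for i in range(n - 3):
            for j in range(i + 1, n - 2):
                wij = W[i, j]
                for k in range(j + 1, n - 1):
                    base = wij + W[i, k] + W[j, k]
                    for l in range(k + 1, n):
                        s = base + W[i, l] + W[j, l] + W[k, l]
                        if s > best:  # strict: keeps the first (lowest) tuple on ties
                            best = s
                            bi, bj, bk, bl = i, j, k, l
        return bi, bj, bk, bl

    def _best_seed_clique(W: np.ndarray) -> tuple[int, int, int, int]:
        i, j, k, l = _best_seed_clique_jit(np.ascontiguousarray(W))
        return int(i), int(j), int(k), int(l)

except ImportError:  # pragma: no cover
    _best_seed_clique = _best_seed_clique_numpy


def tmfg_filter(sim: SimilarityMatrix) -> SemanticNetwork:
    """Triangulated maximally filtered graph of a similarity matrix.

    Greedy construction: seed with the 4-node clique of maximum total edge
    weight, then repeatedly insert the unused node with the largest summed
    similarity to some triangular face, wiring it to that face's three
    vertices.  Each insertion splits one face into three, so the result is a
    planar triangulation with ``3n - 6`` edges.  Ties are broken toward the
    lowest node index, then the earliest-created face.  No edge-swap
    refinement is applied.
    """
    W = sim.values
    n = sim.n_words
    if n < 3:
        raise TooFewNodesError(f"TMFG needs >= 3 nodes, got {n}")
    adj = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)

    def add_edge(i: int, j: int) -> None:
        adj[i, j] = adj[j, i] = W[i, j]
        mask[i, j] = mask[j, i] = True

    if n == 3:
        for i, j in itertools.combinations(range(3), 2):
            add_edge(i, j)
        return SemanticNetwork(sim.words, adj, mask)

    seed = _best_seed_clique(W)
    for i, j in itertools.combinations(seed, 2):
        add_edge(i, j)
    a, b, c, d = seed
    faces: list[tuple[int, int, int]] = [(a, b, c), (a, b, d), (a, c, d), (b, c, d)]
    remaining = sorted(set(range(n)) - set(seed))

    while remaining:
        face_arr = np.array(faces)  # (f, 3)
        gains = W[np.ix_(remaining, face_arr.ravel())].reshape(len(remaining), len(faces), 3).sum(axis=2)
        flat = int(np.argmax(gains))  # row-major: lowest node index, then earliest face
        vi, fi = divmod(flat, len(faces))
        v = remaining.pop(vi)
        fa, fb, fc = faces.pop(fi)
        for u in (fa, fb, fc):
            add_edge(v, u)
        faces.extend([(v, fa, fb), (v, fa, fc), (v, fb, fc)])

    net = SemanticNetwork(sim.words, adj, mask)
    assert net.n_edges == 3 * n - 6
    return net


def estimate_network(matrix: ResponseMatrix) -> SemanticNetwork:
    """Convenience: cosine similarity followed by TMFG filtering."""
    return tmfg_filter(cosine_similarity(matrix))
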