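"""Weighted k-clique percolation and the percolation-integral resilience test.

k-cliques of the weighted network are assigned an intensity (geometric mean
of their edge weights); sweeping an intensity threshold from 0.01 to 1.00
progressively removes weak cliques, and the number of nodes still belonging
to any surviving clique community traces a non-increasing percolation
curve.  Its area (left Riemann sum) is the percolation integral: lower
values mean the network fragments at weaker thresholds and is less
resilient.  Group comparisons repeat the analysis over participant-level
bootstrap resamples (or node subsamples) of each group's response matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .estimate import SemanticNetwork, cosine_similarity, tmfg_filter
from .metrics import MetricDistribution, StatResult, compare_distributions
from .preprocess import ResponseMatrix

__all__ = [
    "PercolationParams",
    "Clique",
    "PercolationCurve",
    "PercolationResult",
    "enumerate_cliques",
    "clique_communities",
    "percolation_curve",
    "percolation_integral",
    "percolation_comparison",
]

PARTICIPANT_BOOTSTRAP = "participant-bootstrap"
NODE_SUBSAMPLE = "node-subsample"


@dataclass(frozen=True)
class PercolationParams:
    k: int = 3
    grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(1, 101) * 0.01, 2))
    iterations: int = 500
    mode: str = NODE_SUBSAMPLE
    subsample_proportion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ConfigurationError("clique size k must be >= 3")
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or len(grid) == 0:
            raise ConfigurationError("grid must be a non-empty 1-d array")
        if np.any(np.diff(grid) <= 0) or grid[0] <= 0 or grid[-1] > 1:
            raise ConfigurationError("grid must be strictly increasing within (0, 1]")
        if self.mode not in (PARTICIPANT_BOOTSTRAP, NODE_SUBSAMPLE):
            raise ConfigurationError(f"unknown iteration mode {self.mode!r}")
        object.__setattr__(self, "grid", grid)

    @property
    def step(self) -> float:
        if len(self.grid) == 1:
            return float(self.grid[0])
        return float(np.mean(np.diff(self.grid)))


@dataclass(frozen=True)
class Clique:
    nodes: tuple[int, ...]
    intensity: float


@dataclass(frozen=True)
class PercolationCurve:
    grid: np.ndarray
    connected_nodes: np.ndarray  # per threshold, count of nodes in >= 1 surviving community
    n_nodes: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.connected_nodes, dtype=int)
        if np.any(np.diff(counts) > 0):
            raise ValueError("connected-node counts must be non-increasing in I")
        object.__setattr__(self, "connected_nodes", counts)


@dataclass(frozen=True)
class PercolationResult:
    integral: float
    curve: PercolationCurve | None = None


def enumerate_cliques(net: SemanticNetwork, k: int = 3) -> list[Clique]:
    """All k-node complete subgraphs with their edge-weight geometric means.

    Enumerates by recursive extension over the (sparse) backbone; node
    indices within a clique are sorted ascending and cliques are returned in
    lexicographic order.
    """
    if k < 3:
        raise ConfigurationError("k must be >= 3")
    mask = net.mask
    n = net.n_nodes
    neighbors = [np.flatnonzero(mask[i]) for i in range(n)]
    cliques: list[Clique] = []

    def extend(nodes: list[int], candidates: np.ndarray) -> None:
        if len(nodes) == k:
            pairs = list(itertools.combinations(nodes, 2))
            weights = np.array([net.adjacency[i, j] for i, j in pairs])
            if np.any(weights <= 0):
                intensity = 0.0
            else:
                intensity = float(np.exp(np.mean(np.log(weights))))
            cliques.append(Clique(tuple(nodes), intensity))
            return
        for v in candidates:
            nxt = candidates[(candidates > v) & mask[v][candidates]]
            extend(nodes + [int(v)], nxt)

    for i in range(n):
        extend([i], neighbors[i][neighbors[i] > i])
    return cliques


def clique_communities(cliques: list[Clique], threshold: float, k: int = 3) -> list[set[int]]:
    """Communities of cliques surviving the intensity threshold.

    Cliques with intensity below the threshold are dropped; survivors are
    adjacent when they share k - 1 nodes, and a community is a connected
    component of that clique-adjacency relation (node set = union of its
    cliques' nodes).
    """
    surviving = [c for c in cliques if c.intensity >= threshold]
    if not surviving:
        return []
    parent = list(range(len(surviving)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    by_subset: dict[tuple[int, ...], int] = {}
    for idx, clique in enumerate(surviving):
        for subset in itertools.combinations(clique.nodes, k - 1):
            if subset in by_subset:
                union(by_subset[subset], idx)
            else:
                by_subset[subset] = idx

    groups: dict[int, set[int]] = {}
    for idx, clique in enumerate(surviving):
        groups.setdefault(find(idx), set()).update(clique.nodes)
    return list(groups.values())


def percolation_curve(net: SemanticNetwork, params: PercolationParams = PercolationParams()) -> PercolationCurve:
    """Connected-node count at every threshold of the intensity grid.

    Every surviving clique belongs to some community, so the connected-node
    count at threshold I is the size of the union of node sets of cliques
    with intensity >= I.
    """
    cliques = enumerate_cliques(net, params.k)
    counts = np.zeros(len(params.grid), dtype=int)
    if cliques:
        intensities = np.array([c.intensity for c in cliques])
        nodes = [np.array(c.nodes) for c in cliques]
        for gi, threshold in enumerate(params.grid):
            alive = intensities >= threshold
            if alive.any():
                counts[gi] = len(np.unique(np.concatenate([nodes[ci] for ci in np.flatnonzero(alive)])))
    return PercolationCurve(params.grid, counts, net.n_nodes)


def percolation_integral(curve: PercolationCurve, step: float | None = None) -> PercolationResult:
    """Left Riemann area under the connected-node curve (node x threshold)."""
    if step is None:
        step = float(np.mean(np.diff(curve.grid))) if len(curve.grid) > 1 else float(curve.grid[0])
    return PercolationResult(float(curve.connected_nodes.sum() * step), curve)


def _network_integral(matrix: ResponseMatrix, params: PercolationParams) -> float:
    net = tmfg_filter(cosine_similarity(matrix))
    return percolation_integral(percolation_curve(net, params)).integral


def percolation_comparison(
    a: ResponseMatrix,
    b: ResponseMatrix,
    params: PercolationParams = PercolationParams(),
) -> tuple[MetricDistribution, MetricDistribution, StatResult]:
    """Iterated percolation-integral comparison between two equated groups.

    ``node-subsample`` (default) draws a common random subset of the shared
    words per iteration, mirroring the node-wise bootstrap;
    ``participant-bootstrap`` instead resamples each group's participants
    with replacement (redrawing, with a log, if a word loses all its
    producers) — note that duplicated participants inflate co-occurrence
    similarities, which perturbs clique intensities.  Each iteration
    re-estimates both networks on the fixed equated lexicon and records
    their percolation integrals; the two integral distributions are
    compared with a pooled-variance t-test.
    """
    if a.words != b.words:
        raise ConfigurationError("matrices must be node-equated")
    rng = np.random.default_rng(params.seed)
    ints_a = np.empty(params.iterations)
    ints_b = np.empty(params.iterations)
    n_redrawn = 0
    for it in range(params.iterations):
        if params.mode == PARTICIPANT_BOOTSTRAP:
            for which, mat in enumerate((a, b)):
                for _attempt in range(100):
                    rows = rng.integers(0, mat.shape[0], size=mat.shape[0])
                    resampled = mat.resample_participants(rows)
                    if np.all(resampled.producer_counts() > 0):
                        break
                    n_redrawn += 1
                else:
                    raise ConfigurationError(
                        "could not resample participants without losing a word"
                    )
                value = _network_integral(resampled, params)
                (ints_a if which == 0 else ints_b)[it] = value
        else:
            n = len(a.words)
            size = max(4, math.ceil(params.subsample_proportion * n))
            idx = np.sort(rng.choice(n, size=size, replace=False))
            words = [a.words[i] for i in idx]
            ints_a[it] = _network_integral(a.restrict_words(words), params)
            ints_b[it] = _network_integral(b.restrict_words(words), params)
    dist_a = MetricDistribution("percolation_integral", ints_a, "percolation", params.seed)
    dist_b = MetricDistribution("percolation_integral", ints_b, "percolation", params.seed)
    return dist_a, dist_b, compare_distributions(dist_a, dist_b)
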