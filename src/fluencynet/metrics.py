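"""Graph metrics and the inferential machinery for group contrasts.

Global metrics (ASPL, global clustering, Louvain modularity) are computed on
the TMFG backbone; by default ASPL and clustering treat the backbone as
unweighted while modularity uses the retained edge weights, and local
metrics are fully weighted (strength and Zhang's weighted clustering
coefficient).  Inference uses three reference distributions: Erdos-Renyi
random graphs with matched density, node-wise bootstrap of partial networks,
and (elsewhere) percolation iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.stats as st
from scipy.sparse.csgraph import shortest_path

from .errors import (
    ConfigurationError,
    DegenerateDistributionError,
    TooFewNodesError,
    UndefinedMetricError,
)
from .estimate import SemanticNetwork, cosine_similarity, tmfg_filter
from .preprocess import ResponseMatrix

__all__ = [
    "GlobalMetrics",
    "LocalMetrics",
    "MetricDistribution",
    "StatResult",
    "aspl",
    "global_cc",
    "modularity",
    "global_metrics",
    "local_metrics",
    "er_baseline",
    "z_test",
    "bootstrap_partial_networks",
    "compare_distributions",
    "compare_local_metrics",
    "paired_t",
]


@dataclass(frozen=True)
class GlobalMetrics:
    aspl: float
    cc: float
    q: float

    def as_dict(self) -> dict[str, float]:
        return {"aspl": self.aspl, "cc": self.cc, "q": self.q}


@dataclass(frozen=True)
class LocalMetrics:
    """Per-node weighted strength and Zhang weighted clustering coefficient."""

    words: tuple[str, ...]
    strength: np.ndarray
    local_cc: np.ndarray


@dataclass(frozen=True)
class MetricDistribution:
    """A named sample of a graph metric from a resampling scheme."""

    name: str
    values: np.ndarray
    provenance: str  # random-baseline | bootstrap | percolation
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return float(np.mean(self.values))

    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class StatResult:
    kind: str  # "t" | "z" | "paired-t"
    statistic: float
    p: float
    df: float | None = None
    effect_size: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# Global metrics


def _pairwise_hops(net: SemanticNetwork, weighted: bool) -> np.ndarray:
    if weighted:
        # conventional weighted distance: stronger similarity = shorter path
        with np.errstate(divide="ignore"):
            dist = np.where(net.mask, 1.0 / np.where(net.adjacency > 0, net.adjacency, np.inf), 0.0)
        graph = sp.csr_matrix(dist)
        return shortest_path(graph, method="D", directed=False)
    return shortest_path(sp.csr_matrix(net.backbone()), method="D", directed=False, unweighted=True)


def aspl(net: SemanticNetwork, weighted: bool = False) -> float:
    """Average shortest path length over connected unordered node pairs.

    Unweighted (hop-count) by default; pairs in different components are
    ignored, which keeps the metric defined for disconnected null-model
    replicates.  Raises for networks with no edges.
    """
    if net.n_nodes < 2:
        raise TooFewNodesError("ASPL needs >= 2 nodes")
    if net.n_edges == 0:
        raise UndefinedMetricError("ASPL undefined for an edgeless network")
    d = _pairwise_hops(net, weighted)
    iu = np.triu_indices(net.n_nodes, 1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    return float(finite.mean())


def global_cc(net: SemanticNetwork, weighted: bool = False) -> float:
    """Mean local clustering coefficient.

    Unweighted on the backbone by default (nodes of degree < 2 contribute
    0); with ``weighted=True`` the mean of the Zhang weighted local
    coefficients is returned instead.
    """
    if net.n_nodes < 3:
        raise TooFewNodesError("clustering needs >= 3 nodes")
    if weighted:
        return float(local_metrics(net).local_cc.mean())
    A = net.backbone().astype(np.int64)
    deg = A.sum(axis=1)
    triangles = np.diag(A @ A @ A) / 2  # closed triangles per node
    denom = deg * (deg - 1) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        local = np.where(denom > 0, triangles / denom, 0.0)
    return float(local.mean())


def modularity(
    net: SemanticNetwork,
    seed: int | np.random.Generator = 0,
    restarts: int = 10,
    weighted: bool = True,
) -> tuple[float, list[set[str]]]:
    """Louvain modularity at resolution 1, best of ``restarts`` seeded runs.

    Returns the best Q and its community partition (sets of words).
    """
    g = net.to_networkx()
    if g.number_of_edges() == 0:
        raise UndefinedMetricError("modularity undefined without edges")
    weight = "weight" if weighted else None
    if weight is not None and sum(d["weight"] for _, _, d in g.edges(data=True)) <= 0:
        weight = None  # all-zero weights: fall back to topology
    rng = np.random.default_rng(seed)
    best_q = -np.inf
    best_part: list[set[str]] = []
    for _ in range(max(1, restarts)):
        sub = int(rng.integers(0, 2**31 - 1))
        communities = nx.community.louvain_communities(g, weight=weight, seed=sub, resolution=1.0)
        q = nx.community.modularity(g, communities, weight=weight)
        if q > best_q:
            best_q = q
            best_part = [set(c) for c in communities]
    return float(best_q), best_part


def global_metrics(
    net: SemanticNetwork,
    seed: int | np.random.Generator = 0,
    weighted_paths: bool = False,
    weighted_cc: bool = False,
    restarts: int = 10,
) -> GlobalMetrics:
    q, _ = modularity(net, seed=seed, restarts=restarts)
    return GlobalMetrics(
        aspl=aspl(net, weighted=weighted_paths),
        cc=global_cc(net, weighted=weighted_cc),
        q=q,
    )


# ---------------------------------------------------------------------------
# Local metrics


def local_metrics(net: SemanticNetwork) -> LocalMetrics:
    """Weighted strength and Zhang weighted local clustering per node.

    With normalized weights ``w_hat = w / max(w)``, Zhang's coefficient for
    node i is ``sum_{j != k} w_hat_ij w_hat_jk w_hat_ki`` over
    ``(sum_j w_hat_ij)^2 - sum_j w_hat_ij^2``; isolated or degenerate nodes
    get 0.
    """
    if net.n_nodes < 2:
        raise TooFewNodesError("local metrics need >= 2 nodes")
    W = net.adjacency
    strength = W.sum(axis=1)
    wmax = W.max()
    if wmax == 0:
        zeros = np.zeros(net.n_nodes)
        return LocalMetrics(net.words, strength, zeros)
    Wh = W / wmax
    num = np.diag(Wh @ Wh @ Wh)  # = sum_{j,k} what_ij what_jk what_ki
    s = Wh.sum(axis=1)
    denom = s**2 - (Wh**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(denom > 1e-15, num / denom, 0.0)
    return LocalMetrics(net.words, strength, cc)


# ---------------------------------------------------------------------------
# Random-graph baseline


def er_baseline(
    n: int,
    m: int,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    louvain_restarts: int = 10,
) -> dict[str, MetricDistribution]:
    """Reference distributions of ASPL/CC/Q from G(n, p) random graphs.

    ``p = 2m / (n (n - 1))`` matches the observed edge density.  ASPL on a
    disconnected replicate averages over connected pairs; replicates with no
    edges contribute NaN (excluded by the z-test caller if present).
    """
    if n < 3:
        raise TooFewNodesError("baseline needs n >= 3")
    p = 2 * m / (n * (n - 1))
    if not (0 < p <= 1):
        raise ConfigurationError(f"edge probability {p:.4f} outside (0, 1]")
    rng = np.random.default_rng(seed)
    out = {name: np.empty(reps) for name in ("aspl", "cc", "q")}
    for r in range(reps):
        g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
        adj = nx.to_numpy_array(g, nodelist=range(n))
        net = SemanticNetwork(tuple(map(str, range(n))), adj)
        if net.n_edges == 0:
            out["aspl"][r] = out["cc"][r] = out["q"][r] = np.nan
            continue
        out["aspl"][r] = aspl(net)
        out["cc"][r] = global_cc(net)
        out["q"][r], _ = modularity(net, seed=rng, restarts=louvain_restarts)
    seed_val = seed if isinstance(seed, int) else None
    return {
        name: MetricDistribution(name, vals, "random-baseline", seed_val)
        for name, vals in out.items()
    }


def z_test(observed: float, dist: MetricDistribution) -> StatResult:
    """One-sample z of an observed value against a reference distribution."""
    vals = dist.values[np.isfinite(dist.values)]
    if len(vals) < 2:
        raise DegenerateDistributionError("need >= 2 reference values")
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise DegenerateDistributionError("reference distribution has zero spread")
    z = (observed - float(np.mean(vals))) / sd
    p = 2 * st.norm.sf(abs(z))
    return StatResult(kind="z", statistic=float(z), p=float(p))


# ---------------------------------------------------------------------------
# Node-wise bootstrap


@dataclass
class BootstrapResult:
    """Paired bootstrap distributions per metric plus replicate bookkeeping."""

    distributions: dict[str, tuple[MetricDistribution, MetricDistribution]]
    subset_size: int
    reps: int
    log: list[str] = field(default_factory=list)


def bootstrap_partial_networks(
    a: ResponseMatrix,
    b: ResponseMatrix,
    reps: int = 1000,
    proportion: float = 0.5,
    seed: int | np.random.Generator = 0,
    louvain_restarts: int = 10,
) -> BootstrapResult:
    """Node-wise bootstrap of partial networks for two equated groups.

    Each replicate draws the same random subset of ``ceil(proportion * n)``
    shared words for both groups, re-estimates each group's network
    (cosine + TMFG) on that subset, and records ASPL/CC/Q, yielding paired
    sampling distributions for every metric.
    """
    if a.words != b.words:
        raise ConfigurationError("matrices must be node-equated before bootstrapping")
    n = len(a.words)
    size = math.ceil(proportion * n)
    if proportion >= 1.0:
        size = n
    if size < 4:
        raise ConfigurationError(f"subset of {size} words is too small for TMFG")
    rng = np.random.default_rng(seed)
    names = ("aspl", "cc", "q")
    samples = {name: (np.empty(reps), np.empty(reps)) for name in names}
    log: list[str] = []
    for r in range(reps):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        words = [a.words[i] for i in idx]
        for which, mat in enumerate((a, b)):
            sub = mat.restrict_words(words)
            net = tmfg_filter(cosine_similarity(sub))
            samples["aspl"][which][r] = aspl(net)
            samples["cc"][which][r] = global_cc(net)
            samples["q"][which][r], _ = modularity(net, seed=rng, restarts=louvain_restarts)
    seed_val = seed if isinstance(seed, int) else None
    dists = {
        name: (
            MetricDistribution(name, pair[0], "bootstrap", seed_val),
            MetricDistribution(name, pair[1], "bootstrap", seed_val),
        )
        for name, pair in samples.items()
    }
    return BootstrapResult(dists, subset_size=size, reps=reps, log=log)


# ---------------------------------------------------------------------------
# Statistical comparisons


def _cohens_d_pooled(x: np.ndarray, y: np.ndarray) -> float:
    nx_, ny = len(x), len(y)
    sp2 = ((nx_ - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx_ + ny - 2)
    return float((np.mean(x) - np.mean(y)) / np.sqrt(sp2))


def compare_distributions(a: MetricDistribution, b: MetricDistribution) -> StatResult:
    """Pooled-variance independent-samples t-test with Cohen's d."""
    x, y = a.values[np.isfinite(a.values)], b.values[np.isfinite(b.values)]
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDistributionError("need >= 2 values per distribution")
    if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return StatResult("t", 0.0, 1.0, df=len(x) + len(y) - 2, effect_size=0.0)
        raise DegenerateDistributionError("both distributions are constant")
    t, p = st.ttest_ind(x, y, equal_var=True)
    return StatResult(
        kind="t",
        statistic=float(t),
        p=float(p),
        df=len(x) + len(y) - 2,
        effect_size=_cohens_d_pooled(x, y),
    )


def paired_t(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Paired t-test with the paired-design Cohen's d (mean diff / SD diff)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ConfigurationError("paired samples must align")
    diff = x - y
    sd = np.std(diff, ddof=1)
    if sd == 0:
        p = 1.0 if np.allclose(diff, 0) else 0.0
        return StatResult("paired-t", 0.0 if np.allclose(diff, 0) else np.inf, p,
                          df=len(x) - 1, effect_size=0.0 if np.allclose(diff, 0) else np.inf)
    t, p = st.ttest_rel(x, y)
    d = float(np.mean(diff) / sd)
    return StatResult("paired-t", float(t), float(p), df=len(x) - 1, effect_size=d)


def compare_local_metrics(a: LocalMetrics, b: LocalMetrics) -> dict[str, StatResult]:
    """Paired t-tests over matched words for strength and Zhang local CC."""
    if a.words != b.words:
        raise ConfigurationError("local metrics must come from equated networks")
    return {
        "strength": paired_t(a.strength, b.strength),
        "local_cc": paired_t(a.local_cc, b.local_cc),
    }
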