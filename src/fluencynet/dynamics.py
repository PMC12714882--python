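"""Spreading-activation simulation on semantic networks.

Each node retains a fraction ``r`` of its activation per time step and
diffuses the remaining ``1 - r`` to its neighbors in proportion to edge
weight; activation then decays by ``d`` and values below the suppression
threshold ``s`` are zeroed.  With ``d = 0`` and ``s = 0`` on a network
without isolated nodes, total activation is conserved and the process
converges to the strength-proportional stationary distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, SingularDesignError
from .estimate import SemanticNetwork
from .metrics import LocalMetrics, StatResult, paired_t

__all__ = [
    "SpreadParams",
    "ActivationTrace",
    "spread_step",
    "simulate_spreading",
    "compare_activation",
    "regress_activation",
    "ActivationRegression",
]

SINGLE_SEED_SWEEP = "single-seed-sweep"
ALL_NODE_INIT = "all-node-init"


@dataclass(frozen=True)
class SpreadParams:
    """Simulation parameters.

    Defaults: 100 units of initial activation per seeded node, retention
    r = 0.5, decay d = 0, suppression s = 0, and 10 time steps.
    """

    initial_activation: float = 100.0
    retention: float = 0.5
    decay: float = 0.0
    suppress: float = 0.0
    time_steps: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.retention <= 1.0):
            raise ConfigurationError("retention must lie in [0, 1]")
        if not (0.0 <= self.decay <= 1.0):
            raise ConfigurationError("decay must lie in [0, 1]")
        if self.suppress < 0:
            raise ConfigurationError("suppress must be >= 0")
        if self.time_steps < 0:
            raise ConfigurationError("time_steps must be >= 0")
        if self.initial_activation < 0:
            raise ConfigurationError("initial activation must be >= 0")


@dataclass(frozen=True)
class ActivationTrace:
    """Recorded activation values.

    ``mode == "single-seed-sweep"``: ``values`` has shape
    ``(n_seeds, n_nodes, t + 1)`` — one independent simulation per seed
    node.  ``mode == "all-node-init"``: shape ``(n_nodes, t + 1)`` — one
    simulation with every node seeded.
    """

    mode: str
    words: tuple[str, ...]
    values: np.ndarray
    params: SpreadParams

    @property
    def time_steps(self) -> int:
        return self.values.shape[-1] - 1

    def seed_series(self) -> np.ndarray:
        """Activation of each word across time under its own seeding.

        For the sweep mode this is the diagonal across (seed, node); for the
        all-node-init mode it is the trace itself.  Shape: (n_nodes, t + 1).
        """
        if self.mode == ALL_NODE_INIT:
            return self.values
        n = len(self.words)
        return self.values[np.arange(n), np.arange(n), :]

    def received_series(self) -> np.ndarray:
        """Mean activation each word receives from the other seeds' runs.

        For word w at time t this averages ``values[seed, w, t]`` over all
        seeds != w: how much activation reaches w when retrieval starts
        elsewhere in the lexicon.  In a well-integrated network activation
        reaches other words quickly, so received activation rises faster;
        degraded networks keep activation stuck near its seed.  Only defined
        for the sweep mode.  Shape: (n_nodes, t + 1).
        """
        if self.mode != SINGLE_SEED_SWEEP:
            raise ConfigurationError("received activation requires the sweep mode")
        n = len(self.words)
        total = self.values.sum(axis=0)  # (node, time)
        return (total - self.seed_series()) / (n - 1)

    def spread_series(self) -> np.ndarray:
        """Activation each word has transmitted into the network.

        For word w at time t this is ``initial_activation - values[w, w, t]``:
        the portion of w's seeded activation that has left the seed (all of
        it circulating among the other words when decay and suppression are
        zero).  It indexes transmission
        efficiency — degraded networks hold activation at the seed, so their
        spread values are lower.  Only defined for the sweep mode.
        Shape: (n_nodes, t + 1).
        """
        if self.mode != SINGLE_SEED_SWEEP:
            raise ConfigurationError("spread activation requires the sweep mode")
        return self.params.initial_activation - self.seed_series()

    def series(self, measure: str = "spread") -> np.ndarray:
        if self.mode == ALL_NODE_INIT:
            return self.values
        if measure == "spread":
            return self.spread_series()
        if measure == "received":
            return self.received_series()
        if measure == "own":
            return self.seed_series()
        raise ConfigurationError(f"unknown measure {measure!r}")

    def final_activation(self, measure: str = "own") -> np.ndarray:
        """Per-word activation at the last time step (own-seed by default)."""
        return self.series(measure)[:, -1]


def _transfer_matrix(net: SemanticNetwork) -> np.ndarray:
    """Column-stochastic diffusion matrix T[i, j] = w_ij / strength_j.

    Columns of isolated nodes are zero: their outgoing share is lost, and
    they only retain ``r`` of their own activation.
    """
    W = net.adjacency
    s = net.strengths()
    T = np.zeros_like(W)
    nz = s > 0
    T[:, nz] = W[:, nz] / s[nz]
    return T


def spread_step(
    net: SemanticNetwork, state: np.ndarray, params: SpreadParams
) -> np.ndarray:
    """One synchronous update of the activation vector."""
    state = np.asarray(state, dtype=float)
    if state.shape[0] != net.n_nodes:
        raise ConfigurationError("state length must equal node count")
    if np.any(state < 0):
        raise ConfigurationError("activation must be non-negative")
    T = _transfer_matrix(net)
    new = params.retention * state + (1 - params.retention) * (T @ state)
    new *= 1 - params.decay
    if params.suppress > 0:
        new[new < params.suppress] = 0.0
    return new


def simulate_spreading(
    net: SemanticNetwork,
    params: SpreadParams = SpreadParams(),
    mode: str = SINGLE_SEED_SWEEP,
) -> ActivationTrace:
    """Run the spreading simulation and record the full activation trace.

    ``single-seed-sweep`` runs one simulation per node with only that node
    seeded (the per-word activation is then read off each word's own run);
    ``all-node-init`` seeds every node at once in a single simulation.
    """
    n = net.n_nodes
    T = _transfer_matrix(net)
    r, d, s, t = params.retention, params.decay, params.suppress, params.time_steps

    def run(initial: np.ndarray) -> np.ndarray:
        # columns of `initial` are independent simulations
        trace = np.empty((initial.shape[1], n, t + 1))
        state = initial.astype(float)
        trace[:, :, 0] = state.T
        for step in range(1, t + 1):
            state = r * state + (1 - r) * (T @ state)
            state *= 1 - d
            if s > 0:
                state[state < s] = 0.0
            trace[:, :, step] = state.T
        return trace

    if mode == SINGLE_SEED_SWEEP:
        values = run(np.eye(n) * params.initial_activation)
    elif mode == ALL_NODE_INIT:
        values = run(np.full((n, 1), params.initial_activation))[0]
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    return ActivationTrace(mode, net.words, values, params)


def compare_activation(
    a: ActivationTrace, b: ActivationTrace, measure: str = "spread"
) -> list[StatResult]:
    """Paired t-test across matched words at each time step 1..t.

    The default ``spread`` measure compares how much of each word's seeded
    activation has been transmitted into the network (the transmission-
    efficiency reading of the simulation); ``received`` compares how much
    activation reaches each word from the other seeds; ``own`` compares
    each word's activation in its own seeded run, which instead indexes how
    slowly activation leaves the seed.
    """
    if a.words != b.words:
        raise ConfigurationError("traces must cover identical word sets")
    if a.mode != b.mode or a.params != b.params:
        raise ConfigurationError("traces must share mode and parameters")
    sa, sb = a.series(measure), b.series(measure)
    return [paired_t(sa[:, step], sb[:, step]) for step in range(1, a.time_steps + 1)]


@dataclass(frozen=True)
class ActivationRegression:
    """OLS of final activation on standardized strength and local CC."""

    terms: tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r_squared: float
    n: int

    def coef(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def as_dict(self) -> dict:
        return {
            term: {
                "estimate": float(self.estimates[i]),
                "se": float(self.se[i]),
                "t": float(self.t[i]),
                "p": float(self.p[i]),
            }
            for i, term in enumerate(self.terms)
        } | {"r_squared": self.r_squared, "n": self.n}


def regress_activation(final: np.ndarray, locals_: LocalMetrics) -> ActivationRegression:
    """Predict per-word final activation from local degree and clustering.

    Both predictors are z-scored, so the estimates are comparable
    standardized effects.  Raises on constant predictors.
    """
    import statsmodels.api as sm

    final = np.asarray(final, float)
    if len(final) < 3:
        raise ConfigurationError("need >= 3 words for regression")
    if len(final) != len(locals_.words):
        raise ConfigurationError("activation and local metrics must align")

    def zscore(x: np.ndarray) -> np.ndarray:
        sd = np.std(x, ddof=1)
        if sd == 0:
            raise SingularDesignError("constant predictor")
        return (x - np.mean(x)) / sd

    X = np.column_stack(
        [np.ones_like(final), zscore(locals_.strength), zscore(locals_.local_cc)]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("collinear predictors")
    fit = sm.OLS(final, X).fit()
    return ActivationRegression(
        terms=("intercept", "strength", "local_cc"),
        estimates=np.asarray(fit.params),
        se=np.asarray(fit.bse),
        t=np.asarray(fit.tvalues),
        p=np.asarray(fit.pvalues),
        r_squared=float(fit.rsquared),
        n=len(final),
    )
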