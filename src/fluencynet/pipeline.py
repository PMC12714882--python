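"""End-to-end two-group comparison orchestration.

``run_comparison`` sequences the full analysis — cleaning, response-count
contrast, matrix construction, node equating, network estimation, global
and local metrics, random-graph z-tests, node-wise bootstrap, spreading
activation, and clique percolation — from a single :class:`RunConfig`, and
optionally serializes every intermediate product.  The master seed spawns a
labelled sub-seed per stochastic stage, so each stage is reproducible
independently of execution order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .dynamics import (
    SpreadParams,
    compare_activation,
    regress_activation,
    simulate_spreading,
)
from .errors import ConfigurationError
from .estimate import SemanticNetwork, estimate_network
from .metrics import (
    MetricDistribution,
    StatResult,
    bootstrap_partial_networks,
    compare_distributions,
    compare_local_metrics,
    er_baseline,
    global_metrics,
    local_metrics,
    z_test,
)
from .percolation import PercolationParams, percolation_comparison
from .preprocess import (
    CleaningDictionary,
    ColumnDialect,
    FluencyDataset,
    build_response_matrix,
    clean_responses,
    compare_counts_adjusted,
    count_appropriate_responses,
    default_animal_dictionary,
    equate_nodes,
    filter_min_producers,
    read_fluency_file,
)
from .synthdata import GroupProfile, default_profiles, simulate_cohort

__all__ = ["RunConfig", "ComparisonReport", "run_comparison", "derive_seed"]


def derive_seed(master: int, label: str) -> int:
    """Stable 31-bit sub-seed for a named pipeline stage."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one comparison run needs.

    Either ``input_path`` (a fluency CSV in the configured dialect, with an
    optional ``demographics_path``) or ``synthetic=True`` (cohorts simulated
    from the named default profiles of the two groups) supplies the data.
    """

    groups: tuple[str, str] = ("control", "aphasia")
    synthetic: bool = True
    input_path: str | None = None
    demographics_path: str | None = None
    dialect: ColumnDialect = field(default_factory=ColumnDialect)
    profiles: dict[str, GroupProfile] | None = None
    min_producers: int = 2
    er_reps: int = 1000
    bootstrap_reps: int = 1000
    bootstrap_proportion: float = 0.5
    spread: SpreadParams = field(default_factory=SpreadParams)
    percolation_k: int = 3
    percolation_iterations: int = 500
    percolation_mode: str = "node-subsample"
    weighted_paths: bool = False
    weighted_cc: bool = False
    louvain_restarts: int = 10
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)  # type: ignore[assignment]
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ConfigurationError("exactly two distinct groups per run")
        if not self.synthetic and self.input_path is None:
            raise ConfigurationError("need input_path when synthetic=False")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "dialect" in raw:
            raw["dialect"] = ColumnDialect(**raw["dialect"])
        if "spread" in raw:
            raw["spread"] = SpreadParams(**raw["spread"])
        if "profiles" in raw and raw["profiles"] is not None:
            raw["profiles"] = {
                name: GroupProfile(name=name, **params)
                for name, params in raw["profiles"].items()
            }
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        out = asdict(self)
        out["groups"] = list(self.groups)
        return out


def _stat_dict(res: StatResult) -> dict[str, Any]:
    return {
        "kind": res.kind,
        "statistic": res.statistic,
        "df": res.df,
        "p": res.p,
        "effect_size": res.effect_size,
    }


@dataclass
class ComparisonReport:
    """Consolidated results of one two-group run (JSON-serializable)."""

    config: dict[str, Any]
    version: str
    counts: dict[str, Any]
    equating: dict[str, Any]
    network_metrics: dict[str, Any]
    random_baseline: dict[str, Any]
    bootstrap: dict[str, Any]
    local: dict[str, Any]
    activation: dict[str, Any]
    percolation: dict[str, Any]

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, default=float))


def _load_dataset(config: RunConfig) -> tuple[FluencyDataset, pd.DataFrame | None]:
    if config.synthetic:
        profiles = config.profiles or default_profiles()
        missing = [g for g in config.groups if g not in profiles]
        if missing:
            raise ConfigurationError(f"no profile for groups: {missing}")
        cohort = simulate_cohort(
            [profiles[g] for g in config.groups],
            seed=derive_seed(config.seed, "synthdata"),
        )
        return cohort.dataset, cohort.demographics
    dataset = read_fluency_file(config.input_path, config.dialect)
    demographics = None
    if config.demographics_path:
        demographics = pd.read_csv(config.demographics_path, index_col="participant")
    return dataset, demographics


def run_comparison(
    config: RunConfig,
    dataset: FluencyDataset | None = None,
    demographics: pd.DataFrame | None = None,
    dictionary: CleaningDictionary | None = None,
) -> ComparisonReport:
    """Execute the full two-group pipeline and return a consolidated report.

    Stages: clean -> count contrast -> binarize/filter/equate -> estimate
    (cosine + TMFG) -> global metrics + ER z-tests -> node-wise bootstrap ->
    local paired tests -> spreading activation (per-step paired tests and
    structure regressions) -> clique-percolation comparison.  When
    ``config.outdir`` is set, the report JSON, GraphML networks, and
    distribution CSVs are written there.
    """
    dictionary = dictionary or default_animal_dictionary()
    if dataset is None:
        dataset, demographics = _load_dataset(config)
    ga, gb = config.groups

    cleaned, log = clean_responses(dataset, dictionary)
    counts = count_appropriate_responses(cleaned)
    group_labels = pd.Series(
        {r.participant_id: r.group for r in cleaned}, name="group"
    )
    keep = group_labels.isin(config.groups)
    covariates = demographics.loc[keep[keep].index] if demographics is not None else None
    count_cmp = compare_counts_adjusted(
        counts[keep], group_labels[keep], covariates, reference=ga
    )
    group_means = {
        g: float(counts[group_labels == g].mean()) for g in config.groups
    }

    # matrices: per-group filter, then equate (no re-filtering after intersection)
    mats = {}
    for g in config.groups:
        mat = build_response_matrix(cleaned.for_group(g))
        mats[g] = filter_min_producers(mat, config.min_producers)
    mat_a, mat_b, equate_report = equate_nodes(mats[ga], mats[gb])

    net_a = estimate_network(mat_a)
    net_b = estimate_network(mat_b)
    nets = {ga: net_a, gb: net_b}

    gm = {
        g: global_metrics(
            net,
            seed=derive_seed(config.seed, f"louvain-{g}"),
            weighted_paths=config.weighted_paths,
            weighted_cc=config.weighted_cc,
            restarts=config.louvain_restarts,
        )
        for g, net in nets.items()
    }

    baseline = {}
    for g, net in nets.items():
        dists = er_baseline(
            net.n_nodes,
            net.n_edges,
            reps=config.er_reps,
            seed=derive_seed(config.seed, f"er-{g}"),
            louvain_restarts=config.louvain_restarts,
        )
        baseline[g] = {
            name: _stat_dict(z_test(getattr(gm[g], name), dist))
            for name, dist in dists.items()
        }

    boot = bootstrap_partial_networks(
        mat_a,
        mat_b,
        reps=config.bootstrap_reps,
        proportion=config.bootstrap_proportion,
        seed=derive_seed(config.seed, "bootstrap"),
        louvain_restarts=config.louvain_restarts,
    )
    boot_report: dict[str, Any] = {}
    boot_dists: dict[str, tuple[MetricDistribution, MetricDistribution]] = boot.distributions
    for name, (da, db) in boot_dists.items():
        boot_report[name] = {
            f"mean_{ga}": da.mean(),
            f"sd_{ga}": da.sd(),
            f"mean_{gb}": db.mean(),
            f"sd_{gb}": db.sd(),
            "test": _stat_dict(compare_distributions(da, db)),
        }

    loc_a, loc_b = local_metrics(net_a), local_metrics(net_b)
    local_tests = {
        name: _stat_dict(res) for name, res in compare_local_metrics(loc_a, loc_b).items()
    }
    local_report = {
        "tests": local_tests,
        "means": {
            ga: {"strength": float(loc_a.strength.mean()), "local_cc": float(loc_a.local_cc.mean())},
            gb: {"strength": float(loc_b.strength.mean()), "local_cc": float(loc_b.local_cc.mean())},
        },
    }

    trace_a = simulate_spreading(net_a, config.spread)
    trace_b = simulate_spreading(net_b, config.spread)
    act_tests = compare_activation(trace_a, trace_b)  # spread (transmission)
    regressions = {
        ga: regress_activation(trace_a.final_activation("own"), loc_a).as_dict(),
        gb: regress_activation(trace_b.final_activation("own"), loc_b).as_dict(),
    }
    activation_report = {
        "measure": "spread",
        "per_step_tests": [_stat_dict(r) for r in act_tests],
        "mean_final_spread": {
            ga: float(trace_a.final_activation("spread").mean()),
            gb: float(trace_b.final_activation("spread").mean()),
        },
        "mean_final_own": {
            ga: float(trace_a.final_activation("own").mean()),
            gb: float(trace_b.final_activation("own").mean()),
        },
        "regressions": regressions,
    }

    perc_params = PercolationParams(
        k=config.percolation_k,
        iterations=config.percolation_iterations,
        mode=config.percolation_mode,
        seed=derive_seed(config.seed, "percolation"),
    )
    perc_a, perc_b, perc_test = percolation_comparison(mat_a, mat_b, perc_params)
    percolation_report = {
        f"mean_{ga}": perc_a.mean(),
        f"sd_{ga}": perc_a.sd(),
        f"mean_{gb}": perc_b.mean(),
        f"sd_{gb}": perc_b.sd(),
        "test": _stat_dict(perc_test),
    }

    report = ComparisonReport(
        config=config.to_dict(),
        version=_version,
        counts={
            "group_means": group_means,
            "comparison": asdict(count_cmp),
            "cleaning_totals": asdict(log.totals()),
        },
        equating={
            "n_shared": equate_report.n_shared,
            f"n_excluded_{ga}": len(equate_report.excluded_a),
            f"n_excluded_{gb}": len(equate_report.excluded_b),
        },
        network_metrics={g: gm[g].as_dict() for g in config.groups},
        random_baseline=baseline,
        bootstrap=boot_report,
        local=local_report,
        activation=activation_report,
        percolation=percolation_report,
    )

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.write_json(outdir / "report.json")
        for g, net in nets.items():
            net.write_graphml(outdir / f"network_{g}.graphml")
            net.write_edgelist(outdir / f"network_{g}_edges.csv")
        frame = pd.DataFrame(
            {
                f"{name}_{g}": dist.values
                for name, pair in boot_dists.items()
                for g, dist in zip(config.groups, pair)
            }
        )
        frame.to_csv(outdir / "bootstrap_distributions.csv", index=False)
        pd.DataFrame(
            {f"integral_{ga}": perc_a.values, f"integral_{gb}": perc_b.values}
        ).to_csv(outdir / "percolation_integrals.csv", index=False)
        log.to_json(outdir / "cleaning_log.json")
    return report
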