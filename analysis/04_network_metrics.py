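"""Global and local network metrics with null-model and bootstrap inference.

For each group pair: full-network ASPL/CC/Q; z-tests against 300
density-matched Erdos-Renyi graphs; node-wise bootstrap (300 half-node
replicates) with pooled t-tests and Cohen's d; and paired t-tests on local
strength and Zhang clustering over the shared words.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import BOOTSTRAP_REPS, COMPARISONS, ER_REPS, RESULTS, SEED, data_dir

from fluencynet.estimate import SemanticNetwork
from fluencynet.metrics import (
    bootstrap_partial_networks,
    compare_distributions,
    compare_local_metrics,
    er_baseline,
    global_metrics,
    local_metrics,
    z_test,
)
from fluencynet.pipeline import derive_seed
from fluencynet.preprocess import ResponseMatrix


def main() -> None:
    summary = []
    for groups in COMPARISONS:
        outdir = data_dir(groups)
        nets = {
            g: SemanticNetwork.read_graphml(outdir / f"network_{g}.graphml")
            for g in groups
        }
        mats = {
            g: ResponseMatrix.read_csv(outdir / f"matrix_{g}.csv") for g in groups
        }

        gm = {
            g: global_metrics(net, seed=derive_seed(SEED, f"louvain-{g}"))
            for g, net in nets.items()
        }
        for g in groups:
            dists = er_baseline(
                nets[g].n_nodes, nets[g].n_edges, reps=ER_REPS,
                seed=derive_seed(SEED, f"er-{g}"),
            )
            zs = {m: z_test(getattr(gm[g], m), d) for m, d in dists.items()}
            print(
                f"{g}: ASPL={gm[g].aspl:.2f} CC={gm[g].cc:.3f} Q={gm[g].q:.3f} | "
                + " ".join(f"z_{m}={zs[m].statistic:+.1f}" for m in zs)
            )

        boot = bootstrap_partial_networks(
            mats[groups[0]], mats[groups[1]], reps=BOOTSTRAP_REPS,
            seed=derive_seed(SEED, "bootstrap"),
        )
        frame = {}
        for metric, (da, db) in boot.distributions.items():
            res = compare_distributions(da, db)
            print(
                f"  bootstrap {metric}: {da.mean():.3f} ({da.sd():.3f}) vs "
                f"{db.mean():.3f} ({db.sd():.3f}), t({res.df:.0f})={res.statistic:.2f},"
                f" d={res.effect_size:.2f}"
            )
            frame[f"{metric}_{groups[0]}"] = da.values
            frame[f"{metric}_{groups[1]}"] = db.values
            summary.append(
                {
                    "comparison": f"{groups[0]}_vs_{groups[1]}",
                    "metric": metric,
                    f"mean_{groups[0]}": da.mean(),
                    f"mean_{groups[1]}": db.mean(),
                    "t": res.statistic,
                    "d": res.effect_size,
                }
            )
        pd.DataFrame(frame).to_csv(outdir / "bootstrap_distributions.csv", index=False)

        loc = {g: local_metrics(nets[g]) for g in groups}
        tests = compare_local_metrics(loc[groups[0]], loc[groups[1]])
        for name, res in tests.items():
            print(
                f"  local {name}: paired t({res.df})={res.statistic:.2f}, "
                f"p={res.p:.3g}, d={res.effect_size:.2f}"
            )
        (outdir / "local_tests.json").write_text(
            json.dumps(
                {
                    name: {"t": r.statistic, "df": r.df, "p": r.p, "d": r.effect_size}
                    for name, r in tests.items()
                },
                indent=2,
            )
        )
    pd.DataFrame(summary).to_csv(RESULTS / "bootstrap_summary.csv", index=False)


if __name__ == "__main__":
    main()
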