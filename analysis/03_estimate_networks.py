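"""Estimate the group semantic networks.

Binarizes the cleaned cohorts, filters words to >= 2 producers per group,
equates nodes across each group pair, and estimates cosine + TMFG networks.
Writes the equated response matrices, GraphML networks, and the node
equating report.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import COMPARISONS, data_dir

from fluencynet.estimate import estimate_network
from fluencynet.preprocess import (
    build_response_matrix,
    equate_nodes,
    filter_min_producers,
    read_fluency_file,
)


def main() -> None:
    for groups in COMPARISONS:
        outdir = data_dir(groups)
        cleaned = read_fluency_file(outdir / "cohort_clean.csv")
        mats = {
            g: filter_min_producers(build_response_matrix(cleaned.for_group(g)))
            for g in groups
        }
        raw_sizes = {g: mats[g].shape[1] for g in groups}
        mat_a, mat_b, report = equate_nodes(mats[groups[0]], mats[groups[1]])
        for g, mat in zip(groups, (mat_a, mat_b)):
            mat.write_csv(outdir / f"matrix_{g}.csv")
            net = estimate_network(mat)
            net.write_graphml(outdir / f"network_{g}.graphml")
            net.write_edgelist(outdir / f"network_{g}_edges.csv")
        (outdir / "equating.json").write_text(
            json.dumps(
                {
                    "n_shared": report.n_shared,
                    "filtered_words": raw_sizes,
                    f"excluded_{groups[0]}": list(report.excluded_a),
                    f"excluded_{groups[1]}": list(report.excluded_b),
                },
                indent=2,
            )
        )
        print(
            f"{groups[0]} vs {groups[1]}: {report.n_shared} shared nodes "
            f"({3 * report.n_shared - 6} TMFG edges each); excluded "
            f"{len(report.excluded_a)} idiosyncratic from {groups[0]}, "
            f"{len(report.excluded_b)} from {groups[1]}"
        )


if __name__ == "__main__":
    main()
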