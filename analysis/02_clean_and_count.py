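"""Clean the cohorts and compare appropriate-response counts.

Standardizes variants, removes intrusions and perseverations, then fits
the covariate-adjusted (age + education) group contrast on per-participant
appropriate-response counts.  Writes per-participant counts and the
contrast table.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import COMPARISONS, RESULTS, data_dir

from fluencynet.preprocess import (
    clean_responses,
    compare_counts_adjusted,
    count_appropriate_responses,
    default_animal_dictionary,
    read_fluency_file,
    write_fluency_file,
)


def main() -> None:
    dictionary = default_animal_dictionary()
    rows = []
    for groups in COMPARISONS:
        outdir = data_dir(groups)
        dataset = read_fluency_file(outdir / "cohort.csv")
        demographics = pd.read_csv(outdir / "demographics.csv", index_col="participant")
        cleaned, log = clean_responses(dataset, dictionary)
        write_fluency_file(cleaned, outdir / "cohort_clean.csv")
        log.to_json(outdir / "cleaning_log.json")

        counts = count_appropriate_responses(cleaned)
        labels = pd.Series({r.participant_id: r.group for r in cleaned})
        counts.to_frame().assign(group=labels).to_csv(outdir / "counts.csv")
        res = compare_counts_adjusted(counts, labels, demographics, reference=groups[0])
        totals = log.totals()
        print(
            f"{groups[0]} vs {groups[1]}: "
            + ", ".join(
                f"{g} M={counts[labels == g].mean():.2f} (SD={counts[labels == g].std():.2f})"
                for g in groups
            )
            + f"; adjusted beta={res.beta:.2f}, t({res.df})={res.t:.2f}, p={res.p:.2g}"
            f" | cleaned out {totals.perseverations_removed} perseverations,"
            f" {totals.noncategory_removed} intrusions"
        )
        rows.append(
            {
                "comparison": f"{groups[0]}_vs_{groups[1]}",
                **{f"mean_{g}": counts[labels == g].mean() for g in groups},
                "beta": res.beta,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    pd.DataFrame(rows).to_csv(RESULTS / "response_counts.csv", index=False)


if __name__ == "__main__":
    main()
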