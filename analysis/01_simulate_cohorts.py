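"""Generate the synthetic study cohorts.

Draws two paired cohorts from the default group profiles — control vs.
aphasia (combined) and fluent vs. nonfluent — whose sizes and response
distributions encode the study conditions, and writes each as a fluency
CSV with demographics and a ground-truth manifest.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import COMPARISONS, SEED, data_dir

from fluencynet.pipeline import derive_seed
from fluencynet.synthdata import default_profiles, simulate_cohort


def main() -> None:
    profiles = default_profiles()
    for groups in COMPARISONS:
        cohort = simulate_cohort(
            [profiles[g] for g in groups], seed=derive_seed(SEED, "synthdata")
        )
        outdir = data_dir(groups)
        cohort.write(outdir)
        sizes = {g: len(cohort.dataset.for_group(g)) for g in groups}
        print(f"{groups[0]} vs {groups[1]}: wrote {sizes} participants -> {outdir}")


if __name__ == "__main__":
    main()
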