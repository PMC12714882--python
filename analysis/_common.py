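"""Shared paths and settings for the analysis drivers.

Each numbered script reads what earlier scripts wrote under results/ and
appends its own tables, so the sequence can be re-run stage by stage.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"
DATA.mkdir(parents=True, exist_ok=True)

SEED = 20251001  # master seed for the whole analysis sequence

# resampling sizes for the interactive analysis run
ER_REPS = 300
BOOTSTRAP_REPS = 300
PERCOLATION_ITERATIONS = 150

COMPARISONS = (("control", "aphasia"), ("fluent", "nonfluent"))


def data_dir(groups: tuple[str, str]) -> Path:
    return DATA / f"{groups[0]}_vs_{groups[1]}"
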