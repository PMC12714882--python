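"""Synthetic fluency cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
shared vocabulary organized into semantic blocks (a community-structured
weighted lexicon network), group-specific list-length distributions
(controls produce more than fluent-profile speakers, who produce more than
nonfluent-profile speakers), and production noise — perseverations,
non-category intrusions, and morphological surface variants — injected at
known rates so the cleaning stage can be checked against exact ground
truth.  Participants are modelled as censored weighted random walks over
their group's (possibly degraded) lexicon network: transitions follow edge
weights with an occasional uniform jump, and each word is emitted on first
visit only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from .errors import ConfigurationError
from .estimate import SemanticNetwork
from .preprocess import (
    CleaningDictionary,
    FluencyDataset,
    FluencyRecord,
    default_animal_dictionary,
    write_fluency_file,
)

__all__ = [
    "GroundTruthLexicon",
    "GroupProfile",
    "CohortResult",
    "make_ground_truth",
    "degrade_network",
    "simulate_participant",
    "simulate_cohort",
    "default_profiles",
    "INTRUSION_VOCABULARY",
]

# Non-category items used as intrusions; none of these are animal roots or
# variants, so cleaning removes exactly the injected count.
INTRUSION_VOCABULARY = (
    "book", "chair", "table", "apple", "car", "house", "pencil",
    "shoe", "cup", "door", "tree", "cloud", "spoon", "guitar",
)


@dataclass(frozen=True)
class GroundTruthLexicon:
    """Planted weighted lexicon network with block (subcategory) structure."""

    words: tuple[str, ...]
    weights: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    blocks: tuple[int, ...]

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        n = len(self.words)
        if W.shape != (n, n) or not np.allclose(W, W.T) or np.any(np.diag(W) != 0):
            raise ValueError("weights must be symmetric with zero diagonal")
        if np.any(W < 0) or np.any(W > 1):
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "weights", W)

    @property
    def n_words(self) -> int:
        return len(self.words)

    def to_network(self) -> SemanticNetwork:
        return SemanticNetwork(self.words, self.weights)

    def planted_partition(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for w, b in zip(self.words, self.blocks):
            out.setdefault(b, set()).add(w)
        return list(out.values())


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one participant group.

    Walk lengths (the number of distinct words a participant produces) are
    drawn from a truncated normal; ``jump_prob`` is the per-step teleport
    probability of the censored random walk; ``degradation`` is the fraction
    of lexicon edges removed for this group; the three noise rates are
    per-token injection probabilities.  Demographic means/SDs feed the
    covariate-adjusted response-count comparison.
    """

    name: str
    n_participants: int = 30
    walk_mean: float = 20.0
    walk_sd: float = 5.0
    jump_prob: float = 0.05
    degradation: float = 0.0
    perseveration_rate: float = 0.05
    intrusion_rate: float = 0.03
    variant_rate: float = 0.05
    age_mean: float = 62.0
    age_sd: float = 11.0
    edu_mean: float = 16.0
    edu_sd: float = 2.3

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("cohort size must be >= 2")
        for rate in (self.jump_prob, self.degradation, self.perseveration_rate,
                     self.intrusion_rate, self.variant_rate):
            if not (0.0 <= rate <= 1.0):
                raise ConfigurationError("rates must lie in [0, 1]")
        if self.walk_mean < 1:
            raise ConfigurationError("walk_mean must be >= 1")


def default_profiles() -> dict[str, GroupProfile]:
    """Study-condition profiles for the four canonical groups.

    Cohort sizes and walk-length (appropriate-response) distributions match
    the group sizes and the reported response means/SDs of the motivating
    study population (120 controls at 22.47 +/- 4.90; 127 aphasia at
    9.63 +/- 5.25, split into 64 fluent at 11.95 +/- 5.08 and 63 nonfluent
    at 7.27 +/- 4.30), as do the demographic distributions.  Degradation,
    jump, and noise rates increase with impairment severity.
    """
    return {
        "control": GroupProfile(
            "control", n_participants=120, walk_mean=22.47, walk_sd=4.90,
            jump_prob=0.05, degradation=0.0, perseveration_rate=0.03,
            intrusion_rate=0.02, variant_rate=0.05,
            age_mean=65.57, age_sd=9.88, edu_mean=16.49, edu_sd=2.34,
        ),
        "aphasia": GroupProfile(
            "aphasia", n_participants=127, walk_mean=9.63, walk_sd=5.25,
            jump_prob=0.12, degradation=0.25, perseveration_rate=0.10,
            intrusion_rate=0.06, variant_rate=0.05,
            age_mean=59.50, age_sd=13.17, edu_mean=15.70, edu_sd=2.32,
        ),
        "fluent": GroupProfile(
            "fluent", n_participants=64, walk_mean=11.95, walk_sd=5.08,
            jump_prob=0.10, degradation=0.15, perseveration_rate=0.08,
            intrusion_rate=0.05, variant_rate=0.05,
            age_mean=59.94, age_sd=12.23, edu_mean=16.03, edu_sd=2.33,
        ),
        "nonfluent": GroupProfile(
            "nonfluent", n_participants=63, walk_mean=7.27, walk_sd=4.30,
            jump_prob=0.15, degradation=0.30, perseveration_rate=0.12,
            intrusion_rate=0.08, variant_rate=0.05,
            age_mean=59.06, age_sd=14.16, edu_mean=15.34, edu_sd=2.28,
        ),
    }


def make_ground_truth(
    n_words: int = 150,
    n_blocks: int = 6,
    w_in: float = 0.55,
    w_out: float = 0.12,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.25,
    popularity_exponent: float = 1.5,
    dictionary: CleaningDictionary | None = None,
) -> GroundTruthLexicon:
    """Block-structured weighted lexicon network over real category words.

    Word labels come from the packaged animal lexicon (sorted); blocks are
    contiguous chunks standing in for semantic subcategories.  Within-block
    edges get weight ``w_in`` and between-block edges ``w_out``, each with
    multiplicative uniform jitter of +/- ``jitter``, clipped to (0, 1].
    On top of the block structure, words carry a Zipf-like popularity
    (rank^-``popularity_exponent``, ranks randomly assigned) that scales
    edge weights multiplicatively: high-popularity words become hubs the
    random walks visit early and often, while the low-popularity tail is
    produced rarely — the idiosyncratic responses that producer filtering
    and node equating later exclude.  The graph is complete with positive
    weights, hence connected; the (defensive) connectivity check re-jitters
    on a failed draw.
    """
    if n_words < 2 * n_blocks:
        raise ConfigurationError("need n_words >= 2 * n_blocks")
    if not (0 < w_out < w_in <= 1):
        raise ConfigurationError("need 0 < w_out < w_in <= 1")
    dictionary = dictionary or default_animal_dictionary()
    roots = sorted(dictionary.category_lexicon)
    if n_words > len(roots):
        raise ConfigurationError(f"lexicon provides only {len(roots)} roots")
    words = tuple(roots[:n_words])
    sizes = [n_words // n_blocks + (1 if b < n_words % n_blocks else 0) for b in range(n_blocks)]
    blocks = tuple(b for b, size in enumerate(sizes) for _ in range(size))

    rng = np.random.default_rng(seed)
    ranks = rng.permutation(n_words) + 1
    popularity = ranks.astype(float) ** -popularity_exponent  # max = 1 at rank 1
    for _attempt in range(10):
        base = np.where(
            np.equal.outer(blocks, blocks), w_in, w_out
        ).astype(float)
        base *= np.sqrt(np.outer(popularity, popularity))
        factor = rng.uniform(1 - jitter, 1 + jitter, size=base.shape)
        W = base * np.triu(factor, 1)
        W = W + W.T
        W = np.clip(W, 0.0, 1.0)
        np.fill_diagonal(W, 0.0)
        n_comp, _ = connected_components(sp.csr_matrix(W), directed=False)
        if n_comp == 1:
            return GroundTruthLexicon(words, W, blocks)
    raise ConfigurationError("could not draw a connected lexicon network")


def degrade_network(
    lex: GroundTruthLexicon,
    degradation: float,
    seed: int | np.random.Generator = 0,
) -> GroundTruthLexicon:
    """Remove each lexicon edge independently with the given probability.

    If removal disconnects the network, the maximum-weight spanning tree of
    the *original* network is re-added, so connectivity is always preserved
    (with probability 1 the result is exactly that spanning skeleton).
    """
    if not (0.0 <= degradation <= 1.0):
        raise ConfigurationError("degradation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    W = lex.weights.copy()
    iu = np.triu_indices(lex.n_words, 1)
    drop = rng.random(len(iu[0])) < degradation
    W[iu[0][drop], iu[1][drop]] = 0.0
    W[iu[1][drop], iu[0][drop]] = 0.0

    n_comp, _ = connected_components(sp.csr_matrix(W), directed=False)
    if n_comp > 1:
        mst = minimum_spanning_tree(sp.csr_matrix(-lex.weights)).toarray()
        rows, cols = np.nonzero(mst)
        for i, j in zip(rows, cols):
            W[i, j] = W[j, i] = lex.weights[i, j]
    return GroundTruthLexicon(lex.words, W, lex.blocks)


@dataclass
class ParticipantTruth:
    true_responses: list[str]
    n_perseverations: int
    n_intrusions: int
    n_variants: int


def _walk(lex: GroundTruthLexicon, length: int, jump_prob: float, rng: np.random.Generator) -> list[int]:
    """Censored weighted random walk: emit nodes on first visit only."""
    n = lex.n_words
    length = min(length, n)
    W = lex.weights
    current = int(rng.integers(n))
    emitted = [current]
    visited = {current}
    max_steps = 500 + 200 * length
    steps = 0
    while len(emitted) < length and steps < max_steps:
        steps += 1
        row = W[current]
        total = row.sum()
        if rng.random() < jump_prob or total <= 0:
            current = int(rng.integers(n))
        else:
            current = int(rng.choice(n, p=row / total))
        if current not in visited:
            visited.add(current)
            emitted.append(current)
    return emitted


def simulate_participant(
    lex: GroundTruthLexicon,
    profile: GroupProfile,
    seed: int | np.random.Generator = 0,
    dictionary: CleaningDictionary | None = None,
    participant_id: str = "p0",
) -> tuple[FluencyRecord, ParticipantTruth]:
    """One participant's noisy production with its ground-truth bookkeeping.

    The pre-noise list is a censored weighted random walk of truncated-
    normal length; perseverations (repeats of an earlier root), intrusions
    (non-category tokens), and surface variants are then injected at the
    profile's rates.  The injected counts are returned so the cleaning log
    can be verified exactly.
    """
    rng = np.random.default_rng(seed)
    dictionary = dictionary or default_animal_dictionary()
    length = max(1, int(round(rng.normal(profile.walk_mean, profile.walk_sd))))
    idx = _walk(lex, length, profile.jump_prob, rng)
    true_roots = [lex.words[i] for i in idx]
    tokens = list(true_roots)

    # perseverations: re-insert an already-produced root strictly after its
    # first occurrence, so cleaning classifies exactly these as repeats
    n_pers = int(rng.binomial(len(true_roots), profile.perseveration_rate))
    for _ in range(n_pers):
        src = int(rng.integers(len(tokens)))
        root = tokens[src]
        while root not in true_roots:  # avoid copying an intrusion
            src = int(rng.integers(len(tokens)))
            root = tokens[src]
        first = tokens.index(root)
        pos = int(rng.integers(first + 1, len(tokens) + 1))
        tokens.insert(pos, root)

    n_intr = int(rng.binomial(len(true_roots), profile.intrusion_rate))
    for _ in range(n_intr):
        word = INTRUSION_VOCABULARY[int(rng.integers(len(INTRUSION_VOCABULARY)))]
        pos = int(rng.integers(0, len(tokens) + 1))
        tokens.insert(pos, word)

    # surface variants: replace category roots by a mapped variant form
    reverse: dict[str, list[str]] = {}
    for surface, root in dictionary.variant_map.items():
        reverse.setdefault(root, []).append(surface)
    n_var = 0
    for pos, tok in enumerate(tokens):
        options = reverse.get(tok)
        if options and rng.random() < profile.variant_rate:
            tokens[pos] = sorted(options)[int(rng.integers(len(options)))]
            n_var += 1

    record = FluencyRecord(participant_id, profile.name, tuple(tokens))
    truth = ParticipantTruth(true_roots, n_pers, n_intr, n_var)
    return record, truth


@dataclass
class CohortResult:
    dataset: FluencyDataset
    manifest: dict[str, ParticipantTruth]
    demographics: pd.DataFrame
    lexicons: dict[str, GroundTruthLexicon]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fluency_file(self.dataset, outdir / "cohort.csv")
        self.demographics.to_csv(outdir / "demographics.csv")
        payload = {pid: asdict(t) for pid, t in self.manifest.items()}
        (outdir / "manifest.json").write_text(json.dumps(payload, indent=2))


def simulate_cohort(
    profiles: list[GroupProfile],
    seed: int = 0,
    lexicons: dict[str, GroundTruthLexicon] | None = None,
    ground_truth: GroundTruthLexicon | None = None,
    dictionary: CleaningDictionary | None = None,
) -> CohortResult:
    """Simulate a multi-group cohort; a pure function of (profiles, seed).

    Each group's walks run on the shared ground-truth lexicon degraded at
    that group's rate (unless explicit per-group lexicons are supplied).
    The manifest records every participant's pre-noise list and injected
    noise counts; demographics are drawn from each profile's distributions.
    """
    if not profiles:
        raise ConfigurationError("need at least one profile")
    dictionary = dictionary or default_animal_dictionary()
    if ground_truth is None:
        ground_truth = make_ground_truth(
            seed=np.random.default_rng(np.random.SeedSequence([seed, 0xBA5E])),
            dictionary=dictionary,
        )
    if lexicons is None:
        lexicons = {}
        for pi, profile in enumerate(profiles):
            lexicons[profile.name] = degrade_network(
                ground_truth,
                profile.degradation,
                seed=np.random.default_rng(np.random.SeedSequence([seed, 1, pi])),
            )

    records: list[FluencyRecord] = []
    manifest: dict[str, ParticipantTruth] = {}
    demo_rows = []
    for pi, profile in enumerate(profiles):
        lex = lexicons[profile.name]
        demo_rng = np.random.default_rng(np.random.SeedSequence([seed, 2, pi]))
        for i in range(profile.n_participants):
            pid = f"{profile.name}_{i:03d}"
            rec, truth = simulate_participant(
                lex,
                profile,
                seed=np.random.default_rng(np.random.SeedSequence([seed, 3, pi, i])),
                dictionary=dictionary,
                participant_id=pid,
            )
            records.append(rec)
            manifest[pid] = truth
            demo_rows.append(
                {
                    "participant": pid,
                    "age": round(float(demo_rng.normal(profile.age_mean, profile.age_sd)), 1),
                    "education": int(np.clip(round(demo_rng.normal(profile.edu_mean, profile.edu_sd)), 10, 24)),
                }
            )
    demographics = pd.DataFrame(demo_rows).set_index("participant")
    return CohortResult(FluencyDataset(tuple(records)), manifest, demographics, dict(lexicons))
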