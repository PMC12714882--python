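"""Reading, cleaning, and binarization of verbal-fluency transcripts.

A fluency transcript is one ordered list of produced tokens per participant.
Cleaning standardizes morphological variants to their root form, removes
non-category intrusions, and removes perseverations (any later repetition of
an already-produced root).  Cleaned lists are binarized into a participants
x words occurrence matrix, filtered to words produced by a minimum number of
participants, and — for two-group comparisons — equated so both group
matrices share an identical node lexicon.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyDatasetError,
    EmptyMatrixError,
    EmptySharedLexiconError,
    SingularDesignError,
)

__all__ = [
    "FluencyRecord",
    "FluencyDataset",
    "CleaningDictionary",
    "CleaningLog",
    "ResponseMatrix",
    "ColumnDialect",
    "read_fluency_file",
    "write_fluency_file",
    "clean_responses",
    "build_response_matrix",
    "filter_min_producers",
    "equate_nodes",
    "EquateReport",
    "count_appropriate_responses",
    "compare_counts_adjusted",
    "CountComparison",
    "default_animal_dictionary",
]


# ---------------------------------------------------------------------------
# Core containers


@dataclass(frozen=True)
class FluencyRecord:
    """One participant's ordered fluency production."""

    participant_id: str
    group: str
    responses: tuple[str, ...]

    def __post_init__(self) -> None:
        cleaned = tuple(tok.strip() for tok in self.responses)
        if any(not tok for tok in cleaned):
            raise ValueError(
                f"participant {self.participant_id!r}: empty token in responses"
            )
        object.__setattr__(self, "responses", cleaned)


@dataclass(frozen=True)
class FluencyDataset:
    """A cohort of fluency records, possibly spanning several groups."""

    records: tuple[FluencyRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FluencyRecord]:
        return iter(self.records)

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.group)
        return tuple(seen)

    def for_group(self, group: str) -> "FluencyDataset":
        return FluencyDataset(tuple(r for r in self.records if r.group == group))

    def to_frame(self, response_sep: str = ";") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": [r.participant_id for r in self.records],
                "group": [r.group for r in self.records],
                "responses": [response_sep.join(r.responses) for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# Cleaning dictionary


@dataclass(frozen=True)
class CleaningDictionary:
    """Category lexicon plus a surface-form -> root variant map.

    ``category_lexicon`` holds the accepted root words; ``variant_map`` sends
    inflections and common misspellings to their root.  Every variant target
    must itself be an accepted root, and each surface form maps to exactly
    one root, so cleaning is deterministic.
    """

    category_lexicon: frozenset[str]
    variant_map: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {r for r in self.variant_map.values() if r not in self.category_lexicon}
        if bad:
            raise ValueError(f"variant_map targets outside the lexicon: {sorted(bad)[:5]}")

    def root_of(self, token: str) -> str | None:
        """Root form of ``token``, or None if it is not a category item."""
        tok = token.strip().casefold()
        if tok in self.variant_map:
            return self.variant_map[tok]
        if tok in self.category_lexicon:
            return tok
        return None

    @classmethod
    def from_files(cls, lexicon_path: Path, variants_path: Path | None = None) -> "CleaningDictionary":
        words = frozenset(
            line.strip().casefold()
            for line in Path(lexicon_path).read_text().splitlines()
            if line.strip()
        )
        variants: dict[str, str] = {}
        if variants_path is not None:
            with open(variants_path, newline="") as fh:
                for row in csv.DictReader(fh):
                    variants[row["surface"].strip().casefold()] = row["root"].strip().casefold()
        return cls(words, variants)


def default_animal_dictionary() -> CleaningDictionary:
    """The packaged animal-category lexicon and variant map.

    A general-purpose list of common English animal names with plural forms
    and frequent misspellings.  It is a replaceable default, not a normative
    scoring standard: pass a custom :class:`CleaningDictionary` to use a
    different category or scoring convention.
    """
    data = resources.files("fluencynet.data")
    words = frozenset(
        line.strip().casefold()
        for line in (data / "animal_lexicon.txt").read_text().splitlines()
        if line.strip()
    )
    variants: dict[str, str] = {}
    for row in csv.DictReader((data / "animal_variants.csv").read_text().splitlines()):
        variants[row["surface"]] = row["root"]
    return CleaningDictionary(words, variants)


# ---------------------------------------------------------------------------
# File IO


@dataclass(frozen=True)
class ColumnDialect:
    """Column mapping for delimited fluency files.

    ``layout`` is ``"wide"`` (one row per participant, responses joined in a
    single field by ``response_sep``) or ``"long"`` (one row per token, in
    production order, with the token in column ``token``).
    """

    participant: str = "participant"
    group: str = "group"
    responses: str = "responses"
    token: str = "token"
    response_sep: str | None = ";"
    layout: str = "wide"
    delimiter: str = ","


DEFAULT_DIALECT = ColumnDialect()


def read_fluency_file(path: str | Path, dialect: ColumnDialect = DEFAULT_DIALECT) -> FluencyDataset:
    """Parse a delimited fluency transcript into a :class:`FluencyDataset`.

    Tokens are case-folded and whitespace-trimmed; production order is
    preserved.  Raises :class:`ConfigurationError` on missing columns and
    :class:`EmptyDatasetError` when the file has no data rows.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError(f"{path}: no rows") from exc

    if dialect.layout == "wide":
        needed = [dialect.participant, dialect.group, dialect.responses]
    elif dialect.layout == "long":
        needed = [dialect.participant, dialect.group, dialect.token]
    else:
        raise ConfigurationError(f"unknown layout {dialect.layout!r}")
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing columns {missing}")
    if frame.empty:
        raise EmptyDatasetError(f"{path}: header only, no participants")

    records: list[FluencyRecord] = []
    if dialect.layout == "wide":
        for _, row in frame.iterrows():
            raw = row[dialect.responses]
            if dialect.response_sep is None:
                tokens = raw.split()
            else:
                tokens = raw.split(dialect.response_sep)
            tokens = [t.strip().casefold() for t in tokens if t.strip()]
            records.append(
                FluencyRecord(row[dialect.participant].strip(), row[dialect.group].strip(), tuple(tokens))
            )
    else:
        # long layout: group consecutive rows by participant, keep file order
        order: dict[str, tuple[str, list[str]]] = {}
        for _, row in frame.iterrows():
            pid = row[dialect.participant].strip()
            tok = row[dialect.token].strip().casefold()
            entry = order.setdefault(pid, (row[dialect.group].strip(), []))
            if tok:
                entry[1].append(tok)
        for pid, (group, tokens) in order.items():
            records.append(FluencyRecord(pid, group, tuple(tokens)))
    return FluencyDataset(tuple(records))


def write_fluency_file(
    dataset: FluencyDataset, path: str | Path, dialect: ColumnDialect = DEFAULT_DIALECT
) -> None:
    """Write a dataset in the wide dialect so it round-trips through
    :func:`read_fluency_file`."""
    if dialect.layout != "wide":
        raise ConfigurationError("writing is supported for the wide layout only")
    sep = dialect.response_sep or " "
    frame = dataset.to_frame(response_sep=sep)
    frame.columns = [dialect.participant, dialect.group, dialect.responses]
    frame.to_csv(path, sep=dialect.delimiter, index=False)


# ---------------------------------------------------------------------------
# Cleaning


@dataclass
class ParticipantCleaning:
    raw: int = 0
    retained: int = 0
    variants_standardized: int = 0
    perseverations_removed: int = 0
    noncategory_removed: int = 0


@dataclass
class CleaningLog:
    """Per-participant accounting of every cleaning decision.

    Invariant: ``raw == retained + perseverations_removed +
    noncategory_removed`` for every participant (variant standardization
    changes a token's form, not its fate).
    """

    per_participant: dict[str, ParticipantCleaning] = field(default_factory=dict)
    removed_tokens: list[tuple[str, str, str]] = field(default_factory=list)

    def totals(self) -> ParticipantCleaning:
        tot = ParticipantCleaning()
        for entry in self.per_participant.values():
            tot.raw += entry.raw
            tot.retained += entry.retained
            tot.variants_standardized += entry.variants_standardized
            tot.perseverations_removed += entry.perseverations_removed
            tot.noncategory_removed += entry.noncategory_removed
        return tot

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_participant": {pid: asdict(e) for pid, e in self.per_participant.items()},
            "removed_tokens": [
                {"participant": p, "token": t, "reason": r} for p, t, r in self.removed_tokens
            ],
            "totals": asdict(self.totals()),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def clean_responses(
    dataset: FluencyDataset, dictionary: CleaningDictionary
) -> tuple[FluencyDataset, CleaningLog]:
    """Standardize variants, drop intrusions, drop perseverations.

    Variants are mapped to roots *before* perseveration detection, so a
    plural repeat of an earlier singular counts as a perseveration.  A
    perseveration is any later occurrence of an already-retained root,
    adjacent or not.  Cleaning is idempotent.
    """
    log = CleaningLog()
    cleaned_records: list[FluencyRecord] = []
    for rec in dataset:
        entry = ParticipantCleaning(raw=len(rec.responses))
        seen: set[str] = set()
        kept: list[str] = []
        for token in rec.responses:
            tok = token.strip().casefold()
            root = dictionary.root_of(tok)
            if root is None:
                entry.noncategory_removed += 1
                log.removed_tokens.append((rec.participant_id, tok, "non-category"))
                continue
            if root != tok:
                entry.variants_standardized += 1
            if root in seen:
                entry.perseverations_removed += 1
                log.removed_tokens.append((rec.participant_id, tok, "perseveration"))
                continue
            seen.add(root)
            kept.append(root)
        entry.retained = len(kept)
        log.per_participant[rec.participant_id] = entry
        cleaned_records.append(FluencyRecord(rec.participant_id, rec.group, tuple(kept)))
    return FluencyDataset(tuple(cleaned_records)), log


# ---------------------------------------------------------------------------
# Response matrix


@dataclass(frozen=True)
class ResponseMatrix:
    """Binary participants x words occurrence matrix for one group.

    Words are unique roots, sorted lexicographically (case-folded) for
    determinism; a cell is 1 iff the participant produced the word at least
    once.
    """

    participant_ids: tuple[str, ...]
    words: tuple[str, ...]
    values: np.ndarray  # shape (n_participants, n_words), dtype int8
    group: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.int8)
        if vals.shape != (len(self.participant_ids), len(self.words)):
            raise ValueError("matrix shape does not match labels")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("cells must be binary")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def producer_counts(self) -> np.ndarray:
        """Number of participants producing each word (column sums)."""
        return self.values.sum(axis=0)

    def restrict_words(self, words: Sequence[str]) -> "ResponseMatrix":
        index = {w: i for i, w in enumerate(self.words)}
        missing = [w for w in words if w not in index]
        if missing:
            raise KeyError(f"words not in matrix: {missing[:5]}")
        cols = [index[w] for w in words]
        return ResponseMatrix(
            self.participant_ids, tuple(words), self.values[:, cols], self.group
        )

    def resample_participants(self, rows: Sequence[int]) -> "ResponseMatrix":
        rows = list(rows)
        pids = tuple(f"{self.participant_ids[i]}#{k}" for k, i in enumerate(rows))
        return ResponseMatrix(pids, self.words, self.values[rows, :], self.group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.participant_ids), columns=list(self.words))

    def write_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "participant"
        frame.insert(0, "group", self.group or "")
        frame.to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ResponseMatrix":
        frame = pd.read_csv(path, index_col="participant")
        group_col = frame.pop("group")
        groups = set(group_col.astype(str))
        group = groups.pop() if len(groups) == 1 else None
        return cls(
            tuple(str(i) for i in frame.index),
            tuple(frame.columns),
            frame.to_numpy(dtype=np.int8),
            group or None,
        )


def build_response_matrix(dataset: FluencyDataset) -> ResponseMatrix:
    """Binarize a cleaned single-group dataset.

    Repeated production of a word does not change the cell (cells are
    occurrence indicators).  Duplicate participant identifiers are an input
    error; word columns exist only for words somebody produced.
    """
    pids = [r.participant_id for r in dataset]
    dupes = [p for p, k in Counter(pids).items() if k > 1]
    if dupes:
        raise ConfigurationError(f"duplicate participant ids: {dupes[:5]}")
    groups = set(r.group for r in dataset)
    group = groups.pop() if len(groups) == 1 else None

    words = sorted({w for rec in dataset for w in rec.responses})
    index = {w: i for i, w in enumerate(words)}
    values = np.zeros((len(pids), len(words)), dtype=np.int8)
    for row, rec in enumerate(dataset):
        for w in rec.responses:
            values[row, index[w]] = 1
    return ResponseMatrix(tuple(pids), tuple(words), values, group)


def filter_min_producers(matrix: ResponseMatrix, min_producers: int = 2) -> ResponseMatrix:
    """Drop word columns produced by fewer than ``min_producers`` participants."""
    if min_producers < 1:
        raise ConfigurationError("min_producers must be >= 1")
    keep = matrix.producer_counts() >= min_producers
    if not keep.any():
        raise EmptyMatrixError(
            f"no word produced by >= {min_producers} participants"
        )
    words = tuple(w for w, k in zip(matrix.words, keep) if k)
    return ResponseMatrix(matrix.participant_ids, words, matrix.values[:, keep], matrix.group)


@dataclass(frozen=True)
class EquateReport:
    shared_words: tuple[str, ...]
    excluded_a: tuple[str, ...]
    excluded_b: tuple[str, ...]

    @property
    def n_shared(self) -> int:
        return len(self.shared_words)


def equate_nodes(
    a: ResponseMatrix, b: ResponseMatrix
) -> tuple[ResponseMatrix, ResponseMatrix, EquateReport]:
    """Restrict both matrices to their shared (intersection) lexicon.

    Words present in only one group are idiosyncratic and excluded; the
    shared set is sorted lexicographically, so the result is independent of
    argument order up to swapping the report's exclusion lists.
    """
    shared = sorted(set(a.words) & set(b.words))
    if not shared:
        raise EmptySharedLexiconError("groups share no words after filtering")
    report = EquateReport(
        tuple(shared),
        tuple(w for w in a.words if w not in set(shared)),
        tuple(w for w in b.words if w not in set(shared)),
    )
    return a.restrict_words(shared), b.restrict_words(shared), report


# ---------------------------------------------------------------------------
# Response counts


def count_appropriate_responses(dataset: FluencyDataset) -> pd.Series:
    """Retained (appropriate) token count per participant of a cleaned dataset."""
    return pd.Series(
        {r.participant_id: len(r.responses) for r in dataset}, name="appropriate_responses"
    )


@dataclass(frozen=True)
class CountComparison:
    """OLS group contrast on appropriate-response counts."""

    reference: str
    contrast: str
    beta: float
    se: float
    t: float
    df: int
    p: float
    n_used: int
    n_dropped: int
    covariates: tuple[str, ...]


def compare_counts_adjusted(
    counts: pd.Series,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference: str | None = None,
) -> CountComparison:
    """Covariate-adjusted two-group comparison of response counts.

    Fits ``count ~ 1 + group + covariates`` by OLS; the reported coefficient
    is the adjusted mean difference of the contrast group relative to
    ``reference`` (lexicographically earlier group when not given).  Rows
    with missing covariates are dropped listwise and counted in
    ``n_dropped``.
    """
    import statsmodels.api as sm

    data = pd.DataFrame({"count": counts, "group": groups.reindex(counts.index)})
    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        cov = covariates.reindex(counts.index)
        cov_names = tuple(cov.columns)
        data = pd.concat([data, cov], axis=1)
    n_total = len(data)
    data = data.dropna()
    n_dropped = n_total - len(data)

    levels = sorted(data["group"].unique())
    if len(levels) != 2:
        raise ConfigurationError(f"exactly two groups required, got {levels}")
    if reference is not None:
        if reference not in levels:
            raise ConfigurationError(f"reference {reference!r} not among {levels}")
        levels = [reference] + [g for g in levels if g != reference]
    reference, contrast = levels
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X[f"group[{contrast}]"] = (data["group"] == contrast).astype(float)
    for name in cov_names:
        X[name] = pd.to_numeric(data[name])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")

    fit = sm.OLS(pd.to_numeric(data["count"]), X).fit()
    key = f"group[{contrast}]"
    return CountComparison(
        reference=reference,
        contrast=contrast,
        beta=float(fit.params[key]),
        se=float(fit.bse[key]),
        t=float(fit.tvalues[key]),
        df=int(fit.df_resid),
        p=float(fit.pvalues[key]),
        n_used=len(data),
        n_dropped=n_dropped,
        covariates=cov_names,
    )
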