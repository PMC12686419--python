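"""Study data model: cases, ranked differentials and the correctness cube.

A paired multi-condition diagnostic-accuracy study presents every case to
every condition (a rater, or a model under a given input modality).  Each
condition returns a ranked differential-diagnosis list; a case is *correct at
rank k* when the gold (histopathological) diagnosis appears among the first k
entries.  The central in-memory object is the :class:`CorrectnessCube`, a
binary array indexed (case, condition, threshold) from which every downstream
accuracy, gain metric and paired test is computed.

Correctness is adjudicated by deterministic exact matching of normalized
labels, optionally through a user-supplied synonym map; pre-adjudicated
binary correctness can also be loaded directly (see :mod:`vbdg.io`).
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateRecordError,
    IncompleteDesignError,
    InvalidLabelError,
    InvalidThresholdError,
    ReferentialError,
    UnknownKeyError,
    ValidationError,
)

__all__ = [
    "LESION_TYPES",
    "DIFFICULTY_LEVELS",
    "DEFAULT_THRESHOLDS",
    "CaseRecord",
    "RankedDifferential",
    "CorrectnessCube",
    "Accuracy",
    "normalize_label",
    "normalize_synonym_map",
    "score_case",
    "build_correctness_cube",
]

#: Closed vocabulary for the lesion-type stratum (WHO head-and-neck grouping).
LESION_TYPES = ("malignant", "benign", "reactive", "inflammatory")

#: Closed vocabulary for the diagnostic-difficulty stratum.
DIFFICULTY_LEVELS = ("low", "moderate", "high")

#: Rank thresholds reported by default: Top-1, Top-3 and Top-5 accuracy.
DEFAULT_THRESHOLDS = (1, 3, 5)

_PUNCT_RE = re.compile(r"[^\w\s]+", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_label(raw: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Canonicalize a free-text diagnosis label.

    Lowercases, strips punctuation, collapses whitespace, then (optionally)
    resolves the label through a synonym map until a fixed point is reached.
    The function is idempotent: ``normalize_label(normalize_label(x)) ==
    normalize_label(x)`` for any input, including chained synonym maps.

    Parameters
    ----------
    raw
        Free-text diagnosis, e.g. ``"Pyogenic  Granuloma."``.
    synonyms
        Optional mapping of normalized label -> preferred normalized label
        (see :func:`normalize_synonym_map`).  Applied after normalization.

    Raises
    ------
    InvalidLabelError
        If the input is empty or whitespace-only.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise InvalidLabelError(f"empty or blank diagnosis label: {raw!r}")
    label = _WS_RE.sub(" ", _PUNCT_RE.sub(" ", raw.lower())).strip()
    if not label:
        raise InvalidLabelError(f"label reduces to nothing after normalization: {raw!r}")
    if synonyms:
        seen = {label}
        while label in synonyms:
            label = _WS_RE.sub(" ", _PUNCT_RE.sub(" ", synonyms[label].lower())).strip()
            if label in seen:  # cycle guard: stop at first repeat
                break
            seen.add(label)
    return label


def normalize_synonym_map(raw_map: Mapping[str, str]) -> dict[str, str]:
    """Normalize both sides of a synonym map so lookups are canonical."""
    return {
        normalize_label(k): normalize_label(v) for k, v in raw_map.items()
    }


@dataclass(frozen=True)
class CaseRecord:
    """One study case: gold diagnosis plus its stratum labels."""

    case_id: str
    gold_diagnosis: str
    lesion_type: str
    difficulty: str

    def __post_init__(self) -> None:
        if self.lesion_type not in LESION_TYPES:
            raise ValidationError(
                f"case {self.case_id!r}: lesion_type {self.lesion_type!r} "
                f"not in {LESION_TYPES}"
            )
        if self.difficulty not in DIFFICULTY_LEVELS:
            raise ValidationError(
                f"case {self.case_id!r}: difficulty {self.difficulty!r} "
                f"not in {DIFFICULTY_LEVELS}"
            )


@dataclass(frozen=True)
class RankedDifferential:
    """An ordered candidate-diagnosis list from one condition for one case.

    ``ranks`` holds at most five labels (the study prompt asks for the five
    most likely diagnoses ranked by probability); duplicates after
    normalization are rejected because a ranked list cannot name the same
    diagnosis twice.
    """

    case_id: str
    condition_id: str
    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", tuple(self.ranks))
        if len(self.ranks) > 5:
            raise ValidationError(
                f"({self.case_id}, {self.condition_id}): ranked list has "
                f"{len(self.ranks)} entries; at most 5 allowed"
            )
        normed = [normalize_label(r) for r in self.ranks]
        if len(set(normed)) != len(normed):
            raise ValidationError(
                f"({self.case_id}, {self.condition_id}): duplicate diagnoses "
                f"after normalization: {normed}"
            )


def score_case(
    ranks: RankedDifferential | Sequence[str],
    gold: str,
    k: int,
    synonyms: Mapping[str, str] | None = None,
) -> int:
    """Binary Top-k correctness of one ranked list against the gold diagnosis.

    Returns 1 iff the normalized gold label appears among the first
    ``min(k, len(ranks))`` normalized entries, else 0.  Matching is exact on
    normalized labels (case-, punctuation- and whitespace-insensitive), with
    the synonym map applied to both sides.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise InvalidThresholdError(f"rank threshold must be a positive integer, got {k!r}")
    entries = ranks.ranks if isinstance(ranks, RankedDifferential) else tuple(ranks)
    gold_n = normalize_label(gold, synonyms)
    top = [normalize_label(r, synonyms) for r in entries[: int(k)]]
    return int(gold_n in top)


class Accuracy(tuple):
    """``(count, n, proportion)`` triple; proportion is ``count / n``."""

    __slots__ = ()

    def __new__(cls, count: int, n: int):
        if n < 1:
            raise ValidationError("accuracy denominator must be >= 1")
        return super().__new__(cls, (int(count), int(n), count / n))

    @property
    def count(self) -> int:
        return self[0]

    @property
    def n(self) -> int:
        return self[1]

    @property
    def proportion(self) -> float:
        return self[2]


@dataclass(frozen=True)
class CorrectnessCube:
    """Binary correctness array indexed (case, condition, rank threshold).

    Invariants enforced at construction:

    * entries are 0/1;
    * thresholds strictly increasing positive integers;
    * per (case, condition), correctness is monotone non-decreasing in the
      threshold (correct at Top-k implies correct at every larger k);
    * case and condition ids are unique.
    """

    values: np.ndarray
    case_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 3:
            raise ValidationError(f"cube must be 3-d, got shape {vals.shape}")
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("cube entries must be 0 or 1")
        vals = vals.astype(np.uint8)
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "case_ids", tuple(str(c) for c in self.case_ids))
        object.__setattr__(self, "condition_ids", tuple(str(c) for c in self.condition_ids))
        object.__setattr__(self, "thresholds", tuple(int(t) for t in self.thresholds))
        if vals.shape != (len(self.case_ids), len(self.condition_ids), len(self.thresholds)):
            raise ValidationError(
                f"cube shape {vals.shape} does not match index sizes "
                f"({len(self.case_ids)}, {len(self.condition_ids)}, {len(self.thresholds)})"
            )
        if len(set(self.case_ids)) != len(self.case_ids):
            raise ValidationError("duplicate case ids")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValidationError("duplicate condition ids")
        if any(t < 1 for t in self.thresholds):
            raise InvalidThresholdError(f"thresholds must be >= 1: {self.thresholds}")
        if any(a >= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValidationError(f"thresholds must be strictly increasing: {self.thresholds}")
        if (np.diff(vals.astype(np.int8), axis=2) < 0).any():
            raise ValidationError(
                "threshold monotonicity violated: a case correct at Top-k "
                "must stay correct at every larger k"
            )

    # -- lookups ---------------------------------------------------------

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    def condition_index(self, condition_id: str) -> int:
        try:
            return self.condition_ids.index(str(condition_id))
        except ValueError:
            raise UnknownKeyError(
                f"unknown condition {condition_id!r}; have {self.condition_ids}"
            ) from None

    def threshold_index(self, k: int) -> int:
        try:
            return self.thresholds.index(int(k))
        except ValueError:
            raise UnknownKeyError(
                f"unknown threshold {k!r}; have {self.thresholds}"
            ) from None

    def slice(self, condition_id: str, k: int) -> np.ndarray:
        """Binary correctness vector (one entry per case) for one condition/threshold."""
        return self.values[:, self.condition_index(condition_id), self.threshold_index(k)]

    def accuracy(self, condition_id: str, k: int) -> Accuracy:
        """Top-k accuracy of one condition as a (count, n, proportion) triple."""
        col = self.slice(condition_id, k)
        return Accuracy(int(col.sum()), self.n_cases)

    def paired_counts(self, image_condition: str, text_condition: str, k: int) -> tuple[int, int, int, int]:
        """Matched-pair 2x2 counts ``(n11, n10, n01, n00)`` at threshold k.

        ``n10`` counts cases correct under ``image_condition`` only (symbol
        b); ``n01`` cases correct under ``text_condition`` only (symbol c).
        """
        x = self.slice(image_condition, k).astype(int)
        y = self.slice(text_condition, k).astype(int)
        n11 = int(((x == 1) & (y == 1)).sum())
        n10 = int(((x == 1) & (y == 0)).sum())
        n01 = int(((x == 0) & (y == 1)).sum())
        n00 = int(((x == 0) & (y == 0)).sum())
        return n11, n10, n01, n00

    def subset(self, case_ids: Iterable[str]) -> "CorrectnessCube":
        """Sub-cube restricted to the given cases (order preserved as given)."""
        wanted = [str(c) for c in case_ids]
        pos = {c: i for i, c in enumerate(self.case_ids)}
        missing = [c for c in wanted if c not in pos]
        if missing:
            raise UnknownKeyError(f"unknown case ids: {missing[:10]}")
        idx = np.array([pos[c] for c in wanted], dtype=int)
        return CorrectnessCube(
            self.values[idx], tuple(wanted), self.condition_ids, self.thresholds
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (case, condition, threshold)."""
        n_c, n_q, n_k = self.values.shape
        return pd.DataFrame(
            {
                "case_id": np.repeat(self.case_ids, n_q * n_k),
                "condition_id": np.tile(np.repeat(self.condition_ids, n_k), n_c),
                "k": np.tile(self.thresholds, n_c * n_q),
                "correct": self.values.reshape(-1),
            }
        )


def build_correctness_cube(
    cases: Iterable[CaseRecord],
    differentials: Iterable[RankedDifferential],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    synonyms: Mapping[str, str] | None = None,
) -> CorrectnessCube:
    """Score ranked differentials against the gold standard into a cube.

    The matched design must be complete: every case must have exactly one
    ranked list per condition.  Missing pairs are an error (listing the
    offenders), never imputed, because every paired test downstream assumes
    complete matched data.

    Raises
    ------
    DuplicateRecordError
        The same (case, condition) appears twice.
    ReferentialError
        A differential references an unknown case id.
    IncompleteDesignError
        Some (case, condition) combinations are missing.
    """
    case_list = list(cases)
    ids = [c.case_id for c in case_list]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateRecordError(f"duplicate case ids in cohort: {dupes[:10]}")
    gold = {c.case_id: c.gold_diagnosis for c in case_list}

    diff_list = list(differentials)
    seen: dict[tuple[str, str], RankedDifferential] = {}
    conditions: list[str] = []
    for d in diff_list:
        if d.case_id not in gold:
            raise ReferentialError(
                f"differential references unknown case id {d.case_id!r}"
            )
        key = (d.case_id, d.condition_id)
        if key in seen:
            raise DuplicateRecordError(f"duplicate (case, condition) record: {key}")
        seen[key] = d
        if d.condition_id not in conditions:
            conditions.append(d.condition_id)

    missing = [
        (cid, q) for cid in gold for q in conditions if (cid, q) not in seen
    ]
    if missing:
        raise IncompleteDesignError(
            f"incomplete matched design: {len(missing)} missing "
            f"(case, condition) pairs, e.g. {missing[:10]}"
        )

    ks = tuple(int(t) for t in thresholds)
    values = np.zeros((len(case_list), len(conditions), len(ks)), dtype=np.uint8)
    for i, c in enumerate(case_list):
        for j, q in enumerate(conditions):
            d = seen[(c.case_id, q)]
            for m, k in enumerate(ks):
                values[i, j, m] = score_case(d, gold[c.case_id], k, synonyms)
    return CorrectnessCube(values, tuple(gold), tuple(conditions), ks)
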