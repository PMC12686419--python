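"""Delimited-text readers and writers for the long study formats.

Three row schemas (comma- or tab-separated UTF-8 with a header row):

* rankings:     ``case_id, condition_id, rank, diagnosis``  (rank 1-5)
* correctness:  ``case_id, condition_id, k, correct``       (correct 0/1)
* metadata:     ``case_id, gold_diagnosis, lesion_type, difficulty``

plus a two-column synonym map ``label, preferred``.  Readers validate hard
and report the offending line numbers; they reject rather than coerce.
Writers round-trip exactly through the readers.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    DIFFICULTY_LEVELS,
    LESION_TYPES,
    CaseRecord,
    CorrectnessCube,
    RankedDifferential,
    normalize_synonym_map,
)
from .exceptions import (
    DuplicateRecordError,
    IncompleteDesignError,
    ValidationError,
)

__all__ = [
    "read_metadata",
    "read_rankings",
    "read_correctness",
    "read_synonyms",
    "cube_from_correctness",
    "write_cohort",
]

# Unicode signs as printed in clinical tables, normalized on input.
_SIGN_MAP = str.maketrans({"−": "-", "×": "x", "–": "-"})


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: header is missing required columns {missing}; "
            f"found {list(df.columns)}"
        )
    for col in df.columns:
        df[col] = df[col].str.strip().str.translate(_SIGN_MAP)
    return df


def _line(i: int) -> int:
    """Data-frame row index -> 1-based file line number (header is line 1)."""
    return i + 2


def read_metadata(path: str | Path) -> list[CaseRecord]:
    """Read per-case metadata; enum labels are validated with line numbers."""
    df = _read_table(path, ("case_id", "gold_diagnosis", "lesion_type", "difficulty"))
    records: list[CaseRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        if not row["case_id"]:
            raise ValidationError(f"{path}: line {_line(i)}: empty case_id")
        if row["case_id"] in seen:
            raise DuplicateRecordError(
                f"{path}: line {_line(i)}: duplicate case_id {row['case_id']!r}"
            )
        seen.add(row["case_id"])
        if row["lesion_type"] not in LESION_TYPES:
            raise ValidationError(
                f"{path}: line {_line(i)}: lesion_type {row['lesion_type']!r} "
                f"not in {LESION_TYPES}"
            )
        if row["difficulty"] not in DIFFICULTY_LEVELS:
            raise ValidationError(
                f"{path}: line {_line(i)}: difficulty {row['difficulty']!r} "
                f"not in {DIFFICULTY_LEVELS}"
            )
        records.append(
            CaseRecord(row["case_id"], row["gold_diagnosis"],
                       row["lesion_type"], row["difficulty"])
        )
    return records


def read_rankings(path: str | Path) -> list[RankedDifferential]:
    """Read ranked differential lists from long format.

    Ranks within each (case, condition) must be the consecutive integers
    1..m with m <= 5.
    """
    df = _read_table(path, ("case_id", "condition_id", "rank", "diagnosis"))
    for i, raw in df["rank"].items():
        if not raw.isdigit() or not (1 <= int(raw) <= 5):
            raise ValidationError(
                f"{path}: line {_line(i)}: rank must be an integer 1-5, got {raw!r}"
            )
    df["rank"] = df["rank"].astype(int)
    out: list[RankedDifferential] = []
    for (case_id, cond), grp in df.groupby(["case_id", "condition_id"], sort=False):
        ranks = sorted(grp["rank"])
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError(
                f"{path}: ({case_id}, {cond}): ranks must be consecutive from 1, "
                f"got {ranks}"
            )
        ordered = grp.sort_values("rank")["diagnosis"].tolist()
        out.append(RankedDifferential(str(case_id), str(cond), tuple(ordered)))
    return out


def read_correctness(path: str | Path) -> pd.DataFrame:
    """Read pre-adjudicated binary correctness rows (case, condition, k, correct)."""
    df = _read_table(path, ("case_id", "condition_id", "k", "correct"))
    for i, row in df.iterrows():
        if not row["k"].isdigit() or int(row["k"]) < 1:
            raise ValidationError(
                f"{path}: line {_line(i)}: k must be a positive integer, got {row['k']!r}"
            )
        if row["correct"] not in ("0", "1"):
            raise ValidationError(
                f"{path}: line {_line(i)}: correct must be 0 or 1, got {row['correct']!r}"
            )
    df["k"] = df["k"].astype(int)
    df["correct"] = df["correct"].astype(int)
    return df


def read_synonyms(path: str | Path) -> dict[str, str]:
    """Read a two-column synonym map (label, preferred); keys normalized."""
    df = _read_table(path, ("label", "preferred"))
    return normalize_synonym_map(dict(zip(df["label"], df["preferred"])))


def cube_from_correctness(frame: pd.DataFrame) -> CorrectnessCube:
    """Assemble a cube from pre-adjudicated correctness rows.

    The design must be complete: every (case, condition, k) combination
    exactly once.  Threshold monotonicity is enforced by the cube itself.
    """
    required = ("case_id", "condition_id", "k", "correct")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"correctness frame missing columns {missing}")
    dup = frame.duplicated(subset=["case_id", "condition_id", "k"])
    if dup.any():
        offenders = frame.loc[dup, ["case_id", "condition_id", "k"]].values.tolist()
        raise DuplicateRecordError(
            f"duplicate (case, condition, k) rows: {offenders[:10]}"
        )
    cases = list(pd.unique(frame["case_id"]))
    conds = list(pd.unique(frame["condition_id"]))
    ks = sorted(int(k) for k in pd.unique(frame["k"]))
    expected = len(cases) * len(conds) * len(ks)
    if len(frame) != expected:
        have = set(zip(frame["case_id"], frame["condition_id"], frame["k"]))
        want = [(c, q, k) for c in cases for q in conds for k in ks]
        missing_cells = [cell for cell in want if cell not in have]
        raise IncompleteDesignError(
            f"incomplete design: {len(missing_cells)} missing "
            f"(case, condition, k) cells, e.g. {missing_cells[:10]}"
        )
    pivot = frame.set_index(["case_id", "condition_id", "k"])["correct"]
    values = np.zeros((len(cases), len(conds), len(ks)), dtype=np.uint8)
    for i, c in enumerate(cases):
        for j, q in enumerate(conds):
            for m, k in enumerate(ks):
                values[i, j, m] = int(pivot.loc[(c, q, k)])
    return CorrectnessCube(values, tuple(map(str, cases)), tuple(map(str, conds)),
                           tuple(ks))


def write_cohort(
    cube: CorrectnessCube,
    metadata: pd.DataFrame,
    correctness_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write a cohort as the two long-format CSV files the readers accept."""
    cube.to_frame().to_csv(correctness_path, index=False,
                           quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    cols = ["case_id", "gold_diagnosis", "lesion_type", "difficulty"]
    metadata[cols].to_csv(metadata_path, index=False,
                          quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
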