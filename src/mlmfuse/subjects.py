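"""Subject table reading.

The study table is a delimited text file (comma or tab, auto-detected from
the header line) with one row per subject.  Mandatory columns are
``subject_id`` and ``group``; ``age``, ``sex`` and ``tiv`` are covariates and
any further column is interpreted as a per-modality file path.  Exactly two
group levels are expected before model fitting — the design codes a two-group
contrast.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SubjectRecord", "read_subject_table", "subjects_to_frame"]

_KNOWN_COLUMNS = ("subject_id", "group", "age", "sex", "tiv")


@dataclass
class SubjectRecord:
    """One study participant: diagnosis group, covariates and file paths."""

    subject_id: str
    group: str
    age: float | None = None
    sex: str | None = None
    tiv: float | None = None
    modality_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age is not None and not self.age > 0:
            raise ValueError(f"subject {self.subject_id}: age must be > 0")
        if self.tiv is not None and not self.tiv > 0:
            raise ValueError(f"subject {self.subject_id}: tiv must be > 0")

    @property
    def missing_covariates(self) -> list[str]:
        return [name for name in ("age", "sex", "tiv") if getattr(self, name) is None]


def _detect_sep(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def _parse_float(raw, column: str, row: int) -> float | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s.lower() in ("na", "nan", "none"):
        return None
    try:
        return float(s)
    except ValueError:
        raise ValueError(
            f"unparseable numeric value {raw!r} in column {column!r} at data row {row}"
        ) from None


def read_subject_table(path, dialect: str | None = None) -> list[SubjectRecord]:
    """Read a subject table from CSV/TSV into :class:`SubjectRecord` objects.

    Parameters
    ----------
    path
        File path of the delimited table (header row required).
    dialect
        Explicit delimiter; by default comma vs tab is auto-detected from the
        first line.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() == "":
        raise ValueError(f"no records in subject table {path}")
    sep = dialect or _detect_sep(text.splitlines()[0])
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"no records in subject table {path}")
    missing = [c for c in ("subject_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"subject table is missing mandatory column(s): {missing}")

    ids = df["subject_id"].astype(str)
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate subject_id in table: {dup}")
    levels = df["group"].astype(str).unique().tolist()
    if len(levels) > 2:
        raise ValueError(
            f"more than two group levels in table: {sorted(levels)} "
            "(exactly two diagnostic groups are supported)"
        )

    path_columns = [c for c in df.columns if c not in _KNOWN_COLUMNS]
    records: list[SubjectRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        sex = row_d.get("sex")
        sex = None if sex is None or str(sex).strip().lower() in ("", "nan", "na") else str(sex).strip()
        records.append(
            SubjectRecord(
                subject_id=str(row_d["subject_id"]).strip(),
                group=str(row_d["group"]).strip(),
                age=_parse_float(row_d.get("age"), "age", i),
                sex=sex,
                tiv=_parse_float(row_d.get("tiv"), "tiv", i),
                modality_paths={
                    c: str(row_d[c]) for c in path_columns
                    if row_d[c] is not None and str(row_d[c]).strip() not in ("", "nan")
                },
            )
        )
    return records


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Tabular view of a subject list (one row per subject, file order)."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "tiv": [s.tiv for s in subjects],
        }
    )
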