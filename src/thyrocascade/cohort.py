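"""Patient-level cohort data model and delimited-text I/O.

A cohort is one row per analyzed nodule-patient with three mandatory
classifications — FNA Bethesda category, frozen-section (FS) category and
final pathology — plus optional clinicopathologic covariates.  Files are
UTF-8 CSV (TSV via ``dialect="tsv"``) with a header row; missing optional
values are empty fields, never sentinel numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterator

import pandas as pd

from . import vocab
from .errors import IntegrityError, SchemaError, VocabularyError

MANDATORY_COLUMNS = ("fna_category", "fs_category", "outcome")
OPTIONAL_COLUMNS = (
    "age_years", "sex", "diameter_mm", "bilateral", "multifocal",
    "combined_category", "fs_used",
)
ALL_COLUMNS = ("patient_id",) + MANDATORY_COLUMNS + OPTIONAL_COLUMNS

_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False,
                "yes": True, "no": False}


@dataclass(frozen=True, slots=True)
class PatientRecord:
    """One analyzed nodule-patient.

    ``combined_category`` and ``fs_used`` are filled by
    :func:`thyrocascade.cascade.apply_cascade`; they are ``None`` on a
    freshly read cohort unless the file carries them.
    """

    patient_id: str
    fna_category: str
    fs_category: str
    outcome: str
    age_years: int | None = None
    sex: str | None = None
    diameter_mm: float | None = None
    bilateral: bool | None = None
    multifocal: bool | None = None
    combined_category: str | None = None
    fs_used: bool | None = None

    def __post_init__(self) -> None:
        if self.fna_category not in vocab.FNA_CATEGORIES:
            raise VocabularyError(f"unknown FNA category {self.fna_category!r}")
        if self.fs_category not in vocab.FS_CATEGORIES:
            raise VocabularyError(f"unknown FS category {self.fs_category!r}")
        if self.outcome not in vocab.OUTCOMES:
            raise VocabularyError(f"unknown outcome {self.outcome!r}")
        if self.sex is not None and self.sex not in ("F", "M"):
            raise VocabularyError(f"unknown sex {self.sex!r}")
        if self.combined_category is not None \
                and self.combined_category not in vocab.FS_CATEGORIES:
            raise VocabularyError(
                f"unknown combined category {self.combined_category!r}")
        if self.age_years is not None and self.age_years < 0:
            raise VocabularyError("age_years must be nonnegative")
        if self.diameter_mm is not None and not self.diameter_mm > 0:
            raise VocabularyError("diameter_mm must be positive")


@dataclass
class Cohort:
    """An ordered collection of :class:`PatientRecord` with unique ids."""

    records: list[PatientRecord]
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id in seen:
                raise IntegrityError(f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def with_records(self, records: list[PatientRecord]) -> "Cohort":
        return Cohort(records=records, label=self.label)

    @property
    def n_events(self) -> int:
        """Number of records with malignant final pathology."""
        return sum(r.outcome == "MALIGNANT" for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame; columns that are all-missing are dropped."""
        rows = []
        for rec in self.records:
            rows.append({f.name: getattr(rec, f.name) for f in fields(rec)})
        df = pd.DataFrame(rows, columns=list(ALL_COLUMNS))
        keep = ["patient_id", *MANDATORY_COLUMNS]
        keep += [c for c in OPTIONAL_COLUMNS if df[c].notna().any()]
        return df[keep]


def _parse_optional(row_no: int, name: str, raw: object):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    try:
        if name == "age_years":
            return int(float(text))
        if name == "diameter_mm":
            return float(text)
        if name == "sex":
            return vocab.normalize_sex(text)
        if name in ("bilateral", "multifocal", "fs_used"):
            return _BOOL_TOKENS[text.lower()]
        if name == "combined_category":
            return vocab.normalize_fs(text)
    except (KeyError, ValueError) as exc:
        raise VocabularyError(
            f"row {row_no}: cannot parse {name}={text!r}") from exc
    raise AssertionError(name)


def read_cohort(path: str | Path, dialect: str = "csv", label: str | None = None) -> Cohort:
    """Read a cohort file.

    Parameters
    ----------
    path
        CSV (or TSV with ``dialect="tsv"``) file with a header row naming at
        least ``fna_category``, ``fs_category`` and ``outcome``.  Category
        tokens are case-normalized and mapped through the synonym table
        (``"Bethesda 6"`` -> ``VI``, ``"suspicious for malignancy"`` ->
        ``SUSPICIOUS``, ...).
    dialect
        ``"csv"`` or ``"tsv"``.
    label
        Cohort label; defaults to the file stem.

    Raises
    ------
    SchemaError
        Missing mandatory column, or an empty file.
    VocabularyError
        An unmappable category token (the message cites the 1-based data
        row number).
    IntegrityError
        Duplicate ``patient_id``.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise SchemaError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")

    has_id = "patient_id" in df.columns
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            fna = vocab.normalize_fna(row["fna_category"])
            fs = vocab.normalize_fs(row["fs_category"])
            outcome = vocab.normalize_outcome(row["outcome"])
        except KeyError as exc:
            raise VocabularyError(
                f"row {i}: unmappable category token {exc.args[0]!r}") from exc
        opt = {
            name: _parse_optional(i, name, row.get(name))
            for name in OPTIONAL_COLUMNS if name in df.columns
        }
        pid = str(row["patient_id"]).strip() if has_id else f"R{i}"
        if pid == "":
            raise IntegrityError(f"row {i}: empty patient_id")
        records.append(PatientRecord(
            patient_id=pid, fna_category=fna, fs_category=fs,
            outcome=outcome, **opt))
    if not records:
        raise SchemaError(f"{path}: no data rows")
    return Cohort(records=records,
                  label=label if label is not None else Path(path).stem)


def write_cohort(cohort: Cohort, path: str | Path, dialect: str = "csv") -> None:
    """Write a cohort; ``read_cohort`` of the result reproduces it exactly.

    Optional columns that are absent on every record are omitted; booleans
    are written as ``true``/``false``; missing values as empty fields.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise SchemaError(f"unknown dialect {dialect!r}")
    df = cohort.to_frame()
    for col in ("bilateral", "multifocal", "fs_used"):
        if col in df.columns:
            df[col] = df[col].map({True: "true", False: "false"})
    df.to_csv(path, sep=sep, index=False, na_rep="")


def strip_combined(cohort: Cohort) -> Cohort:
    """Return a copy with cascade-derived fields cleared."""
    return cohort.with_records([
        replace(r, combined_category=None, fs_used=None) for r in cohort
    ])
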