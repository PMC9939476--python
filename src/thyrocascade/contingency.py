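"""Category x outcome contingency tables, malignancy rates and chi-square tests.

The central container is :class:`ContingencyTable`: an ordered list of
category rows against the two final-pathology columns (MALIGNANT, BENIGN).
Row order is fixed by the stage vocabulary (VI..I for FNA; MALIGNANCY,
SUSPICIOUS, BENIGN, INDETERMINATE for FS and combined stages) so that
outputs are diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import vocab
from .cohort import Cohort
from .errors import DegenerateTableError, ThyroCascadeError

STAGES = {
    "FNA": ("fna_category", vocab.FNA_CATEGORIES),
    "FS": ("fs_category", vocab.FS_CATEGORIES),
    "COMBINED": ("combined_category", vocab.FS_CATEGORIES),
}


def percent_one_decimal(fraction: float) -> float:
    """Render a proportion as a percent rounded half-up to one decimal."""
    return float(Decimal(repr(fraction * 100)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """Integer counts of categories against the binary final pathology."""

    row_labels: tuple[str, ...]
    counts: np.ndarray  # shape (rows, 2); columns (MALIGNANT, BENIGN)
    source: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape != (len(self.row_labels), 2):
            raise ThyroCascadeError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.row_labels)} rows x 2 outcomes")
        if (counts < 0).any():
            raise ThyroCascadeError("negative count in contingency table")
        if counts.sum() == 0:
            raise ThyroCascadeError("contingency table is all zero")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row(self, label: str) -> tuple[int, int]:
        """(malignant, benign) counts for one category."""
        i = self.row_labels.index(label)
        return int(self.counts[i, 0]), int(self.counts[i, 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(vocab.OUTCOMES))

    def to_json(self) -> str:
        return json.dumps({
            "rows": list(self.row_labels),
            "columns": list(vocab.OUTCOMES),
            "counts": self.counts.tolist(),
            "source": self.source,
        }, indent=2)

    def write(self, path: str | Path, fmt: str = "csv") -> None:
        if fmt == "json":
            Path(path).write_text(self.to_json())
        else:
            self.to_frame().to_csv(path, index_label="category")


def tabulate(cohort: Cohort, stage: str) -> ContingencyTable:
    """Cross-tabulate one classification stage against final pathology.

    ``stage`` is ``"FNA"``, ``"FS"`` or ``"COMBINED"`` (the latter requires
    :func:`thyrocascade.cascade.apply_cascade` to have filled the combined
    field on every record).  Cell totals always sum to the cohort size.
    """
    if stage not in STAGES:
        raise ThyroCascadeError(
            f"unknown stage {stage!r}; expected one of {sorted(STAGES)}")
    attr, labels = STAGES[stage]
    if len(cohort) == 0:
        raise ThyroCascadeError("cohort is empty")
    counts = np.zeros((len(labels), 2), dtype=np.int64)
    row_ix = {lab: i for i, lab in enumerate(labels)}
    col_ix = {lab: j for j, lab in enumerate(vocab.OUTCOMES)}
    for rec in cohort:
        value = getattr(rec, attr)
        if value is None:
            raise ThyroCascadeError(
                f"record {rec.patient_id}: stage field {attr!r} is not set")
        counts[row_ix[value], col_ix[rec.outcome]] += 1
    return ContingencyTable(row_labels=labels, counts=counts,
                            source=f"{cohort.label}:{stage}")


@dataclass(frozen=True)
class MalignancyRate:
    """Per-category malignancy rate, kept as an exact fraction."""

    category: str
    malignant: int
    total: int

    @property
    def fraction(self) -> Fraction | None:
        if self.total == 0:
            return None
        return Fraction(self.malignant, self.total)

    @property
    def percent(self) -> float | None:
        """Percent rounded half-up to one decimal (display convention)."""
        if self.total == 0:
            return None
        return percent_one_decimal(self.malignant / self.total)


def malignancy_rates(table: ContingencyTable) -> list[MalignancyRate]:
    """Per-category malignant / total, as exact fraction and one-decimal percent.

    Rows with zero total are reported with ``fraction``/``percent`` of
    ``None`` (undefined) rather than zero.
    """
    out = []
    for i, label in enumerate(table.row_labels):
        m, b = int(table.counts[i, 0]), int(table.counts[i, 1])
        out.append(MalignancyRate(category=label, malignant=m, total=m + b))
    return out


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square(counts, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default (set ``correction=True`` for the
    Yates-corrected 2x2 statistic).  A zero row or column margin makes the
    expected counts degenerate and raises :class:`DegenerateTableError`.
    """
    arr = np.asarray(counts, dtype=np.int64)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise DegenerateTableError("chi-square needs an r x c table, r,c >= 2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero margin: expected counts undefined")
    res = stats.chi2_contingency(arr, correction=correction)
    return ChiSquareResult(statistic=float(res.statistic),
                           df=int(res.dof), p_value=float(res.pvalue))
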