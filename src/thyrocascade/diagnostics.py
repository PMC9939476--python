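"""Dichotomization of categorical calls and diagnostic-accuracy metrics.

A :class:`DichotomizationScheme` names the subset of a stage's categories
that counts as test-positive; collapsing a contingency table under a scheme
gives the 2x2 :class:`BinaryTable`, from which the five standard metrics
(accuracy, sensitivity, specificity, PPV, NPV) are computed with Wilson
score intervals (Clopper-Pearson optionally).

Shipped presets reproduce the clinically conventional dichotomizations:
FNA-positive = Bethesda {V, VI} (malignant + suspicious for malignancy),
FS-positive = {MALIGNANCY}, and the same for the staged combined call.
``search_schemes`` is an exploratory enumeration over alternative cut-offs;
the presets, not the search, define the reference comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from statsmodels.stats.proportion import proportion_confint

from .contingency import ContingencyTable, percent_one_decimal
from .errors import ThyroCascadeError

CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta"}


@dataclass(frozen=True)
class DichotomizationScheme:
    """A non-empty proper subset of a stage's categories declared positive."""

    positive_categories: frozenset[str]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive_categories",
                           frozenset(self.positive_categories))
        if not self.positive_categories:
            raise ThyroCascadeError("positive_categories must be non-empty")


FNA_PAPER = DichotomizationScheme(frozenset({"V", "VI"}), name="fna-paper")
FS_PAPER = DichotomizationScheme(frozenset({"MALIGNANCY"}), name="fs-paper")
CASCADE_PAPER = DichotomizationScheme(frozenset({"MALIGNANCY"}), name="cascade-paper")
PRESETS = {"fna-paper": FNA_PAPER, "fs-paper": FS_PAPER,
           "cascade-paper": CASCADE_PAPER}
#: stage each preset dichotomizes
PRESET_STAGES = {"fna-paper": "FNA", "fs-paper": "FS", "cascade-paper": "COMBINED"}


@dataclass(frozen=True)
class BinaryTable:
    """2x2 counts of a binary test against the binary final pathology."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ThyroCascadeError("negative cell in 2x2 table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def events(self) -> int:
        return self.tp + self.fn

    @property
    def nonevents(self) -> int:
        return self.fp + self.tn


def dichotomize(table: ContingencyTable, scheme: DichotomizationScheme) -> BinaryTable:
    """Collapse a category x outcome table to a 2x2 under a scheme.

    Positive rows contribute their malignant counts to TP and benign counts
    to FP; the complement rows give FN and TN.  The scheme must be a proper
    subset of the table's rows (both test classes realizable).
    """
    rows = set(table.row_labels)
    unknown = scheme.positive_categories - rows
    if unknown:
        raise ThyroCascadeError(
            f"scheme categories {sorted(unknown)} not in table rows")
    if scheme.positive_categories == rows:
        raise ThyroCascadeError(
            "scheme declares every category positive; not a proper subset")
    tp = fp = fn = tn = 0
    for i, label in enumerate(table.row_labels):
        m, b = int(table.counts[i, 0]), int(table.counts[i, 1])
        if label in scheme.positive_categories:
            tp += m
            fp += b
        else:
            fn += m
            tn += b
    return BinaryTable(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its two-sided 95% interval.

    ``value`` is ``None`` when the denominator is zero (undefined metric,
    never silently coerced to 0).
    """

    value: float | None
    ci_low: float | None
    ci_high: float | None
    numerator: int
    denominator: int

    @property
    def percent(self) -> float | None:
        return None if self.value is None else percent_one_decimal(self.value)


@dataclass(frozen=True)
class DiagnosticMetrics:
    accuracy: MetricEstimate
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    counts: BinaryTable

    def as_dict(self) -> dict:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            est: MetricEstimate = getattr(self, name)
            out[name] = {
                "value": est.value, "percent": est.percent,
                "ci95": [est.ci_low, est.ci_high],
                "fraction": f"{est.numerator}/{est.denominator}",
            }
        out["counts"] = {"tp": self.counts.tp, "fp": self.counts.fp,
                         "fn": self.counts.fn, "tn": self.counts.tn}
        return out


def _estimate(num: int, den: int, method: str) -> MetricEstimate:
    if den == 0:
        return MetricEstimate(None, None, None, num, den)
    lo, hi = proportion_confint(num, den, alpha=0.05, method=method)
    return MetricEstimate(num / den, float(lo), float(hi), num, den)


def compute_metrics(bt: BinaryTable, ci: str = "wilson") -> DiagnosticMetrics:
    """Accuracy, sensitivity, specificity, PPV and NPV with 95% intervals.

    ``ci`` is ``"wilson"`` (score interval; default, well-behaved at the
    extreme proportions seen here) or ``"clopper-pearson"`` (exact).
    A metric whose denominator is zero is returned as undefined while the
    others are still computed.
    """
    if bt.total == 0:
        raise ThyroCascadeError("empty 2x2 table")
    try:
        method = CI_METHODS[ci]
    except KeyError:
        raise ThyroCascadeError(f"unknown CI method {ci!r}") from None
    return DiagnosticMetrics(
        accuracy=_estimate(bt.tp + bt.tn, bt.total, method),
        sensitivity=_estimate(bt.tp, bt.tp + bt.fn, method),
        specificity=_estimate(bt.tn, bt.tn + bt.fp, method),
        ppv=_estimate(bt.tp, bt.tp + bt.fp, method),
        npv=_estimate(bt.tn, bt.tn + bt.fn, method),
        counts=bt,
    )


_CRITERIA = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class RankedScheme:
    scheme: DichotomizationScheme
    metrics: DiagnosticMetrics
    criterion_value: float | None


def search_schemes(table: ContingencyTable, criterion: str = "accuracy",
                   family: str = "threshold", ci: str = "wilson") -> list[RankedScheme]:
    """Enumerate and rank dichotomizations of a table (exploratory).

    ``family="threshold"`` takes the contiguous top-k prefixes of the row
    order (most- to least-suspicious), i.e. ordinal cut-offs; ``"subset"``
    enumerates all 2^k - 2 non-empty proper subsets.  Ranking is by the
    criterion metric, descending; ties break toward higher sensitivity,
    then fewer positive categories, then lexically.
    """
    if criterion not in _CRITERIA:
        raise ThyroCascadeError(f"unknown criterion {criterion!r}")
    labels = table.row_labels
    if len(labels) < 2:
        raise ThyroCascadeError("need at least 2 rows to dichotomize")
    if family == "threshold":
        subsets = [tuple(labels[:k]) for k in range(1, len(labels))]
    elif family == "subset":
        subsets = [c for r in range(1, len(labels))
                   for c in combinations(labels, r)]
    else:
        raise ThyroCascadeError(f"unknown family {family!r}")

    ranked = []
    for subset in subsets:
        scheme = DichotomizationScheme(frozenset(subset),
                                       name="+".join(subset))
        mets = compute_metrics(dichotomize(table, scheme), ci=ci)
        ranked.append(RankedScheme(scheme, mets,
                                   getattr(mets, criterion).value))

    def key(rs: RankedScheme):
        crit = -1.0 if rs.criterion_value is None else rs.criterion_value
        sens = rs.metrics.sensitivity.value
        sens = -1.0 if sens is None else sens
        return (-crit, -sens, len(rs.scheme.positive_categories),
                tuple(sorted(rs.scheme.positive_categories)))

    return sorted(ranked, key=key)
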