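"""Staged (triage) diagnostic rules, test-usage accounting and flow tables.

A :class:`CascadeRule` maps every first-stage (FNA) category to either a
terminal label — the patient is classified without the second test — or a
deferral to the second-stage (frozen section) result.  The shipped
``PAPER_RULE`` is the "FNA + selective FS" policy: Bethesda VI is called
malignant outright, Bethesda I-V defer to frozen section.  Terminal labels
live in the second-stage vocabulary, so combined tables have the same four
levels as the frozen-section table.

Also here: per-specimen cost accounting for cascades, and exact
category-to-category flow tables (Sankey-ready JSON export; rendering is
out of scope).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

from . import vocab
from .cohort import Cohort
from .contingency import STAGES, percent_one_decimal
from .errors import CostModelError, RuleCoverageError, ThyroCascadeError

TERMINAL = "TERMINAL"
DEFER = "DEFER"


@dataclass(frozen=True)
class Action:
    """Either TERMINAL with a final label, or DEFER to the second stage."""

    kind: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind == TERMINAL:
            if self.label not in vocab.FS_CATEGORIES:
                raise ThyroCascadeError(
                    f"terminal label {self.label!r} not in the combined "
                    f"(second-stage) vocabulary")
        elif self.kind == DEFER:
            if self.label is not None:
                raise ThyroCascadeError("DEFER takes no label")
        else:
            raise ThyroCascadeError(f"unknown action kind {self.kind!r}")


def terminal(label: str) -> Action:
    return Action(kind=TERMINAL, label=label)


def defer() -> Action:
    return Action(kind=DEFER)


@dataclass(frozen=True)
class CascadeRule:
    """Per-FNA-category action table for a two-stage rule."""

    actions: dict[str, Action]
    second_stage: str = "FS"
    name: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.actions) - set(vocab.FNA_CATEGORIES)
        if unknown:
            raise ThyroCascadeError(f"unknown FNA categories {sorted(unknown)}")

    def action_for(self, category: str) -> Action:
        try:
            return self.actions[category]
        except KeyError:
            raise RuleCoverageError(
                f"cascade rule {self.name!r} has no action for FNA "
                f"category {category!r}") from None


#: FNA + selective FS: Bethesda VI terminal-malignant, I-V defer to FS.
PAPER_RULE = CascadeRule(
    actions={"VI": terminal("MALIGNANCY"),
             **{c: defer() for c in ("V", "IV", "III", "II", "I")}},
    name="fna-plus-selective-fs",
)


def identity_rule() -> CascadeRule:
    """Every category terminal — no second test is ever consumed.

    FNA labels are mapped onto the combined vocabulary with the preset
    dichotomy boundary preserved (V, VI -> MALIGNANCY-side labels)."""
    mapping = {"VI": "MALIGNANCY", "V": "SUSPICIOUS", "IV": "INDETERMINATE",
               "III": "INDETERMINATE", "II": "BENIGN", "I": "INDETERMINATE"}
    return CascadeRule(actions={c: terminal(mapping[c]) for c in vocab.FNA_CATEGORIES},
                       name="identity")


def full_deferral_rule() -> CascadeRule:
    return CascadeRule(actions={c: defer() for c in vocab.FNA_CATEGORIES},
                       name="full-deferral")


def apply_cascade(cohort: Cohort, rule: CascadeRule) -> Cohort:
    """Fill the combined classification (and second-test flag) per record.

    TERMINAL categories take the rule's label without consuming the second
    test; DEFER categories copy the frozen-section category and mark the
    second test as consumed.  Record order and count are preserved.
    """
    records = []
    for rec in cohort:
        action = rule.action_for(rec.fna_category)
        if action.kind == TERMINAL:
            records.append(replace(rec, combined_category=action.label,
                                   fs_used=False))
        else:
            records.append(replace(rec, combined_category=rec.fs_category,
                                   fs_used=True))
    return cohort.with_records(records)


@dataclass(frozen=True)
class CostModel:
    """Per-specimen unit costs by test name."""

    unit_costs: dict[str, float]
    currency: str = "USD"

    def __post_init__(self) -> None:
        for test, cost in self.unit_costs.items():
            if cost < 0:
                raise CostModelError(f"negative unit cost for {test!r}")

    def cost_of(self, test: str) -> float:
        try:
            return self.unit_costs[test]
        except KeyError:
            raise CostModelError(f"no unit cost for test {test!r}") from None


#: Per-specimen costs reported for the study setting.
PAPER_COSTS = CostModel(unit_costs={"FNA": 170.0, "FS": 20.0}, currency="USD")


@dataclass(frozen=True)
class UsageReport:
    """Second-test consumption and cost under a cascade.

    Cost scenarios: (a) first test only for everyone, (b) both tests for
    everyone (routine second test), (c) the cascade (second test only for
    deferred patients).  ``savings_vs_routine`` is (b) - (c).
    """

    n: int
    deferred_count: int
    first_test: str
    second_test: str
    currency: str
    cost_first_only: float
    cost_both_all: float
    cost_cascade: float

    @property
    def deferred_fraction(self) -> Fraction:
        return Fraction(self.deferred_count, self.n)

    @property
    def deferred_percent(self) -> float:
        return percent_one_decimal(float(self.deferred_fraction))

    @property
    def savings_vs_routine(self) -> float:
        return self.cost_both_all - self.cost_cascade

    def as_dict(self) -> dict:
        return {
            "n": self.n, "deferred_count": self.deferred_count,
            "deferred_percent": self.deferred_percent,
            "currency": self.currency,
            "cost_first_only": self.cost_first_only,
            "cost_both_all": self.cost_both_all,
            "cost_cascade": self.cost_cascade,
            "savings_vs_routine": self.savings_vs_routine,
        }


def usage_and_cost(cohort: Cohort, rule: CascadeRule,
                   costs: CostModel = PAPER_COSTS,
                   first_test: str = "FNA", second_test: str = "FS") -> UsageReport:
    """Deferred count/fraction and total cost under the three scenarios."""
    staged = apply_cascade(cohort, rule)
    n = len(staged)
    deferred = sum(1 for r in staged if r.fs_used)
    c1 = costs.cost_of(first_test)
    c2 = costs.cost_of(second_test)
    return UsageReport(
        n=n, deferred_count=deferred,
        first_test=first_test, second_test=second_test,
        currency=costs.currency,
        cost_first_only=n * c1,
        cost_both_all=n * (c1 + c2),
        cost_cascade=n * c1 + deferred * c2,
    )


@dataclass(frozen=True)
class FlowTable:
    """Exact (from-category, to-category, outcome) cross-counts."""

    from_stage: str
    to_stage: str
    counts: dict[tuple[str, str, str], int] = field(compare=True)

    def link(self, from_cat: str, to_cat: str) -> int:
        """Total flow on one link, summed over outcomes."""
        return sum(v for (f, t, _o), v in self.counts.items()
                   if f == from_cat and t == to_cat)

    def marginal_from(self) -> dict[tuple[str, str], int]:
        """Summing over to-categories recovers the from-stage x outcome table."""
        out: dict[tuple[str, str], int] = {}
        for (f, _t, o), v in self.counts.items():
            out[(f, o)] = out.get((f, o), 0) + v
        return out

    def to_sankey_json(self) -> str:
        """Node/link lists for any Sankey renderer; fixed vocabulary order."""
        from_labels = STAGES[self.from_stage][1]
        to_labels = STAGES[self.to_stage][1]
        nodes = ([f"{self.from_stage}:{c}" for c in from_labels]
                 + [f"{self.to_stage}:{c}" for c in to_labels])
        index = {name: i for i, name in enumerate(nodes)}
        links = []
        for f in from_labels:
            for t in to_labels:
                value = self.link(f, t)
                if value:
                    links.append({
                        "source": index[f"{self.from_stage}:{f}"],
                        "target": index[f"{self.to_stage}:{t}"],
                        "value": value,
                    })
        return json.dumps({"nodes": [{"name": n} for n in nodes],
                           "links": links}, indent=2)

    def write_sankey(self, path: str | Path) -> None:
        Path(path).write_text(self.to_sankey_json())


def flow_table(cohort: Cohort, from_stage: str, to_stage: str) -> FlowTable:
    """Cross-count categories between two stages, keeping the outcome split."""
    for stage in (from_stage, to_stage):
        if stage not in STAGES:
            raise ThyroCascadeError(f"unknown stage {stage!r}")
    from_attr = STAGES[from_stage][0]
    to_attr = STAGES[to_stage][0]
    counts: dict[tuple[str, str, str], int] = {}
    for rec in cohort:
        f, t = getattr(rec, from_attr), getattr(rec, to_attr)
        if f is None or t is None:
            raise ThyroCascadeError(
                f"record {rec.patient_id}: stage field not set")
        key = (f, t, rec.outcome)
        counts[key] = counts.get(key, 0) + 1
    return FlowTable(from_stage=from_stage, to_stage=to_stage, counts=counts)
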