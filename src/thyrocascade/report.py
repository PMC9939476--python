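"""Comparison-report assembly: metrics panels, NRI comparisons, usage/cost.

These functions tie the library modules together into the three-way
comparison (FNA alone, frozen section alone, FNA + selective frozen
section) and render it as JSON or a plain-text panel.  The JSON and text
renderings carry identical numbers; provenance (input label/digest,
package version, presets) is embedded so every number is reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from . import __version__
from .cascade import (PAPER_COSTS, PAPER_RULE, CascadeRule, CostModel,
                      apply_cascade, usage_and_cost)
from .cohort import Cohort
from .contingency import tabulate
from .diagnostics import (PRESET_STAGES, PRESETS, DiagnosticMetrics,
                          DichotomizationScheme, compute_metrics, dichotomize)
from .errors import ThyroCascadeError
from .reclassification import ReclassificationResult, nri_paired


def cohort_digest(cohort: Cohort) -> str:
    """Stable digest of the classification content of a cohort."""
    h = hashlib.sha256()
    for rec in cohort:
        h.update(f"{rec.patient_id},{rec.fna_category},{rec.fs_category},"
                 f"{rec.outcome}\n".encode())
    return h.hexdigest()[:16]


@dataclass
class ComparisonReport:
    """Per-scheme metrics, pairwise reclassification and usage summary."""

    metrics: dict[str, DiagnosticMetrics] = field(default_factory=dict)
    reclassification: dict[str, ReclassificationResult] = field(default_factory=dict)
    usage: dict | None = None
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "metrics": {k: v.as_dict() for k, v in self.metrics.items()},
            "reclassification": {k: v.as_dict()
                                 for k, v in self.reclassification.items()},
            "provenance": self.provenance,
        }
        if self.usage is not None:
            out["usage"] = self.usage
        return out

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def to_text(self) -> str:
        """Plain-text panel; percents at one decimal, same numbers as JSON."""
        lines = []
        for name, mets in self.metrics.items():
            lines.append(f"[{name}]")
            d = mets.as_dict()
            for metric in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
                e = d[metric]
                pct = "undefined" if e["percent"] is None else f"{e['percent']}%"
                lines.append(f"  {metric:<12} {pct:>10}   ({e['fraction']})")
        for name, res in self.reclassification.items():
            lines.append(f"[NRI {name}]")
            lines.append(f"  estimate     {res.rounded:>10}")
            if res.ci95 is not None:
                lines.append(f"  95% CI       {res.ci95[0]:.3f} to {res.ci95[1]:.3f}")
                lines.append(f"  p            {res.p_value:.3g}")
        if self.usage is not None:
            u = self.usage
            lines.append("[usage]")
            lines.append(f"  second test  {u['deferred_count']} of {u['n']} "
                         f"({u['deferred_percent']}%)")
            lines.append(f"  cascade cost {u['cost_cascade']:.0f} {u['currency']} "
                         f"(routine both: {u['cost_both_all']:.0f}; "
                         f"savings {u['savings_vs_routine']:.0f})")
        return "\n".join(lines)


def _resolve(preset_or_scheme, stage: str | None) -> tuple[str, DichotomizationScheme]:
    if isinstance(preset_or_scheme, str):
        if preset_or_scheme not in PRESETS:
            raise ThyroCascadeError(f"unknown preset {preset_or_scheme!r}")
        return PRESET_STAGES[preset_or_scheme], PRESETS[preset_or_scheme]
    if stage is None:
        raise ThyroCascadeError("a custom scheme needs an explicit stage")
    return stage, preset_or_scheme


def _base_provenance(cohort: Cohort, seed: int | None = None) -> dict:
    prov = {"cohort": cohort.label, "digest": cohort_digest(cohort),
            "version": __version__}
    if seed is not None:
        prov["seed"] = seed
    return prov


def _prepare(cohort: Cohort, stages: set[str], rule: CascadeRule) -> Cohort:
    if "COMBINED" in stages:
        return apply_cascade(cohort, rule)
    return cohort


def run_evaluate(cohort: Cohort, preset_or_scheme="fna-paper",
                 stage: str | None = None, ci: str = "wilson",
                 rule: CascadeRule = PAPER_RULE) -> ComparisonReport:
    """Metrics panel for a single dichotomization scheme."""
    stage, scheme = _resolve(preset_or_scheme, stage)
    cohort = _prepare(cohort, {stage}, rule)
    table = tabulate(cohort, stage)
    mets = compute_metrics(dichotomize(table, scheme), ci=ci)
    name = scheme.name or f"{stage}:{'+'.join(sorted(scheme.positive_categories))}"
    report = ComparisonReport(metrics={name: mets},
                              provenance=_base_provenance(cohort))
    report.provenance["schemes"] = {name: sorted(scheme.positive_categories)}
    return report


def run_compare(cohort: Cohort, old="fna-paper", new="fs-paper",
                old_stage: str | None = None, new_stage: str | None = None,
                ci: str = "wilson", rule: CascadeRule = PAPER_RULE) -> ComparisonReport:
    """Two metric panels plus the paired NRI from old to new."""
    o_stage, o_scheme = _resolve(old, old_stage)
    n_stage, n_scheme = _resolve(new, new_stage)
    cohort = _prepare(cohort, {o_stage, n_stage}, rule)
    report = ComparisonReport(provenance=_base_provenance(cohort))
    for stage, scheme in ((o_stage, o_scheme), (n_stage, n_scheme)):
        name = scheme.name or f"{stage}:{'+'.join(sorted(scheme.positive_categories))}"
        table = tabulate(cohort, stage)
        report.metrics[name] = compute_metrics(dichotomize(table, scheme), ci=ci)
    o_name, n_name = list(report.metrics)[:2]
    report.reclassification[f"{o_name} -> {n_name}"] = nri_paired(
        cohort, o_stage, o_scheme, n_stage, n_scheme)
    return report


def run_cascade(cohort: Cohort, rule: CascadeRule = PAPER_RULE,
                costs: CostModel = PAPER_COSTS, ci: str = "wilson") -> ComparisonReport:
    """Combined-scheme metrics plus second-test usage and cost accounting."""
    staged = apply_cascade(cohort, rule)
    report = run_evaluate(staged, "cascade-paper", ci=ci, rule=rule)
    report.usage = usage_and_cost(cohort, rule, costs).as_dict()
    report.provenance["rule"] = rule.name
    return report
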