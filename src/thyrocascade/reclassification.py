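"""Categorical Net Reclassification Index (NRI) between binary schemes.

For two binary classifiers of the same cohort the NRI is

    NRI = [P(up | event) - P(down | event)]
        + [P(down | non-event) - P(up | non-event)]

where "up" is a move from test-negative to test-positive and "down" the
reverse, events are malignant final pathology.  For binary old/new schemes
this telescopes to (sens_new - sens_old) + (spec_new - spec_old), so the
point estimate is computable from the two marginal 2x2 tables alone; the
asymptotic standard error, however, needs the patient-level pairing:

    se^2 = [p_up,e + p_down,e - (p_up,e - p_down,e)^2] / n_e
         + [p_up,ne + p_down,ne - (p_up,ne - p_down,ne)^2] / n_ne

Hence two estimators: :func:`nri_from_marginals` (point estimate only) and
:func:`nri_paired` (point + SE/CI/p), whose point estimates coincide on
any cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from scipy import stats

from .cohort import Cohort
from .contingency import STAGES
from .diagnostics import BinaryTable, DichotomizationScheme
from .errors import CohortMismatchError, StratumEmptyError, ThyroCascadeError


@dataclass(frozen=True)
class ReclassificationResult:
    """NRI point estimate with event / non-event components.

    ``se``, ``ci95`` and ``p_value`` are present only when the estimate was
    computed from paired records (``pairing="PAIRED_RECORDS"``): the paired
    variance is not identifiable from marginal tables, and no approximate
    interval is fabricated in that case.
    """

    nri: float
    nri_events: float
    nri_nonevents: float
    pairing: str  # PAIRED_RECORDS | MARGINAL_ONLY
    nri_exact: Fraction
    se: float | None = None
    ci95: tuple[float, float] | None = None
    p_value: float | None = None

    @property
    def rounded(self) -> float:
        """Display convention: three decimals."""
        return round(self.nri, 3)

    def as_dict(self) -> dict:
        return {
            "estimate": self.nri,
            "nri_events": self.nri_events,
            "nri_nonevents": self.nri_nonevents,
            "pairing": self.pairing,
            "ci_low": None if self.ci95 is None else self.ci95[0],
            "ci_high": None if self.ci95 is None else self.ci95[1],
            "p": self.p_value,
        }


def nri_from_marginals(old: BinaryTable, new: BinaryTable) -> ReclassificationResult:
    """NRI point estimate from two marginal 2x2 tables of the same cohort.

    The tables must agree on the cohort size and the event count; the
    result carries no SE/CI/p (pairing unknown).
    """
    if old.total != new.total or old.events != new.events:
        raise CohortMismatchError(
            f"tables describe different cohorts: totals {old.total}/{new.total}, "
            f"events {old.events}/{new.events}")
    if old.events == 0 or old.nonevents == 0:
        raise StratumEmptyError("need at least one event and one non-event")
    ev = Fraction(new.tp, new.events) - Fraction(old.tp, old.events)
    ne = Fraction(new.tn, new.nonevents) - Fraction(old.tn, old.nonevents)
    return ReclassificationResult(
        nri=float(ev + ne), nri_events=float(ev), nri_nonevents=float(ne),
        nri_exact=ev + ne, pairing="MARGINAL_ONLY")


def _is_positive(record, stage: str, scheme: DichotomizationScheme) -> bool:
    attr, labels = STAGES[stage]
    value = getattr(record, attr)
    if value is None:
        raise ThyroCascadeError(
            f"record {record.patient_id}: stage field {attr!r} is not set")
    return value in scheme.positive_categories


def nri_paired(cohort: Cohort, old_stage: str, old_scheme: DichotomizationScheme,
               new_stage: str, new_scheme: DichotomizationScheme) -> ReclassificationResult:
    """Paired categorical NRI from record-level up/down movements.

    Counts upward (negative -> positive) and downward moves separately in
    the event and non-event strata and applies the asymptotic variance
    above; p is the two-sided normal test of NRI/SE.  With zero movements
    the SE is 0 and p is reported as 1 by convention.  The point estimate
    equals :func:`nri_from_marginals` of the two induced 2x2 tables.
    """
    for stage in (old_stage, new_stage):
        if stage not in STAGES:
            raise ThyroCascadeError(f"unknown stage {stage!r}")
    up = {"e": 0, "ne": 0}
    down = {"e": 0, "ne": 0}
    n = {"e": 0, "ne": 0}
    for rec in cohort:
        stratum = "e" if rec.outcome == "MALIGNANT" else "ne"
        n[stratum] += 1
        was = _is_positive(rec, old_stage, old_scheme)
        now = _is_positive(rec, new_stage, new_scheme)
        if now and not was:
            up[stratum] += 1
        elif was and not now:
            down[stratum] += 1
    if n["e"] == 0 or n["ne"] == 0:
        raise StratumEmptyError("need at least one event and one non-event")

    ev = Fraction(up["e"] - down["e"], n["e"])
    ne = Fraction(down["ne"] - up["ne"], n["ne"])
    nri = ev + ne

    var = 0.0
    for stratum, comp in (("e", ev), ("ne", ne)):
        p_up = up[stratum] / n[stratum]
        p_down = down[stratum] / n[stratum]
        var += (p_up + p_down - (p_up - p_down) ** 2) / n[stratum]
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        z = float(nri) / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
    else:
        p = 1.0
    ci = (float(nri) - 1.96 * se, float(nri) + 1.96 * se)
    return ReclassificationResult(
        nri=float(nri), nri_events=float(ev), nri_nonevents=float(ne),
        nri_exact=nri, pairing="PAIRED_RECORDS", se=se, ci95=ci, p_value=p)
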