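"""Test usage and cost under the staged FNA + selective frozen-section rule.

Bethesda VI nodules are called malignant from cytology alone; categories
I-V defer to the intraoperative frozen section.  The report compares three
spending scenarios per specimen (FNA 170 USD, FS 20 USD): FNA only,
routine FS for everyone, and the selective cascade.
"""

from thyrocascade import reconstruct_paper_cohort, usage_and_cost
from thyrocascade.cascade import PAPER_COSTS, PAPER_RULE

cohort = reconstruct_paper_cohort()
report = usage_and_cost(cohort, PAPER_RULE, PAPER_COSTS)

print(f"second test consumed by {report.deferred_count} of {report.n} "
      f"patients ({report.deferred_percent}%)")
print(f"FNA only            : {report.cost_first_only:>9,.0f} {report.currency}")
print(f"FNA + routine FS    : {report.cost_both_all:>9,.0f} {report.currency}")
print(f"FNA + selective FS  : {report.cost_cascade:>9,.0f} {report.currency}")
print(f"savings vs routine  : {report.savings_vs_routine:>9,.0f} {report.currency}"
      f"  (the frozen-section budget shrinks by "
      f"{1 - report.deferred_count / report.n:.0%})")
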