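"""Net Reclassification Index: does a second test reclassify patients better?

Compares FNA alone against frozen section and against the staged
FNA + selective frozen section rule.  A positive NRI means the new scheme
moves malignant patients toward test-positive and benign patients toward
test-negative, net of movements in the wrong direction; for binary
schemes it equals (delta sensitivity) + (delta specificity).
"""

from thyrocascade import reconstruct_paper_cohort, run_compare

cohort = reconstruct_paper_cohort()

for new in ("fs-paper", "cascade-paper"):
    report = run_compare(cohort, "fna-paper", new)
    name, result = next(iter(report.reclassification.items()))
    lo, hi = result.ci95
    print(f"{name}: NRI = {result.rounded} "
          f"(events {result.nri_events:+.3f}, non-events {result.nri_nonevents:+.3f}; "
          f"95% CI {lo:.3f} to {hi:.3f}, p = {result.p_value:.2g})")
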