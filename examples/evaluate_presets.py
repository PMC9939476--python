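"""Diagnostic-accuracy panels for FNA, frozen section, and the staged rule.

Builds the deterministic 3807-patient reconstruction cohort and prints the
five standard metrics for each preset dichotomization.  Accuracy is the
share of all patients classified correctly; sensitivity/specificity are
the detection rates among malignant/benign final pathology; PPV/NPV are
the post-test malignancy probabilities given a positive/negative call.
"""

from thyrocascade import reconstruct_paper_cohort, run_cascade, run_evaluate

cohort = reconstruct_paper_cohort()
print(f"cohort: {len(cohort)} patients, {cohort.n_events} malignant\n")

for preset in ("fna-paper", "fs-paper"):
    print(run_evaluate(cohort, preset).to_text(), "\n")

# the staged rule needs the cascade applied first; run_cascade does that
print(run_cascade(cohort).to_text())
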