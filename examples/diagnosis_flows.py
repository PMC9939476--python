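"""Category-to-category flows between FNA and frozen section.

Counts how each Bethesda category is re-read by the frozen section (with
the final-pathology split retained) and exports Sankey-ready JSON.  The
printed lines show, per Bethesda category, how many patients the frozen
section called malignant and how many it pushed to benign/indeterminate.
"""

from thyrocascade import flow_table, reconstruct_paper_cohort

cohort = reconstruct_paper_cohort()
ft = flow_table(cohort, "FNA", "FS")

for cat in ("VI", "V", "IV", "III", "II", "I"):
    total = sum(ft.link(cat, fs) for fs in
                ("MALIGNANCY", "SUSPICIOUS", "BENIGN", "INDETERMINATE"))
    mal = ft.link(cat, "MALIGNANCY")
    soft = ft.link(cat, "BENIGN") + ft.link(cat, "INDETERMINATE")
    print(f"Bethesda {cat:>3}: {mal:>4}/{total:<4} read as malignant, "
          f"{soft:>3} as benign/indeterminate")

ft.write_sankey("sankey_fna_fs.json")
print("\nwrote sankey_fna_fs.json (node/link lists for any Sankey renderer)")
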