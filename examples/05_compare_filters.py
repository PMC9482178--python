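"""Benchmark the MI filter against traditional abundance/prevalence filters.

Runs four classic ad hoc filters and the full MI pipeline on the same
labelled community and prints a comparison table plus the ROC AUC of the
MI network's non-isolation rule.
"""

from mifilter import (
    adjusted_mi_matrix,
    brooks_like_spec,
    comparison_report,
    generate_community,
    roc_analysis,
)

table, labels = generate_community(brooks_like_spec(seed=1))

frame = comparison_report(table, labels)
print(frame.to_string(index=False))
print("\npercent_contamination_preserved = share of the 39 contaminants a")
print("filter failed to remove; lower is better, 0.0 is perfect.")

roc = roc_analysis(adjusted_mi_matrix(table), labels)
print(f"\nMI network ROC AUC: {roc.auc:.3f} "
      "(1.0 = contaminants perfectly separated from true taxa)")
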