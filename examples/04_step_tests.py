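"""Decide how much to remove: permutation and bootstrap step tests.

For every adjacent pair of removal quantiles, tests H0: the extra
information loss of stepping to the higher quantile is what association-free
data would produce.  The permutation null shuffles each taxon's counts
across samples; the bootstrap resamples retained columns.  Early
(contaminant-only) steps give p near 1, and p collapses to the resampling
floor 1/(M+1) once a step starts consuming true taxa.
"""

from mifilter import brooks_like_spec, generate_community, scan_steps

table, labels = generate_community(brooks_like_spec(seed=1))
scan = scan_steps(table, n_permutations=500, n_bootstrap=500, seed=11)

cols = ["step_lo", "step_hi", "n_removed_hi", "delta", "p_perm", "p_boot"]
print(scan.results[cols].to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print(f"\nrecommended removal level: q = {scan.recommended_quantile:g}")
print("(the largest quantile whose steps never rejected; removing taxa up to")
print(" this degree quantile does not significantly alter the MI network —")
print(" here it lands next to the simulated contaminant fraction 39/46 = 0.85)")
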