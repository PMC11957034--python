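"""Deep-vs-superficial enrichment testing with age-permutation nulls.

The running-sum enrichment score asks whether node-wise age effects
concentrate in superficial tract regions; the null permutes participant
age while keeping profiles and covariates fixed, which respects the
spatial autocorrelation along the tract.
"""

import alongtract as at

cfg = at.SimulationConfig(n_subjects=250, n_tracts=4, seed=11)
cohort, _, _, profiles, _ = at.generate_dataset(cfg)

contrast = at.deep_superficial_contrast()  # superficial 5-9, 90-94 vs deep 46-55
results = {}
for tid, ps in profiles.items():
    tract = at.trim_end_nodes(ps)
    results[tid] = at.nest_test(tract, cohort, contrast, n_perm=499, seed=11)
at.enrichment.fdr_across_tracts(results)

for tid, r in sorted(results.items()):
    print(f"{tid:24s} ES={r.es_observed:+.2f}  p={r.p_perm:.4f}  q={r.q:.4f}")
print("\nPositive ES: age effects rank toward superficial nodes; with the")
print("generator's 4:1 gradient every tract is significantly enriched.")

# end-vs-end contrast on the heterotopic tract (two-sided, unweighted score)
tract = at.trim_end_nodes(profiles["tract01_heterotopic"])
res = at.endpoint_contrast(tract, cohort, n_perm=499, seed=11)
print(f"\nend_A vs end_B (heterotopic): ES={res.es_observed:+.2f} "
      f"p={res.p_perm:.4f} ({res.tail})")

# robustness of the deep/superficial definition to the bin size
table = at.enrichment.bin_sensitivity(tract, cohort, bin_sizes=(3, 5, 7, 10),
                                      n_perm=199, seed=11)
print("\nbin-size sensitivity:")
print(table.to_string(index=False))
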