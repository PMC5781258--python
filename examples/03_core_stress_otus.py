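"""Call stress-responsive OTUs and tally the core stress set.

Per stress treatment, each OTU's relative abundance is compared to
control (equal-variance t-test, BH FDR within treatment, responsive iff
raw p < 0.05 and q <= 0.10).  OTUs responsive in more than one treatment
with a consistent direction form the core stress microbiome; the summary
mirrors a per-treatment responsiveness-class table (3/3, 2/3, 1/3).
"""

from coreshift import (SimConfig, consistency_totals, core_consistency,
                       differential_otus, rarefy, responsive_summary,
                       simulate_dataset)

table, _, truth = simulate_dataset(SimConfig(seed=1))
rare = rarefy(table, 19_000, seed=2)

results = {t: differential_otus(rare, t, control="control")
           for t in ("copper", "drought", "shade")}
core = core_consistency(results)
totals = consistency_totals(core)
print(f"responsive in >=1 treatment: {totals['n_significant_any']}")
print(f"responsive in  >1 treatment: {totals['n_significant_multi']}")
print(f"  of which direction-consistent: {totals['n_consistent_multi']}")

hits = set(core.index[core["n_significant_treatments"] >= 2])
print(f"planted core OTUs recovered among multi-treatment hits: "
      f"{len(hits & truth.core)}/{len(truth.core)}")

print(responsive_summary(results, rare).to_string(index=False))
# abundance_pct: share of the community carried by OTUs responsive in
# exactly k of 3 treatments (k/3), per treatment
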