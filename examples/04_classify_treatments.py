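"""Predict treatment from the microbiome with Gaussian naive Bayes.

Features are relative abundances of OTUs present in at least 80% of
samples; evaluation is leave-one-out.  Accuracy is reported over the four
labels and with copper/drought/shade collapsed to one "stress" class —
the collapsed view asks whether a stressed plant is recognizable as
stressed at all.
"""

from coreshift import (SimConfig, loo_evaluate, prevalence_filter,
                       simulate_dataset)

table, _, _ = simulate_dataset(SimConfig(effect_log2=2.0, seed=1))
X, otus = prevalence_filter(table, min_prevalence=0.80)
labels = [table.metadata[s]["treatment"] for s in table.sample_ids]

report = loo_evaluate(X, labels)
print(f"features: {X.shape[1]} OTUs at >=80% prevalence")
print(f"LOO accuracy (4 classes): {report.accuracy:.2f}")
print(f"LOO accuracy (stress vs control): {report.collapsed_accuracy:.2f}")
print("confusion matrix (rows = true):")
print(report.confusion.to_string())
print("collapsed:")
print(report.collapsed_confusion.to_string())
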