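"""Classify targets from mutant-vs-wild-type expression time courses.

Simulates a six-point (10-20 h) log2 expression matrix with 3 replicates
per strain, combines replicates, computes mutant - WT fold changes and
applies the 2-fold rule: a target whose expression rises >= 2-fold in the
regulator-null mutant is normally repressed by the regulator; one that
falls >= 2-fold is normally activated.
"""

from chipregulon import SimulationConfig, classify_targets, \
    combine_replicates, log_fold_changes, regulon_summary, simulate_genome
from chipregulon.synthetic import simulate_expression

config = SimulationConfig(seed=3)
genome, genes, truth = simulate_genome(config)
expression = simulate_expression(genes, truth, config)

means = combine_replicates(expression)
logfc = log_fold_changes(means)
classes = classify_targets(logfc, fc_threshold_log2=1.0)

print("planted effect vs recovered class for each bound target:")
for site in truth.sites:
    c = classes[site.gene_id]
    peak = max(c.logfc.values(), key=abs)
    print(f"  {site.gene_id}: planted {site.expr_effect:+.1f} -> {c.label} "
          f"(extreme logFC {peak:+.2f} at t={c.supporting_times or '-'} h)")

print("\nregulon summary over bound targets:")
print(regulon_summary(classes, truth.target_gene_ids).to_string(index=False))
# Accuracy is essentially perfect at effect +-2 and noise sd 0.3: the
# per-time logFC standard error is 0.3 * sqrt(2/3) ~ 0.24 log2 units.
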