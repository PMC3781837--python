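"""Simulate a ChIP-seq condition and call peaks with the windowed statistic.

Builds one synthetic study (200-kb GC-rich chromosome, 10 planted binding
sites, 8-fold summit enrichment over a depth-50 background), computes
local enrichment ratios for the IP and input tracks at the onset of
sporulation, and prints the fitted null parameters and the significant
positions next to the planted summits.
"""

import numpy as np

from chipregulon import SimulationConfig, StatParams, call_condition, \
    significant_positions, simulate_coverage, simulate_genome

config = SimulationConfig(seed=1)
genome, genes, truth = simulate_genome(config)
ip, total = simulate_coverage(genome, truth, config, "F")

params = StatParams()  # 51-nt window over 2001-nt window, step 25, alpha 1e-4
track = call_condition(ip, total, params)
sig = significant_positions(track, params)

print(f"fitted null: mu_hat={track.mu_hat:.3e}  sigma_hat={track.sigma_hat:.3e}")
print(f"significant grid positions (adjusted P <= {params.alpha:g}): {len(sig)}")

print("\nplanted summit -> nearest significant position (distance):")
sig_pos = np.array([p for p, _, _ in sig])
for site in truth.sites:
    i = np.abs(sig_pos - site.summit_position).argmin()
    print(f"  {site.gene_id}: {site.summit_position:>7d} -> {sig_pos[i]:>7d} "
          f"({sig_pos[i] - site.summit_position:+d} nt)")
# Each planted summit should have a significant grid position within one
# 25-nt grid step; positions elsewhere on the chromosome stay quiet.
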