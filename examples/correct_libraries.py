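"""Ratio-correct ribo-minus TPMs into polyA+ space on a simulated pair.

Simulates six polyA-selected and six rRNA-depleted replicate libraries from
the same ground truth, computes the per-gene ratio of median TPMs, applies
it, and shows how the library-type bias disappears.
"""

import numpy as np

from ribopolya import (
    SimulationConfig,
    apply_correction,
    cliffs_delta,
    compute_ratios,
    correlate,
    generate_truth,
    median_profile,
    simulate_libraries,
)
from ribopolya.stats import paired_log2_values

config = SimulationConfig(n_genes=5000, seed=7)
truth = generate_truth(config)
polya = simulate_libraries(truth, "polyA", config)
ribo = simulate_libraries(truth, "ribominus", config)

ratios = compute_ratios(polya, ribo)
corrected = apply_correction(ribo, ratios)

med_p, med_r, med_c = (median_profile(m) for m in (polya, ribo, corrected))
for label, other in (("uncorrected", med_r), ("corrected", med_c)):
    x, y = paired_log2_values(med_p, other)
    r, _ = correlate(x, y)
    delta = cliffs_delta(x, y)
    print(f"{label:>11}: Pearson r = {r:.4f}, Cliff's delta = {delta.delta:+.4f} "
          f"({delta.magnitude}), n = {x.size} genes detected in both")

nz = med_r > 0
print(f"median-equality check: max |corrected median - polyA median| = "
      f"{float((med_c[nz] - med_p[nz]).abs().max()):.2e}")
# The corrected ribo-minus medians coincide with the polyA+ medians by
# construction, so the residual effect size collapses to ~0.
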