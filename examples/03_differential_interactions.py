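"""Full differential-interaction analysis on simulated Hi-C counts.

Simulates overdispersed bin-pair counts for 2 groups x 2 replicates with
10 % of intra-chromosomal bin pairs spiked at fold 4, then runs the full
chain — non-specific-ligation filter, scaling normalization, trended NB
dispersion, EB-moderated quasi-likelihood F-tests, BH correction — and
compares detections with the simulation truth.
"""

import numpy as np

from hicdelta.simhic import SimParams, evaluate_detection, simulate_counts, ql_pipeline_detect

params = SimParams()  # ~10,000 bin pairs, phi=0.05, 10% DIs at fold 4
cm, truth = simulate_counts(params, seed=1)
print(f"simulated {cm.n_pairs} bin pairs x {cm.n_libs} libraries "
      f"({truth.is_di.sum()} true differential interactions)")

groups = ["g1", "g1", "g2", "g2"]
keep, detected, res = ql_pipeline_detect(cm, groups, nominal_fdr=0.05)
print(f"filter kept {keep.sum()} bin pairs above 5x the non-specific ligation rate")
print(f"detected {detected.sum()} differential interactions at 5% FDR")

fdr, tp = evaluate_detection(detected, truth.is_di)
print(f"observed FDR {fdr:.3f}, true positives {tp} "
      f"of {truth.is_di[keep].sum()} testable true DIs")

top = res.table.sort_values("pvalue").head(5)
print("\nstrongest differential interactions (log2 fold change, F, p, FDR):")
print(top.to_string(float_format=lambda v: f"{v:.3g}"))
# logFC near +/-2 matches the simulated fold of 4; the observed FDR at or
# below the nominal 5% is the point of the quasi-likelihood machinery.
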