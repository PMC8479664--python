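"""Sample-adapted expression profiles.

The bulk sample's cancer cells express 10% of genes differently from the
single-cell reference (log-normal fold noise, sd 0.5).  Because the joint
model shares profiles between the reference and the bulk, the fitted
cancer profile adapts toward the sample's true state instead of copying
the reference: on the perturbed genes it correlates better with the truth
than the raw reference mean does.
"""

import numpy as np
from scipy.stats import spearmanr

from prism import fit_joint, simulate_cohort

bundle = simulate_cohort("perturbed-profiles", seed=3)
result = fit_joint(bundle.reference, bundle.labels, bundle.bulk)

genes = bundle.bulk_truth.perturbed_genes[0]
truth = bundle.bulk_truth.perturbed_X[genes, 0, 0]
cancer_cells = np.flatnonzero(bundle.labels.type_index() == 0)
ref_mean = bundle.reference.values[np.ix_(genes, cancer_cells)].mean(axis=1)

rho_fit = spearmanr(result.X[genes, 0], truth).statistic
rho_ref = spearmanr(ref_mean, truth).statistic
print(f"{len(genes)} perturbed genes; cancer fraction "
      f"{bundle.bulk_truth.params.W[0, 0]:.2f}")
print(f"Spearman(fitted profile, perturbed truth):    {rho_fit:.3f}")
print(f"Spearman(reference mean, perturbed truth):    {rho_ref:.3f}")
print("the adapted profile tracks the sample-specific expression state")
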