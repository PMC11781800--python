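"""Residualize, reduce, and decompose a cohort into latent components.

Runs confound residualization, per-modality PCA at the 50% variance
threshold, and the PLS correlation, then prints singular values, covariance
explained, composite-score correlations, and how well the planted saliences
were recovered.
"""

import numpy as np

import bbpls
from bbpls.preprocess import residualize_dataset

cfg = bbpls.SyntheticConfig(
    n_subjects=800, n_sites=4, n_parcels_cortical=60, n_parcels_subcortical=8,
    n_items=40, n_latent=3, latent_strength=(5.0, 3.0, 2.0), seed=1,
)
dataset, truth = bbpls.generate_dataset(cfg)

blocks, behavior = residualize_dataset(dataset)
model, X = bbpls.fit_reduction(blocks, variance_threshold=0.5)
print("retained components per modality:", model.retained_counts)

result = bbpls.pls_decompose(X, behavior)
print("\nfirst three latent components:")
for k in range(3):
    print(f"  LC{k+1}: singular value {result.singular_values[k]:8.1f}, "
          f"covariance explained {100*result.covariance_explained[k]:5.1f}%, "
          f"corr(LX, LY) = {result.lc_correlations[k]:.2f}")
print("(covariance explained decreases with the planted strengths 5/3/2;")
print(" the composite-score correlation is each component's effect size)")

print("\nplanted-salience recovery, |cosine(recovered, truth)|:")
for k in range(3):
    c = abs(truth.behavior_saliences[:, k] @ result.U[:, k])
    print(f"  behavior LC{k+1}: {c:.3f}")

for m in model.order:
    contrib = bbpls.modality_contribution(result, X, m)
    print(f"modality contribution of {m:10s} to LC1: {contrib[0]:.2f}")
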