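"""Out-of-sample generalization by discovery-to-replication weight transfer.

Fits PCA + PLS on a discovery arm, freezes all weights, applies them to an
independent replication arm drawn from the same generative truth, and
compares within-sample to cross-validated effect sizes.
"""

import numpy as np

import bbpls
from bbpls.preprocess import residualize_dataset

cfg = bbpls.SyntheticConfig(
    n_subjects=2000, n_sites=4, n_parcels_cortical=30, n_parcels_subcortical=5,
    n_items=30, n_latent=3, latent_strength=(5.0, 3.0, 2.0), seed=4,
)
dataset, _ = bbpls.generate_dataset(cfg)
blocks, behavior = residualize_dataset(dataset)
disc = np.arange(1000)
repl = np.arange(1000, 2000)

dblocks = {m: b.iloc[disc] for m, b in blocks.items()}
rblocks = {m: b.iloc[repl] for m, b in blocks.items()}
model, X = bbpls.fit_reduction(dblocks, 0.5)
result = bbpls.pls_decompose(X, behavior.iloc[disc])

tm = bbpls.fit_transfer(model, X.to_numpy(), behavior.iloc[disc])
transfer = bbpls.transfer_scores(tm, rblocks, behavior.iloc[repl])
r_obs, p, q = bbpls.transfer_significance(
    tm, rblocks, behavior.iloc[repl],
    dataset.covariates["site"].to_numpy()[repl], n_perm=199, k_test=3, seed=0,
)

print("component   within-sample r   out-of-sample r   permuted p (FDR q)")
for k in range(3):
    print(f"  LC{k+1}          {result.lc_correlations[k]:.3f}            "
          f"{transfer.lc_correlations[k]:.3f}          {p[k]:.3f} ({q[k]:.3f})")
print("\n(out-of-sample r is slightly below the within-sample value — the"
      " optimism gap — but remains significant against the site-aware null;"
      " with real cohorts the gap is far larger because imaging effects are"
      " weak and sample-specific)")

posthoc = bbpls.demographic_posthoc(
    __import__("pandas").DataFrame(result.LX[:, :2], index=behavior.iloc[disc].index,
                                   columns=["LX1", "LX2"]),
    dataset.covariates.iloc[disc],
)
n_sig = int(posthoc["significant"].sum())
print(f"demographic post hocs (sex t-tests, age/age^2 correlations): "
      f"{n_sig}/{len(posthoc)} significant after FDR — residualization removed them")
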