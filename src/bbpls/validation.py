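"""Validation studies: parameter recovery and calibration on synthetic cohorts.

Each function runs a self-contained simulation study at a fixed problem
size and returns the measured quantities (recovery cosines, type-I rates,
CI coverage, spin-test calibration, out-of-sample correlations). They are
the package's evidence that every stage behaves as designed; the test
suite asserts bands on their outputs and ``scripts/acceptance.py`` reports
them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .gradients import build_affinity, diffusion_embed
from .inference import bootstrap_loadings, permutation_test
from .pls import pls_decompose
from .preprocess import (
    build_design,
    drop_invariant_items,
    modality_covariates,
    residualize,
)
from .reduction import fit_reduction
from .generalize import fit_transfer, transfer_scores
from .spatial import spin_correlation, spin_permutation
from .synth import (
    SyntheticConfig,
    generate_dataset,
    generate_parcellation_assets,
    generate_smooth_map,
)
from .utils import devectorize_edges


def _residualized(dataset):
    blocks = {m: residualize(b, dataset.covariates, modality_covariates(m))
              for m, b in dataset.modality_blocks.items()}
    kept, _ = drop_invariant_items(dataset.behavior)
    behavior = residualize(kept.astype(float), dataset.covariates,
                           modality_covariates("behavior"))
    return blocks, behavior


def pls_recovery_study(
    seed: int = 0,
    n_subjects: int = 2000,
    n_parcels_cortical: int = 90,
    n_parcels_subcortical: int = 10,
    n_items: int = 60,
    strengths: tuple[float, ...] = (5.0, 3.0, 2.0),
) -> dict:
    """Recover three planted latent components through the full pipeline.

    Returns per-component |cosine| between recovered and planted behavior
    saliences (item space) and imaging saliences (compared within the
    retained PCA span, where the fitted salience lives), plus the
    covariance-explained profile.
    """
    cfg = SyntheticConfig(
        n_subjects=n_subjects, n_sites=5, n_parcels_cortical=n_parcels_cortical,
        n_parcels_subcortical=n_parcels_subcortical, n_items=n_items,
        n_latent=len(strengths), latent_strength=strengths, seed=seed,
    )
    dataset, truth = generate_dataset(cfg)
    blocks, behavior = _residualized(dataset)
    model, X = fit_reduction(blocks, 0.5)
    res = pls_decompose(X, behavior)
    K = len(strengths)
    u_cos = [abs(float(truth.behavior_saliences[:, k] @ res.U[:, k])) for k in range(K)]
    off, vt = 0, []
    for m in model.order:
        L = model.entries[m].loadings
        vt.append(L.T @ truth.imaging_saliences[off:off + L.shape[0]])
        off += L.shape[0]
    vt = np.vstack(vt)
    vt = vt / np.linalg.norm(vt, axis=0)
    v_cos = [abs(float(vt[:, k] @ res.V[:, k])) for k in range(K)]
    return {
        "behavior_cosines": u_cos,
        "imaging_cosines": v_cos,
        "covariance_explained": res.covariance_explained[:K].tolist(),
        "lc_correlations": res.lc_correlations[:K].tolist(),
        "n": n_subjects,
    }


def permutation_calibration_study(
    seed: int = 0, n_replicates: int = 500, n_subjects: int = 300, n_perm: int = 99
) -> dict:
    """Type-I error of the site-restricted permutation test of the leading
    component under a null generator (site shifts, no planted signal)."""
    rejections = 0
    for rep in range(n_replicates):
        cfg = SyntheticConfig(
            n_subjects=n_subjects, n_sites=3, n_parcels_cortical=12,
            n_parcels_subcortical=3, n_items=20, n_latent=3,
            latent_strength=(0.0, 0.0, 0.0), confound_strength=0.0,
            site_effect_strength=1.0, seed=seed + rep,
        )
        dataset, _ = generate_dataset(cfg)
        blocks, behavior = _residualized(dataset)
        design = build_design(dataset.covariates,
                              modality_covariates("behavior")).to_numpy()
        X = np.hstack([blocks[m].to_numpy() for m in blocks])
        pr = permutation_test(X, behavior, dataset.covariates["site"].to_numpy(),
                              n_perm=n_perm, k_test=1, seed=seed + rep, design=design)
        rejections += pr.p_values[0] <= 0.05
    return {"rejection_rate": rejections / n_replicates, "n": n_replicates}


def bootstrap_coverage_study(
    seed: int = 0, n_replicates: int = 100, n_subjects: int = 1000, n_boot: int = 200
) -> dict:
    """Coverage of 95% percentile bootstrap CIs for a planted item loading.

    Items load equally on one latent factor with a coefficient chosen so the
    population correlation between an item and the behavior composite score
    is 0.6; sampling is site-restricted across 4 sites.
    """
    I, J = 15, 10
    t = 0.46  # squared item-factor coefficient; yields loading 0.6 (closed form)
    target = (I * t + 1) / np.sqrt((1 + t) * (I * I * t + I))
    b = np.sqrt(t)
    covered = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        z = rng.standard_normal(n_subjects)
        X = 2.0 * z[:, None] * np.ones(J) / np.sqrt(J) + rng.standard_normal((n_subjects, J))
        Y = b * z[:, None] + rng.standard_normal((n_subjects, I))
        sites = np.repeat(np.arange(4), n_subjects // 4)
        res = bootstrap_loadings(X, Y, sites, n_boot=n_boot, seed=seed + 10_000 + rep)
        lo = res.ci_low["behavior"][0, 0]
        hi = res.ci_high["behavior"][0, 0]
        covered += lo <= target <= hi
    return {"coverage": covered / n_replicates, "target_loading": float(target),
            "n": n_replicates}


def gradient_recovery_study(seed: int = 0) -> dict:
    """Recover a planted 1D connectivity axis and the ring-lattice geometry."""
    cfg = SyntheticConfig(
        n_subjects=120, n_sites=3, n_parcels_cortical=80, n_parcels_subcortical=10,
        n_items=12, gradient_strength=3.0, seed=seed,
    )
    dataset, truth = generate_dataset(cfg)
    P = cfg.n_parcels_total
    C = devectorize_edges(dataset.modality_blocks["rsfc"].to_numpy().mean(0), P, diag=1.0)
    grad = diffusion_embed(build_affinity(C, 0.10), alpha=0.5, t=0.0, n_gradients=5)
    rho = stats.spearmanr(grad.embedding[:, 0], truth.planted_gradient).statistic

    n = 60
    ring = np.zeros((n, n))
    for i in range(n):
        for d, w in ((1, 1.0), (2, 0.5)):
            ring[i, (i + d) % n] = ring[(i + d) % n, i] = w
    g = diffusion_embed(ring, alpha=0.5, t=0.0, n_gradients=3)
    theta = 2 * np.pi * np.arange(n) / n
    th_hat = np.arctan2(g.embedding[:, 1], g.embedding[:, 0])
    circ = max(abs(np.mean(np.exp(1j * (th_hat - theta)))),
               abs(np.mean(np.exp(1j * (th_hat + theta)))))
    return {
        "gradient_spearman": abs(float(rho)),
        "ring_circular_correlation": float(circ),
        "variance_explained_g1": float(grad.variance_explained[0]),
        "n": P,
    }


def spin_calibration_study(
    seed: int = 0, n_replicates: int = 200, n_spin: int = 99, fwhm: float = 60.0
) -> dict:
    """Spin-test calibration on independent smooth maps vs the naive test.

    Returns the KS p-value of the spin p-value distribution against uniform,
    plus rejection rates of the spin and naive parametric tests at 0.05.
    """
    cfg = SyntheticConfig(n_parcels_cortical=100, n_parcels_subcortical=5,
                          n_items=10, n_subjects=10, seed=seed)
    _, coords = generate_parcellation_assets(cfg)
    ctx = coords.cortical()
    spins = spin_permutation(coords, n_spin, seed=seed)
    p_spin, p_naive = [], []
    base = np.random.default_rng(seed).integers(0, 2**31 - 2, size=2 * n_replicates)
    for rep in range(n_replicates):
        a = generate_smooth_map(ctx, fwhm, int(base[2 * rep]))
        bmap = generate_smooth_map(ctx, fwhm, int(base[2 * rep + 1]))
        p_spin.append(spin_correlation(a, bmap, spins).p_spin)
        p_naive.append(stats.pearsonr(a, bmap).pvalue)
    p_spin, p_naive = np.array(p_spin), np.array(p_naive)
    return {
        "ks_pvalue": float(stats.kstest(p_spin, "uniform").pvalue),
        "spin_rejection_rate": float((p_spin <= 0.05).mean()),
        "naive_rejection_rate": float((p_naive < 0.05).mean()),
        "n": n_replicates,
    }


def transfer_study(seed: int = 0, n_per_arm: int = 2000) -> dict:
    """Out-of-sample transfer contract on same-truth and null cohorts."""
    cfg = SyntheticConfig(
        n_subjects=2 * n_per_arm, n_sites=4, n_parcels_cortical=30,
        n_parcels_subcortical=5, n_items=30, n_latent=3,
        latent_strength=(5.0, 3.0, 2.0), confound_strength=0.5, seed=seed,
    )
    dataset, _ = generate_dataset(cfg)
    blocks, behavior = _residualized(dataset)
    disc = np.arange(n_per_arm)
    repl = np.arange(n_per_arm, 2 * n_per_arm)
    dblocks = {m: b.iloc[disc] for m, b in blocks.items()}
    rblocks = {m: b.iloc[repl] for m, b in blocks.items()}
    model, X = fit_reduction(dblocks, 0.5)
    res = pls_decompose(X, behavior.iloc[disc])
    tm = fit_transfer(model, X.to_numpy(), behavior.iloc[disc])
    self_t = transfer_scores(tm, dblocks, behavior.iloc[disc])
    t = transfer_scores(tm, rblocks, behavior.iloc[repl])

    cfg0 = SyntheticConfig(
        n_subjects=2 * n_per_arm, n_sites=4, n_parcels_cortical=16,
        n_parcels_subcortical=4, n_items=16, n_latent=3,
        latent_strength=(0.0, 0.0, 0.0), confound_strength=0.5, seed=seed + 1,
    )
    dataset0, _ = generate_dataset(cfg0)
    blocks0, behavior0 = _residualized(dataset0)
    model0, X0 = fit_reduction({m: b.iloc[disc] for m, b in blocks0.items()}, 0.5)
    tm0 = fit_transfer(model0, X0.to_numpy(), behavior0.iloc[disc])
    t0 = transfer_scores(tm0, {m: b.iloc[repl] for m, b in blocks0.items()},
                         behavior0.iloc[repl])
    return {
        "within_sample_r": res.lc_correlations[:3].tolist(),
        "out_of_sample_r": t.lc_correlations[:3].tolist(),
        "max_gap": float(np.abs(res.lc_correlations[:3] - t.lc_correlations[:3]).max()),
        "self_transfer_max_error": float(np.abs(self_t.LX - res.LX).max()),
        "null_oos_r1": float(t0.lc_correlations[0]),
        "n": n_per_arm,
    }
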