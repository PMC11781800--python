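"""PLS correlation core: oracle equivalence, loadings, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bbpls
from bbpls.pls import covariance_explained, modality_contribution, pls_decompose, project_loadings_back
from bbpls.reduction import ReducedMatrix
from bbpls.utils import zscore


def test_singular_values_match_eigendecomposition_oracle(rng):
    """SVD singular values equal sqrt of eigenvalues of R R' on random problems."""
    for _ in range(50):
        X = rng.standard_normal((40, 30))
        Y = rng.standard_normal((40, 20))
        res = pls_decompose(X, Y)
        R = zscore(Y).T @ zscore(X)
        eig = np.sort(np.linalg.eigvalsh(R @ R.T))[::-1]
        np.testing.assert_allclose(res.singular_values, np.sqrt(np.clip(eig, 0, None)),
                                   rtol=1e-10, atol=1e-8)


def test_loadings_match_per_feature_correlation_loop(rng):
    X = rng.standard_normal((60, 12))
    Y = rng.standard_normal((60, 8))
    res = pls_decompose(X, Y)
    loop = np.empty_like(res.behavior_loadings)
    for i in range(Y.shape[1]):
        for k in range(res.n_components):
            loop[i, k] = stats.pearsonr(Y[:, i], res.LY[:, k]).statistic
    np.testing.assert_allclose(res.behavior_loadings, loop, atol=1e-10)


def test_rank_one_limit(rng):
    n = 500
    x = rng.standard_normal((n, 6))
    for noise in (0.5, 0.1, 0.01):
        y = np.column_stack([2 * x[:, 0] + noise * rng.standard_normal(n),
                             -x[:, 0] + noise * rng.standard_normal(n)])
        res = pls_decompose(x, y)
        r1 = abs(np.corrcoef(res.LX[:, 0], res.LY[:, 0])[0, 1])
        assert r1 > 1 - 2 * noise
    assert res.covariance_explained[0] > 0.95


def test_independent_blocks_yield_flat_spectrum():
    """Under the null no component dominates and composite correlations vanish."""
    gen = np.random.default_rng(2024)
    # composite correlations scale as (sqrt(I)+sqrt(F))/sqrt(n): tiny here
    res = pls_decompose(gen.standard_normal((20_000, 9)), gen.standard_normal((20_000, 4)))
    assert np.abs(res.lc_correlations).max() < 0.05
    # with many components the covariance shares stay within random-matrix
    # spread: max share far below dominance (uniform share is 0.01 here)
    res_wide = pls_decompose(gen.standard_normal((20_000, 100)),
                             gen.standard_normal((20_000, 100)))
    assert res_wide.covariance_explained.max() < 0.05


def test_recovers_planted_saliences(strong_fit):
    truth, res, model, X = (strong_fit["truth"], strong_fit["result"],
                            strong_fit["model"], strong_fit["X"])
    for k in range(3):
        assert abs(truth.behavior_saliences[:, k] @ res.U[:, k]) > 0.9
    # compare imaging saliences inside the retained PCA span
    off, Vt = 0, []
    for m in model.order:
        L = model.entries[m].loadings
        Vt.append(L.T @ truth.imaging_saliences[off:off + L.shape[0]])
        off += L.shape[0]
    Vt = np.vstack(Vt)
    Vt /= np.linalg.norm(Vt, axis=0)
    for k in range(3):
        assert abs(Vt[:, k] @ res.V[:, k]) > 0.9
    assert list(res.covariance_explained[:3]) == sorted(res.covariance_explained[:3],
                                                        reverse=True)


def test_subject_permutation_invariance(rng):
    X = rng.standard_normal((80, 6))
    Y = rng.standard_normal((80, 5))
    perm = rng.permutation(80)
    a = pls_decompose(X, Y)
    b = pls_decompose(X[perm], Y[perm])
    np.testing.assert_allclose(a.singular_values, b.singular_values, atol=1e-10)
    np.testing.assert_allclose(a.U, b.U, atol=1e-8)
    np.testing.assert_allclose(a.LX[perm], b.LX, atol=1e-8)


def test_composite_scores_mutually_uncorrelated(strong_fit):
    res = strong_fit["result"]
    k = 3  # well-separated singular values
    for scores in (res.LX, res.LY):
        c = np.corrcoef(scores[:, :k].T)
        off = c[~np.eye(k, dtype=bool)]
        assert np.abs(off).max() < 0.05


def test_sign_convention_largest_behavior_loading_positive(rng):
    for seed in range(5):
        r = np.random.default_rng(seed)
        res = pls_decompose(r.standard_normal((50, 7)), r.standard_normal((50, 6)))
        for k in range(res.n_components):
            col = res.behavior_loadings[:, k]
            assert col[np.argmax(np.abs(col))] > 0


def test_zero_variance_column_raises(rng):
    X = rng.standard_normal((30, 4))
    Y = rng.standard_normal((30, 3))
    Y[:, 1] = 2.0
    with pytest.raises(ValueError, match="zero-variance"):
        pls_decompose(X, Y)


@pytest.mark.parametrize(
    "s, expected",
    [
        ([4.0], [1.0]),
        ([2, 2, 2, 2], [0.25] * 4),
        (np.sqrt([21, 4, 3, 3, 2]), [21 / 33, 4 / 33, 3 / 33, 3 / 33, 2 / 33]),
    ],
)
def test_covariance_explained_arithmetic(s, expected):
    np.testing.assert_allclose(covariance_explained(np.asarray(s, float)), expected,
                               atol=1e-12)


def test_covariance_explained_rejects_all_zero():
    with pytest.raises(ValueError):
        covariance_explained(np.zeros(3))


class TestModalityContribution:
    def test_single_modality_gives_one(self, rng):
        X = ReducedMatrix(pd.DataFrame(rng.standard_normal((60, 5)),
                                       columns=[f"area:PC{i}" for i in range(5)]))
        res = pls_decompose(X, rng.standard_normal((60, 4)))
        np.testing.assert_allclose(modality_contribution(res, X, "area"), 1.0, atol=1e-10)

    def test_two_equal_modalities_contribute_inverse_sqrt_two(self, rng):
        # orthogonal equal-norm salience halves: each modality composite
        # carries half the variance of the full composite
        n = 20_000
        za, zb = rng.standard_normal(n), rng.standard_normal(n)
        X = ReducedMatrix(pd.DataFrame(np.column_stack([za, zb]),
                                       columns=["area:PC1", "rsfc:PC1"]))
        y = za + zb + 0.05 * rng.standard_normal(n)
        res = pls_decompose(X, y[:, None])
        for m in ("area", "rsfc"):
            contrib = modality_contribution(res, X, m)[0]
            assert abs(contrib - 1 / np.sqrt(2)) < 0.03

    def test_unknown_modality_raises(self, rng):
        X = ReducedMatrix(pd.DataFrame(rng.standard_normal((30, 2)),
                                       columns=["area:PC1", "area:PC2"]))
        res = pls_decompose(X, rng.standard_normal((30, 3)))
        with pytest.raises(ValueError):
            modality_contribution(res, X, "volume")

    def test_zeroed_modality_reports_zero_with_flag(self, rng):
        X = ReducedMatrix(pd.DataFrame(rng.standard_normal((30, 3)),
                                       columns=["area:PC1", "area:PC2", "rsfc:PC1"]))
        res = pls_decompose(X, rng.standard_normal((30, 2)))
        res.V[2] = 0.0  # force the rsfc rows of V to zero
        contrib = modality_contribution(res, X, "rsfc")
        assert (contrib == 0).all()
        assert any("zero-variance" in f for f in res.degenerate_flags)


class TestProjectLoadingsBack:
    def test_feature_equal_to_composite_loads_one(self, rng):
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal((40, 4))
        res = pls_decompose(X, Y)
        maps = project_loadings_back(res, {"probe": res.LX[:, [0]]})
        assert abs(maps["probe"][0, 0] - 1.0) < 1e-10

    def test_orthogonal_feature_loads_zero(self, rng):
        X = rng.standard_normal((300, 5))
        Y = rng.standard_normal((300, 4))
        res = pls_decompose(X, Y)
        probe = rng.standard_normal((300, 1))
        probe -= res.LX @ np.linalg.lstsq(res.LX, probe, rcond=None)[0]
        maps = project_loadings_back(res, {"probe": probe})
        assert np.abs(maps["probe"]).max() < 1e-8

    def test_matches_bruteforce_loop(self, strong_fit):
        res = strong_fit["result"]
        block = strong_fit["blocks"]["thickness"].to_numpy()
        maps = project_loadings_back(res, {"thickness": block})
        for f in (0, 5, 11):
            for k in (0, 2):
                r = stats.pearsonr(block[:, f], res.LX[:, k]).statistic
                assert abs(maps["thickness"][f, k] - r) < 1e-10
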