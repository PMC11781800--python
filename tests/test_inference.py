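"""Site-restricted permutation/bootstrap inference, block averaging, FDR."""

import numpy as np
import pandas as pd
import pytest

import bbpls
from bbpls.containers import NetworkPartition
from bbpls.inference import (
    block_average_edges,
    block_labels,
    bootstrap_loadings,
    bootstrap_within_site,
    fdr_bh,
    permutation_test,
    permute_within_site,
)


class TestPermuteWithinSite:
    def test_site_membership_preserved(self, rng):
        sites = np.array(["a"] * 5 + ["b"] * 7 + ["c"] * 3)
        for _ in range(20):
            perm = permute_within_site(sites, rng)
            assert (sites[perm] == sites).all()
            assert sorted(perm) == list(range(15))

    def test_singleton_sites_force_identity(self, rng):
        sites = np.array([f"s{i}" for i in range(10)])
        for _ in range(5):
            np.testing.assert_array_equal(permute_within_site(sites, rng),
                                          np.arange(10))

    def test_reachable_permutation_support(self, rng):
        # sites of sizes 3 and 4: exactly 3! * 4! = 144 reachable permutations
        sites = np.array(["a"] * 3 + ["b"] * 4)
        seen = {tuple(permute_within_site(sites, rng)) for _ in range(10_000)}
        assert len(seen) > 0.95 * 144
        assert len(seen) <= 144


class TestPermutationTest:
    def test_strong_signal_attains_minimum_p(self, rng):
        n = 1000
        z = rng.standard_normal(n)
        X = np.outer(z, np.ones(5)) + 0.3 * rng.standard_normal((n, 5))
        Y = np.outer(z, np.ones(4)) + 0.3 * rng.standard_normal((n, 4))
        sites = np.repeat(["a", "b"], n // 2)
        res = permutation_test(X, Y, sites, n_perm=199, k_test=1, seed=0)
        assert res.p_values[0] == pytest.approx(1 / 200)

    def test_observed_below_null_gives_p_one(self, rng):
        # constant-ish Y after permutation always beats an anti-selected stat:
        # force it by checking the add-one convention directly on the null matrix
        n = 60
        X = rng.standard_normal((n, 4))
        Y = rng.standard_normal((n, 3))
        sites = np.array(["a"] * n)
        res = permutation_test(X, Y, sites, n_perm=99, k_test=2, seed=1)
        assert np.all(res.p_values > 0) and np.all(res.p_values <= 1)
        worst = (1 + res.n_perm) / (1 + res.n_perm)
        assert ((1 + (res.null_distribution >= res.observed).sum(0)) / (1 + res.n_perm)
                <= worst).all()

    def test_first_null_dominates_fifth(self, rng):
        n = 300
        X = rng.standard_normal((n, 12))
        Y = rng.standard_normal((n, 8))
        sites = np.repeat(["a", "b", "c"], n // 3)
        res = permutation_test(X, Y, sites, n_perm=60, k_test=5, seed=2)
        assert np.median(res.null_distribution[:, 0]) > np.median(res.null_distribution[:, 4])

    def test_site_restriction_controls_site_confounding(self):
        """With strong site shifts and no signal, unrestricted permutation is
        anticonservative relative to site-restricted permutation."""
        rejections = {"restricted": 0, "free": 0}
        reps = 60
        for rep in range(reps):
            r = np.random.default_rng(rep)
            n = 120
            sites = np.repeat([f"s{i}" for i in range(3)], n // 3)
            shift = {f"s{i}": v for i, v in enumerate((-2.0, 0.0, 2.0))}
            site_eff = np.array([shift[s] for s in sites])
            X = site_eff[:, None] * r.uniform(0.5, 1, 6) + r.standard_normal((n, 6))
            Y = site_eff[:, None] * r.uniform(0.5, 1, 5) + r.standard_normal((n, 5))
            res_r = permutation_test(X, Y, sites, n_perm=99, k_test=1, seed=rep)
            res_f = permutation_test(X, Y, np.array(["all"] * n), n_perm=99,
                                     k_test=1, seed=rep)
            rejections["restricted"] += res_r.p_values[0] <= 0.05
            rejections["free"] += res_f.p_values[0] <= 0.05
        assert rejections["free"] > rejections["restricted"]
        assert rejections["free"] / reps > 0.5
        assert rejections["restricted"] / reps < 0.2


class TestBootstrap:
    def test_resampling_respects_site_sizes(self, rng):
        sites = np.array(["a"] * 6 + ["b"] * 9)
        for _ in range(10):
            idx = bootstrap_within_site(sites, rng)
            assert (sites[idx] == sites).all()

    def test_degenerate_loading_flagged_significant(self, rng):
        n = 80
        z = rng.standard_normal(n)
        X = np.outer(z, [1.0, 0.5]) + 0.01 * rng.standard_normal((n, 2))
        Y = np.outer(z, [1.0, -0.4]) + 0.01 * rng.standard_normal((n, 2))
        sites = np.array(["a"] * n)
        res = bootstrap_loadings(X, Y, sites, n_boot=30, seed=0)
        # near-deterministic loading: tiny SD, huge Z, still significant
        assert res.fdr_mask["behavior"][0, 0]

    def test_bootstrap_sd_tracks_sampling_sd(self):
        """Bootstrap SD of a loading approximates the across-replicate
        sampling SD of that loading (moderate n, strong signal)."""
        def one(seed, n=400):
            r = np.random.default_rng(seed)
            z = r.standard_normal(n)
            X = 1.5 * z[:, None] * np.ones(4) + r.standard_normal((n, 4))
            Y = 0.8 * z[:, None] * np.ones(6) + r.standard_normal((n, 6))
            return X, Y

        loadings = []
        for seed in range(60):
            X, Y = one(seed)
            loadings.append(bbpls.pls_decompose(X, Y).behavior_loadings[0, 0])
        sampling_sd = np.std(loadings, ddof=1)
        X, Y = one(123)
        res = bootstrap_loadings(X, Y, np.array(["a"] * 400), n_boot=400, seed=5)
        assert abs(res.loading_sd["behavior"][0, 0] / sampling_sd - 1) < 0.35

    def test_null_fdr_mask_mostly_empty(self):
        empty = 0
        for rep in range(25):
            r = np.random.default_rng(100 + rep)
            X = r.standard_normal((200, 8))
            Y = r.standard_normal((200, 20))
            sites = np.repeat(["a", "b"], 100)
            res = bootstrap_loadings(X, Y, sites, n_boot=200, seed=rep)
            empty += not res.fdr_mask["behavior"].any()
        assert empty >= 22


class TestBlockAverage:
    @pytest.fixture()
    def partition18(self):
        labels = []
        for b in range(18):
            labels += [f"n{b:02d}"] * 4
        ids = pd.Index([f"p{i}" for i in range(72)])
        return NetworkPartition(pd.Series(labels, index=ids))

    def test_18_networks_give_171_blocks(self, partition18):
        assert len(block_labels(partition18)) == 18 + 18 * 17 // 2

    def test_constant_loadings_give_constant_blocks(self, partition18, rng):
        W = np.full((72, 72), 0.37)
        np.fill_diagonal(W, 0.0)
        out = block_average_edges(W, partition18)
        np.testing.assert_allclose(out, 0.37, atol=1e-12)

    def test_checkerboard_two_networks(self):
        labels = pd.Series(["x"] * 3 + ["y"] * 3, index=[f"p{i}" for i in range(6)])
        part = NetworkPartition(labels)
        same = np.array([[l1 == l2 for l2 in labels] for l1 in labels])
        W = np.where(same, 1.0, -1.0).astype(float)
        np.fill_diagonal(W, 0.0)
        out = block_average_edges(W, part)
        np.testing.assert_allclose(np.diag(out), 1.0)
        assert out[0, 1] == pytest.approx(-1.0)

    def test_singleton_network_within_block_is_nan(self):
        labels = pd.Series(["x", "x", "solo"], index=["a", "b", "c"])
        part = NetworkPartition(labels)
        W = np.ones((3, 3)) - np.eye(3)
        out = block_average_edges(W, part)
        nets = part.networks
        i = nets.index("solo")
        assert np.isnan(out[i, i])


class TestFdrBH:
    def test_all_small_p_all_rejected(self):
        reject, _ = fdr_bh(np.full(10, 0.001), 0.05)
        assert reject.all()

    def test_single_p_reduces_to_raw_threshold(self):
        reject, adj = fdr_bh(np.array([0.04]), 0.05)
        assert reject[0] and adj[0] == pytest.approx(0.04)

    def test_stepup_hand_oracle(self):
        # p=(0.01,0.02,0.03,0.5): thresholds q*k/m = (0.0125,0.025,0.0375,0.05)
        reject, adj = fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]), 0.05)
        np.testing.assert_array_equal(reject, [True, True, True, False])
        np.testing.assert_allclose(adj[:3], [0.04, 0.04, 0.04])

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.1, 1.2]))
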