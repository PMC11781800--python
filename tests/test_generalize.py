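"""Out-of-sample transfer, replication comparison, held-out associations, post hocs."""

import hashlib
import pickle

import numpy as np
import pandas as pd
import pytest

import bbpls
from bbpls.generalize import (
    compare_loadings,
    demographic_posthoc,
    fit_transfer,
    heldout_association,
    transfer_scores,
    transfer_significance,
)
from bbpls.preprocess import residualize_dataset


@pytest.fixture(scope="module")
def twin_cohorts():
    """One generative truth, two disjoint subject samples."""
    cfg = bbpls.SyntheticConfig(
        n_subjects=2400, n_sites=4, n_parcels_cortical=24, n_parcels_subcortical=4,
        n_items=20, n_latent=3, latent_strength=(5.0, 3.0, 2.0),
        confound_strength=0.5, seed=31,
    )
    dataset, truth = bbpls.generate_dataset(cfg)
    blocks, behavior = residualize_dataset(dataset)
    disc = np.arange(1200)
    repl = np.arange(1200, 2400)
    d = dict(blocks={m: b.iloc[disc] for m, b in blocks.items()},
             behavior=behavior.iloc[disc],
             sites=dataset.covariates["site"].to_numpy()[disc])
    r = dict(blocks={m: b.iloc[repl] for m, b in blocks.items()},
             behavior=behavior.iloc[repl],
             sites=dataset.covariates["site"].to_numpy()[repl])
    model, X = bbpls.fit_reduction(d["blocks"], 0.5)
    res = bbpls.pls_decompose(X, d["behavior"])
    tm = fit_transfer(model, X.to_numpy(), d["behavior"])
    return dict(cfg=cfg, truth=truth, disc=d, repl=r, model=model, X=X,
                result=res, transfer_model=tm)


class TestTransferScores:
    def test_self_transfer_reproduces_within_sample_scores(self, twin_cohorts):
        t = transfer_scores(twin_cohorts["transfer_model"], twin_cohorts["disc"]["blocks"],
                            twin_cohorts["disc"]["behavior"])
        np.testing.assert_allclose(t.LX, twin_cohorts["result"].LX, atol=1e-8)
        np.testing.assert_allclose(t.LY, twin_cohorts["result"].LY, atol=1e-8)

    def test_same_truth_sample_keeps_r_close_to_within_sample(self, twin_cohorts):
        t = transfer_scores(twin_cohorts["transfer_model"], twin_cohorts["repl"]["blocks"],
                            twin_cohorts["repl"]["behavior"])
        within = twin_cohorts["result"].lc_correlations[:3]
        assert (t.lc_correlations[:3] > 0).all()
        assert np.abs(within - t.lc_correlations[:3]).max() < 0.1

    def test_null_replication_gives_vanishing_r(self):
        cfg = bbpls.SyntheticConfig(
            n_subjects=2400, n_sites=4, n_parcels_cortical=16, n_parcels_subcortical=4,
            n_items=16, n_latent=3, latent_strength=(0.0, 0.0, 0.0),
            confound_strength=0.5, seed=33,
        )
        dataset, _ = bbpls.generate_dataset(cfg)
        blocks, behavior = residualize_dataset(dataset)
        disc, repl = np.arange(1200), np.arange(1200, 2400)
        model, X = bbpls.fit_reduction({m: b.iloc[disc] for m, b in blocks.items()}, 0.5)
        tm = fit_transfer(model, X.to_numpy(), behavior.iloc[disc])
        t = transfer_scores(tm, {m: b.iloc[repl] for m, b in blocks.items()},
                            behavior.iloc[repl])
        assert abs(t.lc_correlations[0]) < 2 / np.sqrt(1200)

    def test_transfer_is_strictly_out_of_sample(self, twin_cohorts):
        tm = twin_cohorts["transfer_model"]
        digest = hashlib.sha256(pickle.dumps(
            (tm.x_mean, tm.x_sd, tm.y_mean, tm.y_sd, tm.U, tm.V, tm.singular_values)
        )).hexdigest()
        # score a truncated replication sample; the model must be untouched
        blocks = {m: b.iloc[:-50] for m, b in twin_cohorts["repl"]["blocks"].items()}
        transfer_scores(tm, blocks, twin_cohorts["repl"]["behavior"].iloc[:-50])
        digest2 = hashlib.sha256(pickle.dumps(
            (tm.x_mean, tm.x_sd, tm.y_mean, tm.y_sd, tm.U, tm.V, tm.singular_values)
        )).hexdigest()
        assert digest == digest2

    def test_out_of_sample_r_not_above_within_sample_on_average(self):
        """Optimism: within-sample fit overstates out-of-sample correlation."""
        gaps = []
        for seed in range(10):
            cfg = bbpls.SyntheticConfig(
                n_subjects=600, n_sites=2, n_parcels_cortical=10,
                n_parcels_subcortical=2, n_items=10, n_latent=1,
                latent_strength=(2.0,), confound_strength=0.0, seed=400 + seed,
            )
            dataset, _ = bbpls.generate_dataset(cfg)
            blocks, behavior = residualize_dataset(dataset)
            disc, repl = np.arange(300), np.arange(300, 600)
            model, X = bbpls.fit_reduction({m: b.iloc[disc] for m, b in blocks.items()}, 0.5)
            res = bbpls.pls_decompose(X, behavior.iloc[disc])
            tm = fit_transfer(model, X.to_numpy(), behavior.iloc[disc])
            t = transfer_scores(tm, {m: b.iloc[repl] for m, b in blocks.items()},
                                behavior.iloc[repl])
            gaps.append(res.lc_correlations[0] - t.lc_correlations[0])
        assert np.mean(gaps) > 0


class TestTransferSignificance:
    def test_strong_signal_attains_minimum_p(self, twin_cohorts):
        r, p, q = transfer_significance(
            twin_cohorts["transfer_model"], twin_cohorts["repl"]["blocks"],
            twin_cohorts["repl"]["behavior"], twin_cohorts["repl"]["sites"],
            n_perm=99, k_test=3, seed=0,
        )
        assert (r > 0.2).all()
        np.testing.assert_allclose(p, 0.01)

    def test_zero_permutations_raise(self, twin_cohorts):
        with pytest.raises(ValueError):
            transfer_significance(
                twin_cohorts["transfer_model"], twin_cohorts["repl"]["blocks"],
                twin_cohorts["repl"]["behavior"], twin_cohorts["repl"]["sites"],
                n_perm=0,
            )


def test_identical_arms_have_unit_loading_correlations(twin_cohorts):
    res = twin_cohorts["result"]
    table = compare_loadings(res, res, k=3)
    np.testing.assert_allclose(table["r"], 1.0, atol=1e-12)


def test_independent_truths_decorrelate_loadings():
    results = []
    for seed in (51, 52):  # different seeds -> different planted truths
        cfg = bbpls.SyntheticConfig(
            n_subjects=500, n_sites=2, n_parcels_cortical=12, n_parcels_subcortical=3,
            n_items=18, n_latent=2, latent_strength=(4.0, 2.0),
            confound_strength=0.0, seed=seed,
        )
        dataset, _ = bbpls.generate_dataset(cfg)
        blocks, behavior = residualize_dataset(dataset)
        _, X = bbpls.fit_reduction(blocks, 0.5)
        results.append(bbpls.pls_decompose(X, behavior))
    table = compare_loadings(results[0], results[1], k=2)
    assert np.abs(table["r"]).max() < 0.6  # no shared structure beyond chance


class TestHeldoutAssociation:
    def test_feature_equal_to_composite_loads_one(self, twin_cohorts):
        res = twin_cohorts["result"]
        idx = twin_cohorts["disc"]["behavior"].index
        scores = pd.DataFrame(res.LX[:, :2], index=idx, columns=["LX1", "LX2"])
        held = pd.DataFrame({"probe": res.LX[:, 0]}, index=idx)
        sites = pd.Series(twin_cohorts["disc"]["sites"], index=idx)
        obs, stats_d = heldout_association(held, scores, sites, n_boot=30, seed=0)
        assert obs[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert stats_d["n_overlap"] == len(idx)

    def test_planted_tract_effect_recovers_sign(self, twin_cohorts):
        truth = twin_cohorts["truth"]
        res = twin_cohorts["result"]
        idx = twin_cohorts["disc"]["behavior"].index
        rng = np.random.default_rng(0)
        z = truth.subject_scores[:1200, 0]
        hits = 0
        for rep in range(20):
            tract = 0.3 * z + rng.standard_normal(1200)
            held = pd.DataFrame({"tract": tract}, index=idx)
            scores = pd.DataFrame(res.LX[:, :1], index=idx, columns=["LX1"])
            sites = pd.Series(twin_cohorts["disc"]["sites"], index=idx)
            obs, _ = heldout_association(held, scores, sites, n_boot=20, seed=rep)
            hits += obs[0, 0] > 0
        assert hits == 20

    def test_null_features_rarely_pass_fdr(self, twin_cohorts):
        res = twin_cohorts["result"]
        idx = twin_cohorts["disc"]["behavior"].index
        sites = pd.Series(twin_cohorts["disc"]["sites"], index=idx)
        scores = pd.DataFrame(res.LX[:, :2], index=idx, columns=["LX1", "LX2"])
        empty = 0
        for rep in range(10):
            rng = np.random.default_rng(700 + rep)
            held = pd.DataFrame(rng.standard_normal((1200, 10)), index=idx)
            _, d = heldout_association(held, scores, sites, n_boot=100, seed=rep)
            empty += not d["fdr_mask"].any()
        assert empty >= 8

    def test_empty_overlap_raises(self, twin_cohorts):
        res = twin_cohorts["result"]
        idx = twin_cohorts["disc"]["behavior"].index
        scores = pd.DataFrame(res.LX[:, :1], index=idx, columns=["LX1"])
        held = pd.DataFrame({"x": [1.0, 2.0]}, index=["nope1", "nope2"])
        with pytest.raises(ValueError, match="overlap"):
            heldout_association(held, scores, pd.Series(["a"] * 2, index=held.index),
                                n_boot=10)


class TestDemographicPosthoc:
    def _cov(self, n, rng):
        return pd.DataFrame({
            "age": rng.uniform(9, 11, n),
            "sex": rng.choice(["F", "M"], n),
        }, index=[f"s{i}" for i in range(n)])

    def test_age_dependent_score_detected_sex_not(self, rng):
        cov = self._cov(500, rng)
        scores = pd.DataFrame({
            "LX1": cov["age"].to_numpy() + 0.3 * rng.standard_normal(500),
        }, index=cov.index)
        table = demographic_posthoc(scores, cov).set_index("test")
        assert table.loc["age_r", "significant"]
        assert not table.loc["sex_t", "significant"]

    def test_null_scores_rarely_flagged(self):
        flagged = 0
        for rep in range(30):
            r = np.random.default_rng(rep)
            cov = self._cov(300, r)
            scores = pd.DataFrame(r.standard_normal((300, 2)), index=cov.index,
                                  columns=["LX1", "LY1"])
            t = demographic_posthoc(scores, cov)
            flagged += bool(t["significant"].any())
        assert flagged <= 4

    def test_one_sex_absent_is_skipped_with_flag(self, rng):
        cov = self._cov(100, rng)
        cov["sex"] = "F"
        scores = pd.DataFrame({"LX1": rng.standard_normal(100)}, index=cov.index)
        t = demographic_posthoc(scores, cov).set_index("test")
        assert "skipped" in t.loc["sex_t", "flag"]

    def test_equal_means_unequal_variances_welch_near_zero(self, rng):
        n = 4000
        cov = self._cov(n, rng)
        s = np.where(cov["sex"] == "F", 1.0, 3.0) * rng.standard_normal(n)
        t = demographic_posthoc(pd.DataFrame({"LX1": s}, index=cov.index), cov)
        stat = t.set_index("test").loc["sex_t", "statistic"]
        assert abs(stat) < 2.5
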