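"""Offset model fits, the elastic-net solver against independent oracles,
cross-validated genetic models, importance, and transfer."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

from demrisk import modeling
from demrisk.modeling import (ElasticNetGrid, elastic_net_logistic,
                              feature_importance, fit_genetic_model,
                              fit_offset_model, transfer_model)


def _simulate(rng, n, p, beta, intercept=-1.0, offset_sd=0.0):
    X = rng.standard_normal((n, p))
    off = rng.normal(0, offset_sd, n) if offset_sd else np.zeros(n)
    y = (rng.random(n) < expit(intercept + X @ beta + off)).astype(float)
    return X, off, y


class TestOffsetModel:
    def test_null_covariates_give_flat_offsets(self):
        rng = np.random.default_rng(0)
        n = 4000
        y = (rng.random(n) < 0.3).astype(float)
        age = rng.uniform(60, 85, n)
        sex = (rng.random(n) < 0.5).astype(float)
        m = fit_offset_model(y, age, sex)
        assert abs(m.params[1]) < 0.01 and abs(m.params[2]) < 0.2
        assert np.allclose(m.offsets.mean(), logit(y.mean()), atol=0.05)

    def test_age_effect_recovered(self):
        rng = np.random.default_rng(1)
        n = 8000
        age = rng.uniform(55, 90, n)
        sex = (rng.random(n) < 0.5).astype(float)
        eta = -4.5 + 0.05 * age + 0.2 * sex
        y = (rng.random(n) < expit(eta)).astype(float)
        m = fit_offset_model(y, age, sex)
        res = sm.GLM(y, sm.add_constant(np.column_stack([age, sex])),
                     family=sm.families.Binomial()).fit()
        lo, hi = res.conf_int()[1]
        assert lo < 0.05 < hi
        assert m.params[1] == pytest.approx(res.params[1], abs=1e-6)

    def test_constant_sex_dropped_with_notice(self, caplog):
        rng = np.random.default_rng(2)
        y = (rng.random(500) < 0.3).astype(float)
        age = rng.uniform(60, 80, 500)
        with caplog.at_level("INFO"):
            m = fit_offset_model(y, age, np.ones(500))
        assert m.dropped == ["sex"] and m.feature_names == ["age"]

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="case"):
            fit_offset_model(np.ones(10), np.arange(10.0),
                             np.zeros(10))

    def test_refit_reproduces_offsets(self):
        rng = np.random.default_rng(3)
        y = (rng.random(300) < 0.3).astype(float)
        age = rng.uniform(60, 80, 300)
        sex = (rng.random(300) < 0.5).astype(float)
        a = fit_offset_model(y, age, sex)
        b = fit_offset_model(y, age, sex)
        np.testing.assert_allclose(a.offsets, b.offsets, atol=1e-8)


class TestElasticNetSolver:
    def test_matches_statsmodels_on_well_conditioned_problem(self):
        """Independent oracle: statsmodels' coordinate-descent elastic net
        on uncorrelated features, where it converges."""
        rng = np.random.default_rng(4)
        X, off, y = _simulate(rng, 600, 8, np.r_[0.6, 0.4, np.zeros(6)],
                              offset_sd=0.3)
        alpha, l1 = 0.02, 0.5
        mine = elastic_net_logistic(y, X, off, alpha, l1, tol=1e-12)
        pen = np.full(9, alpha)
        pen[0] = 0.0
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial(),
                     offset=off).fit_regularized(
            method="elastic_net", alpha=pen, L1_wt=l1, maxiter=400)
        np.testing.assert_allclose(mine, np.asarray(ref.params), atol=2e-3)

    def test_vanishing_penalty_matches_unpenalized_glm(self):
        rng = np.random.default_rng(5)
        X, off, y = _simulate(rng, 800, 5, np.r_[0.5, -0.3, 0.2, 0.0, 0.1],
                              offset_sd=0.2)
        mine = elastic_net_logistic(y, X, off, 1e-10, 0.5, tol=1e-14,
                                    max_iter=100000)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial(),
                     offset=off).fit()
        np.testing.assert_allclose(mine, np.asarray(ref.params), atol=1e-4)

    def test_strong_penalty_zeroes_everything(self):
        rng = np.random.default_rng(6)
        X, off, y = _simulate(rng, 300, 10, np.zeros(10), offset_sd=0.2)
        params = elastic_net_logistic(y, X, off, 5.0, 1.0)
        assert np.all(params[1:] == 0.0)

    def test_training_deviance_monotone_along_penalty_path(self):
        rng = np.random.default_rng(7)
        X, off, y = _simulate(rng, 400, 12, np.r_[0.5, 0.4, np.zeros(10)])

        def deviance(params):
            eta = params[0] + X @ params[1:] + off
            return 2 * np.sum(np.logaddexp(0, eta) - y * eta)
        devs = [deviance(elastic_net_logistic(y, X, off, a, 0.5))
                for a in (0.3, 0.1, 0.03, 0.01, 0.003)]
        assert all(b <= a + 1e-6 for a, b in zip(devs[:-1], devs[1:]))


class TestGeneticModelCv:
    def test_pure_noise_with_strong_penalty_returns_offset_probs(self):
        rng = np.random.default_rng(8)
        n = 400
        X = rng.standard_normal((n, 20))
        off = rng.normal(-1.0, 0.5, n)
        y = (rng.random(n) < expit(off)).astype(float)
        grid = ElasticNetGrid(l1_ratios=(1.0,), alphas=(2.0,), n_inner=2)
        model, pred = fit_genetic_model(
            pd.DataFrame(X), y, off, "enet_snp", enet_grid=grid, seed=0)
        assert np.all(model.coef == 0.0)
        # intercept-only refit on the offset: predictions are a monotone
        # shift of the offset probabilities
        assert np.corrcoef(pred.yhat, expit(off))[0, 1] > 0.999

    def test_out_of_fold_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(9)
        X, off, y = _simulate(rng, 200, 3, np.zeros(3), intercept=-0.5)
        model, pred = fit_genetic_model(
            pd.DataFrame(X), y, off, "multi_prs", seed=1)
        assert not np.isnan(pred.yhat).any()
        assert sorted(np.unique(pred.fold_ids)) == [0, 1, 2, 3, 4]
        counts = np.bincount(pred.fold_ids)
        assert counts.sum() == 200 and counts.min() >= 30

    def test_apoe_family_requires_single_feature(self):
        y = np.r_[np.ones(20), np.zeros(40)]
        X = pd.DataFrame(np.random.default_rng(0).random((60, 2)))
        with pytest.raises(ValueError, match="exactly one"):
            fit_genetic_model(X, y, np.zeros(60), "apoe")

    def test_too_few_cases_for_folds_rejected(self):
        y = np.r_[np.ones(3), np.zeros(60)]
        X = pd.DataFrame(np.random.default_rng(0).random((63, 1)))
        with pytest.raises(ValueError, match="5-fold"):
            fit_genetic_model(X, y, np.zeros(63), "apoe", cv_folds=5)

    def test_planted_snps_recovered_among_nonzero(self):
        rng = np.random.default_rng(10)
        n, p = 1500, 100
        beta = np.zeros(p)
        beta[:8] = 0.45
        X, off, y = _simulate(rng, n, p, beta, intercept=-1.2)
        grid = ElasticNetGrid(l1_ratios=(0.9,), alphas=(0.01, 0.03),
                              n_inner=3)
        model, _ = fit_genetic_model(pd.DataFrame(X), y, off, "enet_snp",
                                     enet_grid=grid, seed=3)
        selected = set(np.flatnonzero(model.coef != 0.0))
        assert len(selected & set(range(8))) >= 7


class TestImportance:
    def _model(self, coef, names=None):
        coef = np.asarray(coef, dtype=float)
        return modeling.GeneticRiskModel(
            "enet_snp", names or [f"f{i}" for i in range(len(coef))],
            0.0, coef, coef.copy())

    def test_single_nonzero_feature_gets_full_importance(self):
        feats = pd.DataFrame(np.random.default_rng(0).random((50, 3)),
                             columns=["a", "b", "c"])
        imp = feature_importance(self._model([0.0, 1.2, 0.0],
                                             ["a", "b", "c"]), feats)
        assert list(imp.index) == ["b"] and imp.iloc[0] == pytest.approx(1.0)

    def test_equal_scaled_coefficients_split_evenly(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame({"a": rng.normal(0, 1.0, 2000),
                              "b": rng.normal(0, 2.0, 2000)})
        imp = feature_importance(self._model([0.5, 0.25], ["a", "b"]), feats)
        assert imp["a"] == pytest.approx(0.5, abs=0.02)
        assert imp["b"] == pytest.approx(0.5, abs=0.02)

    def test_ranking_matches_drop_one_auprc_degradation(self):
        """On three planted features of increasing strength, the
        |beta|*SD ranking matches a brute-force ablation ordering."""
        from sklearn.metrics import average_precision_score
        rng = np.random.default_rng(2)
        n = 4000
        X = rng.standard_normal((n, 3))
        beta = np.array([0.2, 0.5, 1.0])
        y = (rng.random(n) < expit(-1.0 + X @ beta)).astype(float)
        off = np.zeros(n)
        grid = ElasticNetGrid(l1_ratios=(0.5,), alphas=(0.001,), n_inner=2)
        model, _ = fit_genetic_model(pd.DataFrame(X), y, off, "enet_snp",
                                     enet_grid=grid, seed=0)
        imp = feature_importance(model, pd.DataFrame(X))
        drops = []
        for j in range(3):
            keep = [k for k in range(3) if k != j]
            sub, _ = fit_genetic_model(pd.DataFrame(X[:, keep]), y, off,
                                       "multi_prs", seed=0)
            yhat = expit(sub.intercept + X[:, keep] @ sub.coef)
            drops.append(average_precision_score(y, yhat))
        ablation_rank = np.argsort(drops)  # biggest drop = most important
        importance_rank = np.argsort(
            [-imp.get(j, 0.0) for j in range(3)])
        np.testing.assert_array_equal(ablation_rank, importance_rank)


class TestTransfer:
    def _fitted(self, rng, n=600):
        X, _, y = _simulate(rng, n, 4, np.r_[0.5, 0.4, 0.0, 0.0],
                            intercept=-1.0)
        age = rng.uniform(60, 85, n)
        sex = (rng.random(n) < 0.5).astype(float)
        om = fit_offset_model(y, age, sex)
        feats = pd.DataFrame(X, columns=list("abcd"))
        model, _ = fit_genetic_model(feats, y, om.offsets, "multi_prs",
                                     seed=0)
        return model, feats, y, age, sex, om

    def test_identity_transfer_reproduces_in_sample_predictions(self):
        rng = np.random.default_rng(11)
        model, feats, y, age, sex, om = self._fitted(rng)
        pred, om2 = transfer_model(model, feats, y, age, sex)
        direct = model.predict(feats.to_numpy(), om.offsets)
        np.testing.assert_allclose(pred.yhat, direct, atol=1e-6)

    def test_genetic_coefficients_frozen_bitwise(self):
        rng = np.random.default_rng(12)
        model, feats, y, age, sex, _ = self._fitted(rng)
        before = model.coef.copy()
        transfer_model(model, feats, y, age + 10.0, sex)
        np.testing.assert_array_equal(model.coef, before)

    def test_missing_features_listed(self):
        rng = np.random.default_rng(13)
        model, feats, y, age, sex, _ = self._fitted(rng)
        with pytest.raises(ValueError, match="'d'"):
            transfer_model(model, feats[["a", "b", "c"]], y, age, sex)

    def test_transferred_multisnp_model_beats_apoe_on_shared_architecture(
            self):
        """A frozen multi-SNP model transferred to a second cohort drawn
        from the same causal architecture outperforms a single-variant
        model, mirroring cross-biobank validation."""
        from sklearn.metrics import average_precision_score
        rng = np.random.default_rng(14)
        p = 30
        beta = np.zeros(p)
        beta[:6] = 0.5
        beta[6] = 0.6  # the "APOE-like" single variant

        def cohort_draw(n):
            X = rng.standard_normal((n, p))
            y = (rng.random(n) < expit(-1.1 + X @ beta)).astype(float)
            age = rng.uniform(60, 85, n)
            sex = (rng.random(n) < 0.5).astype(float)
            return pd.DataFrame(X), y, age, sex

        Xs, ys, ages, sexs = cohort_draw(1500)
        om = fit_offset_model(ys, ages, sexs)
        grid = ElasticNetGrid(l1_ratios=(0.5,), alphas=(0.01,), n_inner=2)
        enet, _ = fit_genetic_model(Xs, ys, om.offsets, "enet_snp",
                                    enet_grid=grid, seed=0)
        apoe, _ = fit_genetic_model(Xs[[6]], ys, om.offsets, "apoe", seed=0)
        Xt, yt, aget, sext = cohort_draw(1500)
        pe, _ = transfer_model(enet, Xt, yt, aget, sext)
        pa, _ = transfer_model(apoe, Xt, yt, aget, sext)
        assert average_precision_score(yt, pe.yhat) > \
            average_precision_score(yt, pa.yhat)


class TestOffsetContract:
    def test_two_stage_matches_joint_fit_when_independent(self):
        """With genotype independent of demographics, the offset two-stage
        fit recovers the same genetic coefficients as a joint logistic
        model (one seed here; the full ten-seed check runs in the
        acceptance suite)."""
        rng = np.random.default_rng(15)
        n = 8000
        G = rng.integers(0, 3, (n, 3)).astype(float)
        age = rng.uniform(60, 85, n)
        sex = (rng.random(n) < 0.5).astype(float)
        eta = -6.0 + 0.05 * age + 0.3 * sex + G @ [0.4, 0.25, 0.0]
        y = (rng.random(n) < expit(eta)).astype(float)
        om = fit_offset_model(y, age, sex)
        model, _ = fit_genetic_model(pd.DataFrame(G), y, om.offsets,
                                     "multi_prs", seed=0)
        joint = sm.GLM(y, sm.add_constant(
            np.column_stack([age, sex, G])),
            family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(model.coef, joint.params[3:], atol=0.05)
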