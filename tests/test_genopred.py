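"""Genomic prediction: GBLUP/RR-BLUP, lasso, cross-validation, deregression."""

import numpy as np
import pandas as pd
import pytest

from vinegp import simcross as sc
from vinegp.genomat import GenotypeMatrix
from vinegp.genopred import (
    GBLUP,
    LogisticMarkerLasso,
    MarkerLasso,
    cross_validate,
    deregress_predictions,
    fit_gblup,
    kkt_violation,
    predict_validation,
    select_best_method,
    CVResult,
)
from tests.conftest import stack_crosses


def random_instance(rng, n=50, p=200, h2=0.5, n_qtl=None):
    X = rng.integers(0, 3, (n, p)).astype(float)
    n_qtl = n_qtl or p
    beta = np.zeros(p)
    beta[rng.choice(p, n_qtl, replace=False)] = rng.normal(0, 1, n_qtl)
    g = X @ beta
    g = (g - g.mean()) / max(g.std(), 1e-9)
    e = rng.normal(0, 1, n)
    y = np.sqrt(h2) * g + np.sqrt(1 - h2) * (e - e.mean()) / e.std()
    return X, y


class TestGBLUP:
    def test_henderson_toy_oracle(self):
        """Fixed-variance GBLUP equals a direct Henderson/GLS solve."""
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, (6, 3)).astype(float)
        y = rng.normal(0, 1, 6)
        s2u, s2e = 2.0, 1.0
        m = GBLUP(var_components=(s2u, s2e)).fit(X, y)
        freq = X.mean(0) / 2
        Z = X - 2 * freq
        K = Z @ Z.T / (2 * np.sum(freq * (1 - freq)))
        V = s2u * K + s2e * np.eye(6)
        Vi = np.linalg.inv(V)
        one = np.ones(6)
        mu = (one @ Vi @ y) / (one @ Vi @ one)
        g = s2u * K @ Vi @ (y - mu)
        np.testing.assert_allclose(m.gebv_, g, atol=1e-10)
        P = Vi - np.outer(Vi @ one, one @ Vi) / (one @ Vi @ one)
        pev = np.diag(s2u * K - s2u * K @ P @ K * s2u)
        np.testing.assert_allclose(m.pev_, pev, atol=1e-10)

    def test_marker_kinship_equivalence(self):
        """GEBVs from ridge marker effects equal kinship-form GEBVs."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            X, y = random_instance(rng)
            m = GBLUP().fit(X, y)
            np.testing.assert_allclose(
                (X - 2 * m.freq_) @ m.coef_, m.gebv_, atol=1e-8
            )

    def test_reml_matches_grid_oracle(self):
        """Spectral REML optimum beats/equals a fine grid over the ratio."""
        rng = np.random.default_rng(2)
        X, y = random_instance(rng, n=50, p=100)
        m = GBLUP().fit(X, y)
        freq = X.mean(0) / 2
        Z = X - 2 * freq
        K = Z @ Z.T / (2 * np.sum(freq * (1 - freq)))
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 0, None)
        yt, xt = U.T @ y, U.T @ np.ones(len(y))

        def neg2(lam):
            dl = d + lam
            xwx = np.sum(xt**2 / dl)
            mu = np.sum(xt * yt / dl) / xwx
            quad = np.sum((yt - xt * mu) ** 2 / dl)
            return (len(y) - 1) * np.log(quad / (len(y) - 1)) + np.sum(np.log(dl)) + np.log(xwx)

        grid = np.exp(np.linspace(-10, 10, 20001))
        best = grid[int(np.argmin([neg2(l) for l in grid]))]
        assert neg2(m.lambda_) <= neg2(best) + 1e-6

    def test_shrinkage_limit(self):
        rng = np.random.default_rng(3)
        X, y = random_instance(rng, n=30, p=50)
        m = GBLUP(var_components=(1e-10, 1.0)).fit(X, y)
        assert np.abs(m.gebv_).max() < 1e-6

    def test_constant_response_rejected(self):
        X = np.random.default_rng(4).integers(0, 3, (10, 5)).astype(float)
        with pytest.raises(ValueError, match="constant"):
            GBLUP().fit(X, np.ones(10))


class TestLasso:
    def test_lambda_max_all_zero(self):
        rng = np.random.default_rng(5)
        X, y = random_instance(rng, n=60, p=80)
        m = MarkerLasso(n_lambda=30, random_state=0).fit(X, y)
        lam_max = m.lambda_path_[0]
        Xs = (X - X.mean(0)) / X.std(0)
        # at lambda_max the all-zero solution satisfies the KKT conditions
        assert np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y) <= lam_max + 1e-12
        assert kkt_violation(X, y, np.zeros(X.shape[1]), lam_max) <= 1e-10

    def test_kkt_at_solutions(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            X, y = random_instance(rng, n=40, p=60)
            m = MarkerLasso(n_lambda=25, random_state=1).fit(X, y)
            assert kkt_violation(X, y, m.coef_std_, m.lambda_) <= 1e-6

    def test_matches_sklearn(self):
        """Dual route: our coordinate descent equals sklearn's at fixed lambda."""
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(7)
        X, y = random_instance(rng, n=50, p=120)
        m = MarkerLasso(n_lambda=30, random_state=2).fit(X, y)
        Xs = (X - X.mean(0)) / X.std(0)
        sk = Lasso(alpha=m.lambda_, tol=1e-12, max_iter=10**6).fit(Xs, y - y.mean())
        np.testing.assert_allclose(m.coef_std_, sk.coef_, atol=1e-6)

    def test_single_qtl_recovered(self):
        """A strong single QTL (or a tightly linked marker) enters the active set."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = sc.SimConfig(n_founders=2, n_chromosomes=2,
                               snps_per_chromosome=100, seed=seed)
            f = sc.simulate_founders(cfg)
            fam = sc.simulate_cross(f, "P1", "P2", 150, seed=seed + 50)
            arch = sc.TraitArchitecture(n_qtl=1, target_h2=0.8,
                                        qtl_effect_distribution="equal")
            try:
                tt = sc.simulate_trait(fam, arch, seed=seed + 99)
            except ValueError:
                hits += 1  # monomorphic draw: no signal to recover, skip
                continue
            rng = np.random.default_rng(seed)
            y = tt.genotypic_values.to_numpy() + rng.normal(
                0, np.sqrt(arch.residual_var) / 2, fam.n_individuals
            )
            m = MarkerLasso(n_lambda=40, random_state=seed).fit(fam.dosages, y)
            qtl = tt.qtl.index[0]
            cm_q = fam.markers.loc[qtl, "cm"]
            chrom_q = fam.markers.loc[qtl, "chrom"]
            active = fam.markers.iloc[m.active_]
            near = (
                (active["chrom"] == chrom_q) & ((active["cm"] - cm_q).abs() <= 1.0)
            ).any()
            hits += bool(near)
        assert hits >= int(0.95 * n_seeds)

    def test_path_monotone_sparsity_at_top(self):
        rng = np.random.default_rng(8)
        X, y = random_instance(rng, n=50, p=80)
        m = MarkerLasso(n_lambda=30, random_state=3).fit(X, y)
        from vinegp._cd import lasso_path_gram
        Xs = (X - X.mean(0)) / X.std(0)
        B = lasso_path_gram(Xs.T @ Xs / 50, Xs.T @ (y - y.mean()) / 50,
                            m.lambda_path_, 1e-8, 2000)
        nnz = (B != 0).sum(axis=1)
        assert nnz[0] == 0
        head = nnz[:10]
        assert np.all(np.diff(head) >= 0)


class TestLogisticLasso:
    def test_null_labels_accuracy_near_majority(self):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 3, (120, 60)).astype(float)
        y = (rng.random(120) < 0.6).astype(int)
        cv = cross_validate(y, X, "logistic_lasso", k=5, r=2, seed=0)
        assert abs(cv.mean_pa - max(y.mean(), 1 - y.mean())) < 0.12

    def test_perfect_major_gene(self):
        cfg = sc.SimConfig(n_founders=2, n_chromosomes=2, snps_per_chromosome=60,
                           seed=10)
        f = sc.simulate_founders(cfg)
        fam = sc.simulate_cross(f, "P1", "P2", 300, seed=11)
        var = fam.dosages.var(axis=0)
        locus = fam.marker_ids[int(np.argmax(var))]
        lab = sc.simulate_binary_trait(fam, locus, 1.0, seed=12)
        cv = cross_validate(lab.to_numpy(), fam.dosages, "logistic_lasso",
                            k=5, r=1, seed=1)
        assert cv.mean_pa > 0.97

    def test_single_class_rejected(self):
        X = np.random.default_rng(13).integers(0, 3, (20, 10)).astype(float)
        with pytest.raises(ValueError, match="single-class"):
            LogisticMarkerLasso().fit(X, np.ones(20))


class TestCrossValidate:
    def test_fold_count_and_determinism(self):
        rng = np.random.default_rng(14)
        X, y = random_instance(rng, n=80, p=60)
        cv1 = cross_validate(y, X, "gblup", k=5, r=10, seed=3)
        cv2 = cross_validate(y, X, "gblup", k=5, r=10, seed=3)
        assert cv1.fold_pa.size == 50
        np.testing.assert_array_equal(cv1.fold_pa, cv2.fold_pa)
        cv3 = cross_validate(y, X, "gblup", k=5, r=10, seed=4)
        assert not np.array_equal(cv1.fold_pa, cv3.fold_pa)

    def test_null_trait_pa_centered_at_zero(self):
        rng = np.random.default_rng(15)
        X = rng.integers(0, 3, (100, 80)).astype(float)
        y = rng.normal(0, 1, 100)
        cv = cross_validate(y, X, "gblup", k=5, r=5, seed=5)
        assert abs(cv.mean_pa) < 2 * cv.se + 0.1

    def test_small_fold_rejected(self):
        rng = np.random.default_rng(16)
        X, y = random_instance(rng, n=10, p=20)
        with pytest.raises(ValueError, match="fold"):
            cross_validate(y, X, "gblup", k=5, r=1, seed=0)


class TestBestMethod:
    def _cv(self, method, mean):
        return CVResult(trait="t", method=method,
                        fold_pa=np.full((1, 5), mean), k=5, r=1, seed=0)

    def test_paper_style_pair(self):
        assert select_best_method(self._cv("gblup", 0.41), self._cv("lasso", 0.34)) == "gblup"

    def test_tie_prefers_gblup(self):
        assert select_best_method(self._cv("lasso", 0.4), self._cv("gblup", 0.4)) == "gblup"

    def test_lasso_wins(self):
        assert select_best_method(self._cv("gblup", 0.10), self._cv("lasso", 0.30)) == "lasso"


class TestValidationPrediction:
    def _split(self, founders, n=60):
        fam = sc.simulate_cross(founders, "P1", "P2", 2 * n, seed=17)
        ts = fam.take_individuals(np.arange(n))
        vs = fam.take_individuals(np.arange(n, 2 * n))
        return ts, vs

    def test_duplicate_genotype_same_prediction(self, founders):
        ts, vs = self._split(founders)
        rng = np.random.default_rng(18)
        y = ts.dosages @ rng.normal(0, 0.2, ts.n_markers) + rng.normal(0, 1, 60)
        model = fit_gblup(y, ts)
        # graft a VS individual with a TS individual's genotype
        vs2 = vs.copy()
        vs2.dosages[0] = ts.dosages[3]
        preds = predict_validation(model, vs2)
        assert preds.frame["predicted"].iloc[0] == pytest.approx(model.predict(ts.dosages[[3]])[0])

    def test_marker_mismatch_rejected(self, founders):
        ts, vs = self._split(founders)
        rng = np.random.default_rng(19)
        y = rng.normal(0, 1, 60) + ts.dosages[:, 0]
        model = fit_gblup(y, ts)
        with pytest.raises(ValueError, match="intersect_markers"):
            predict_validation(model, vs.take_markers(np.arange(10)))

    def test_zero_effects_constant_prediction(self, founders):
        ts, vs = self._split(founders)
        rng = np.random.default_rng(20)
        y = rng.normal(5, 1, 60) + 0.3 * ts.dosages[:, 5]
        m = MarkerLasso(n_lambda=5, lambda_min_ratio=0.9, random_state=0).fit(ts.dosages, y)
        if len(m.active_) == 0:  # heavy penalty: intercept-only model
            pred = m.predict(vs.dosages)
            np.testing.assert_allclose(pred, pred[0])

    def test_full_sib_vs_prediction_correlates_with_truth(self, founders):
        corrs = []
        for seed in range(5):
            fam = sc.simulate_cross(founders, "P2", "P5", 160, seed=30 + seed)
            arch = sc.TraitArchitecture(n_qtl=50, target_h2=0.5)
            tt = sc.simulate_trait(fam, arch, seed=60 + seed)
            rng = np.random.default_rng(90 + seed)
            y = tt.genotypic_values.to_numpy() + rng.normal(0, 1, 160)
            ts, vs = np.arange(80), np.arange(80, 160)
            model = GBLUP().fit(fam.dosages[ts], y[ts])
            pred = model.predict(fam.dosages[vs])
            corrs.append(np.corrcoef(pred, tt.genotypic_values.to_numpy()[vs])[0, 1])
        assert np.mean(corrs) > 0.2 and min(corrs) > 0


class TestDeregressPredictions:
    def test_gblup_zero_pev_identity(self, founders):
        fam = sc.simulate_cross(founders, "P1", "P3", 50, seed=40)
        rng = np.random.default_rng(41)
        y = fam.dosages @ rng.normal(0, 0.2, fam.n_markers) + rng.normal(0, 0.5, 50)
        model = fit_gblup(y, fam)
        preds = predict_validation(model, fam)
        out = deregress_predictions(model, preds, fam)
        pev = model.predict_pev(fam.dosages)
        rel = 1 - pev / model.sigma2_u_
        manual = model.mu_ + (preds.frame["predicted"].to_numpy() - model.mu_) / rel
        ok = rel > 0
        np.testing.assert_allclose(out.frame["deregressed"].to_numpy()[ok], manual[ok])

    def test_variance_restored(self, founders):
        fam = sc.simulate_cross(founders, "P1", "P4", 120, seed=42)
        arch = sc.TraitArchitecture(n_qtl=40, target_h2=0.5)
        tt = sc.simulate_trait(fam, arch, seed=43)
        rng = np.random.default_rng(44)
        y = tt.genotypic_values.to_numpy() + rng.normal(0, 1, 120)
        ts = fam.take_individuals(np.arange(60))
        vs = fam.take_individuals(np.arange(60, 120))
        model = fit_gblup(y[:60], ts)
        preds = predict_validation(model, vs)
        out = deregress_predictions(model, preds, vs)
        ok = out.frame["deregressed"].notna()
        assert out.frame.loc[ok, "deregressed"].var() >= out.frame.loc[ok, "predicted"].var() - 1e-12

    def test_lasso_ols_on_orthonormal_design(self):
        """With orthonormal columns OLS refits undo the soft-threshold shrinkage."""
        rng = np.random.default_rng(45)
        n, p = 64, 8
        Q, _ = np.linalg.qr(rng.normal(0, 1, (n, p)))
        X = Q * np.sqrt(n)  # columns: mean ~0, x'x/n = 1
        X = X - X.mean(0)
        beta = np.array([3.0, -2.0, 1.5, 0, 0, 0, 0, 0])
        y = X @ beta + rng.normal(0, 0.1, n)
        m = MarkerLasso(n_lambda=30, random_state=1).fit(X, y)
        if len(m.active_) == 0:
            pytest.skip("penalty removed all effects")
        A = np.column_stack([np.ones(n), X[:, m.active_]])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        # |OLS| >= |lasso| coefficient-wise on the active set
        assert np.all(np.abs(coef[1:]) >= np.abs(m.coef_[m.active_]) - 1e-8)

    def test_empty_active_set_warns(self, founders):
        fam = sc.simulate_cross(founders, "P2", "P6", 40, seed=46)
        rng = np.random.default_rng(47)
        y = rng.normal(0, 1, 40)
        m = MarkerLasso(n_lambda=3, lambda_min_ratio=0.99, random_state=2).fit(fam.dosages, y)
        if len(m.active_):
            pytest.skip("active set not empty under this draw")
        preds = predict_validation(m, fam)
        with pytest.warns(UserWarning, match="active set"):
            out = deregress_predictions(m, preds, fam)
        np.testing.assert_allclose(out.frame["deregressed"], m.intercept_)
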