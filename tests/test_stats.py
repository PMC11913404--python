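"""Pointwise regression, cluster permutation, Wilcoxon/AUC tests, shuffle-R²
and nested mixed-model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from routineform import stats as rs
from routineform.align import AlignedMatrix


def make_matrix(Y, fs=30.0, t0=0.0):
    T = Y.shape[1]
    ta = t0 + np.arange(T) / fs
    return AlignedMatrix(Y=Y, time_axis=ta, mode="head_fixed",
                         window_length=(T - 1) / fs, fs=fs)


def make_covariates(rng, K):
    return rs.CovariateSet(se=rng.uniform(0, 1, K),
                           bv=rng.uniform(0.1, 2.0, K),
                           ri=rng.uniform(0.5, 1.5, K))


class TestPointwiseRegression:
    def test_noiseless_linear_recovery(self, rng):
        K, T = 40, 25
        X = make_covariates(rng, K)
        Y = (0.5 + 2.0 * X.ri)[:, None] * np.ones((K, T))
        bs = rs.pointwise_regression(make_matrix(Y), X)
        np.testing.assert_allclose(bs.beta_ri, 2.0, atol=1e-9)
        np.testing.assert_allclose(bs.beta0, 0.5, atol=1e-9)
        np.testing.assert_allclose(bs.beta_se, 0.0, atol=1e-9)

    def test_matches_per_timepoint_lstsq_loop(self, rng):
        K, T = 30, 12
        X = make_covariates(rng, K)
        Y = rng.normal(size=(K, T))
        bs = rs.pointwise_regression(make_matrix(Y), X)
        D = X.design()
        for t in range(T):
            beta_t = np.linalg.lstsq(D, Y[:, t], rcond=None)[0]
            assert bs.beta0[t] == pytest.approx(beta_t[0], abs=1e-10)
            assert bs.beta_ri[t] == pytest.approx(beta_t[3], abs=1e-10)

    def test_noise_coefficients_unbiased(self, rng):
        # OLS on pure noise: mean beta_ri near 0, SD matching theory
        K, T = 50, 1
        X = make_covariates(rng, K)
        D = X.design()
        sigma2 = np.linalg.inv(D.T @ D)[3, 3]
        betas = [rs.pointwise_regression(
            make_matrix(rng.normal(size=(K, T))), X).beta_ri[0]
            for _ in range(500)]
        assert abs(np.mean(betas)) < 4 * np.sqrt(sigma2 / 500)
        assert np.std(betas) == pytest.approx(np.sqrt(sigma2), rel=0.10)

    def test_too_few_blocks_rejected(self, rng):
        X = make_covariates(rng, 5)
        with pytest.raises(ValueError, match="8"):
            rs.pointwise_regression(make_matrix(np.zeros((5, 3))), X)

    def test_collinear_pair_named(self, rng):
        se = rng.uniform(0, 1, 20)
        X = rs.CovariateSet(se=se, bv=rng.uniform(0.1, 1, 20), ri=2 * se + 1)
        with pytest.raises(ValueError, match="se and ri"):
            rs.pointwise_regression(make_matrix(np.zeros((20, 3))), X)

    def test_recovery_error_shrinks_with_noise(self, rng):
        # injected beta_ri over a window, three noise levels, monotone error
        K, T = 60, 30
        X = make_covariates(rng, K)
        W = slice(10, 20)
        base = np.zeros((K, T))
        base[:, W] = 1.7 * X.ri[:, None]
        noise = rng.normal(size=(K, T))
        errs = []
        for level in (1.0, 0.3, 0.03):
            bs = rs.pointwise_regression(make_matrix(base + level * noise), X)
            errs.append(abs(bs.beta_ri[W].mean() - 1.7))
        assert errs[0] > errs[1] > errs[2]


class TestClusterPermutation:
    def test_zero_matrix_no_clusters(self):
        res = rs.cluster_permutation(np.zeros((8, 30)), n_perm=200, seed=0)
        assert res.clusters == []

    def test_shared_bump_detected_and_localized(self, rng):
        N, T = 11, 50
        W = slice(20, 35)
        B = rng.normal(size=(N, T))
        B[:, W] += 2.0
        res = rs.cluster_permutation(B, n_perm=1000, seed=1)
        sig = res.significant(0.01)
        assert len(sig) >= 1
        best = max(sig, key=lambda c: c.mass)
        overlap = max(0, min(best.end, W.stop - 1) - max(best.start, W.start) + 1)
        assert overlap >= 0.8 * (W.stop - W.start)

    def test_p_never_zero_and_monotone_in_effect(self, rng):
        N, T = 10, 40
        noise = rng.normal(size=(N, T))
        ps = []
        for amp in (0.5, 1.0, 2.0, 4.0):
            B = noise.copy()
            B[:, 15:25] += amp
            res = rs.cluster_permutation(B, n_perm=500, seed=7)
            p_min = min((c.p for c in res.clusters), default=1.0)
            assert p_min > 0
            ps.append(p_min)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invariant_to_subject_relabeling_and_sign_flip(self, rng):
        B = rng.normal(size=(9, 30))
        B[:, 5:12] += 1.5
        r1 = rs.cluster_permutation(B, n_perm=400, seed=3)
        r2 = rs.cluster_permutation(B[rng.permutation(9)], n_perm=400, seed=3)
        r3 = rs.cluster_permutation(-B, n_perm=400, seed=3)
        def key(r):
            return [(c.start, c.end, round(c.mass, 9), c.p) for c in r.clusters]
        assert key(r1) == key(r2)
        assert key(r1) == [(c.start, c.end, round(c.mass, 9), c.p)
                           for c in r3.clusters]
        assert all(c1.sign == -c3.sign
                   for c1, c3 in zip(r1.clusters, r3.clusters))

    def test_perm_t_matches_direct_computation(self, rng):
        B = rng.normal(size=(7, 15))
        signs = rng.choice([-1.0, 1.0], size=(20, 7))
        fast = rs._perm_t_stats(B, signs)
        for r in range(20):
            direct = sps.ttest_1samp(signs[r][:, None] * B, 0.0).statistic
            np.testing.assert_allclose(fast[r], direct, atol=1e-10)

    def test_max_cluster_mass_matches_scan(self, rng):
        t_abs = np.abs(rng.normal(size=(50, 40)))
        thr = 1.0
        fast = rs._max_cluster_mass_rows(t_abs, thr)
        for r in range(50):
            best = cur = 0.0
            for v in t_abs[r]:
                cur = cur + v if v > thr else 0.0
                best = max(best, cur)
            assert fast[r] == pytest.approx(best, abs=1e-12)


class TestWilcoxonAndAuc:
    def test_same_sign_eleven_subjects_exact_p(self):
        w = np.linspace(2.5, 3.5, 11)
        assert rs.wilcoxon_across_subjects(w) == pytest.approx(2 * 0.5 ** 11)

    def test_symmetric_null_roughly_uniform(self, rng):
        ps = [rs.wilcoxon_across_subjects(rng.normal(size=11))
              for _ in range(200)]
        assert 0.35 < np.mean(ps) < 0.65

    def test_contracts(self, rng):
        with pytest.raises(ValueError):
            rs.wilcoxon_across_subjects([1.0])
        with pytest.raises(ValueError):
            rs.wilcoxon_across_subjects(np.zeros(8))

    def test_auc_regression_exact_recovery(self, rng):
        ps = []
        weights = []
        for s in range(11):
            X = make_covariates(rng, 30)
            Y = np.tile((3.0 * X.ri)[:, None] / 10, (1, 10))
            weights.append(rs.auc_regression(make_matrix(Y), X,
                                             (0.0, 9 / 30.0))[3])
        np.testing.assert_allclose(weights, 3.0, atol=1e-8)
        assert rs.wilcoxon_across_subjects(np.array(weights)) == pytest.approx(
            2 * 0.5 ** 11)


class TestPrePost:
    def _mats(self, rng, drop=0.0, n_subj=8):
        mats = {}
        for s in range(n_subj):
            Y = rng.normal(size=(12, 31), scale=0.1)
            Y[:, 16:] -= drop
            mats[f"m{s}"] = make_matrix(Y, t0=-0.5)
        return mats

    def test_identical_pre_post_gives_p_one(self):
        Y = np.ones((10, 31))
        mats = {f"m{s}": make_matrix(Y, t0=-0.5) for s in range(6)}
        res = rs.pre_post_comparison(mats)
        assert res.p == 1.0

    def test_activity_drop_detected_with_direction(self, rng):
        res = rs.pre_post_comparison(self._mats(rng, drop=1.0))
        assert res.p < 0.05
        assert (res.table["pre"] > res.table["post"]).all()

    def test_sign_flip_symmetry(self, rng):
        mats = self._mats(rng, drop=0.7)
        flipped = {k: make_matrix(-M.Y, t0=-0.5) for k, M in mats.items()}
        assert rs.pre_post_comparison(mats).p == pytest.approx(
            rs.pre_post_comparison(flipped).p)

    def test_window_coverage_required(self, rng):
        Y = rng.normal(size=(10, 10))
        mats = {"a": make_matrix(Y, t0=0.0)}
        with pytest.raises(ValueError):
            rs.pre_post_comparison(mats)


class TestShuffleR2:
    def _curves(self, rng, n_subj=8, n_bins=10, linked=True):
        ri = pd.DataFrame(rng.uniform(0.5, 2.0, size=(n_subj, n_bins)),
                          index=[f"m{s}" for s in range(n_subj)])
        if linked:
            beh = 2.0 * ri + 1.0
        else:
            beh = pd.DataFrame(rng.uniform(size=(n_subj, n_bins)),
                               index=ri.index)
        return ri, beh

    def test_perfect_linearity_attains_lower_bound(self, rng):
        ri, beh = self._curves(rng, linked=True)
        res = rs.shuffle_r2_validation(ri, beh, n_shuffles=200, seed=0)
        np.testing.assert_allclose(res.r2_original, 1.0, atol=1e-12)
        assert res.p == pytest.approx(1 / 201)

    def test_unlinked_curves_null_behaviour(self, rng):
        ps = []
        for k in range(30):
            ri, beh = self._curves(rng, linked=False)
            ps.append(rs.shuffle_r2_validation(ri, beh, n_shuffles=99,
                                               seed=k).p)
        assert 0.25 < np.mean(ps) < 0.75

    def test_r2_matches_ols_oracle(self, rng):
        for _ in range(100):
            x, y = rng.normal(size=(2, 12))
            X = np.column_stack([np.ones(12), x])
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            r2_ols = 1 - resid.var() / y.var()
            assert rs._r2(x, y) == pytest.approx(r2_ols, abs=1e-12)

    def test_sparse_subject_dropped(self, rng):
        ri, beh = self._curves(rng)
        ri.iloc[0, 2:] = np.nan  # leaves 2 occupied bins
        with pytest.warns(UserWarning, match="m0"):
            res = rs.shuffle_r2_validation(ri, beh, n_shuffles=50, seed=0)
        assert res.dropped_subjects == ["m0"]


def make_lmm_frame(rng, n_subj=8, n_blocks=25, n_time=6,
                   b_ri=1.0, b_se=0.0, b_bv=0.0, noise=1.0):
    rows = []
    for s in range(n_subj):
        u = rng.normal(0, 0.5)
        ri = rng.uniform(0.5, 1.5, n_blocks)
        se = rng.uniform(0, 1, n_blocks)
        bv = rng.uniform(0.2, 2.0, n_blocks)
        for t in np.linspace(0, 1, n_time):
            y = (0.2 + u + 0.3 * t + (b_ri * ri + b_se * se + b_bv * bv) * t
                 + rng.normal(0, noise, n_blocks))
            rows += [{"subject": f"m{s}", "time": t, "y": y[k],
                      "ri": ri[k], "se": se[k], "bv": bv[k]}
                     for k in range(n_blocks)]
    return pd.DataFrame(rows)


class TestLrtComparison:
    def test_self_comparison_zero_lr(self, rng):
        df = make_lmm_frame(rng)
        models = {"Same": rs.MODEL_FORMULAS["Full"],
                  "Full": rs.MODEL_FORMULAS["Full"]}
        tab = rs.lrt_model_comparison(df, models=models).table
        row = tab.set_index("Model").loc["Same"]
        assert row["LR"] == pytest.approx(0.0, abs=1e-5)
        assert row["dDF"] == 0

    def test_full_likelihood_dominates_and_df_pattern(self, rng):
        df = make_lmm_frame(rng, b_se=0.5, b_bv=0.5)
        res = rs.lrt_model_comparison(df)
        tab = res.table.set_index("Model")
        assert tab.loc["Full", "LL"] >= tab["LL"].drop("Full").max() - 1e-6
        assert list(tab["DF"]) == [6, 8, 8, 10]
        assert list(tab["dDF"].drop("Full")) == [4, 2, 2]
        assert (tab["LR"].drop("Full") >= -1e-6).all()

    def test_strong_bv_effect_rejects_model_without_bv(self, rng):
        df = make_lmm_frame(rng, b_bv=1.5, noise=0.5)
        tab = rs.lrt_model_comparison(df).table.set_index("Model")
        assert tab.loc["RI + SE", "p"] < 0.05

    def test_null_terms_usually_retained(self, rng):
        df = make_lmm_frame(rng, b_se=0.0, b_bv=0.0)
        tab = rs.lrt_model_comparison(df).table.set_index("Model")
        # dropping the truly-null SE and BV terms costs little likelihood
        assert tab.loc["RI", "LR"] < 20


class TestModelResultsObjects:
    def test_fit_and_cluster_roundtrip(self, rng):
        mats, covs = {}, {}
        for s in range(6):
            X = make_covariates(rng, 20)
            Y = rng.normal(size=(20, 15), scale=0.5)
            Y[:, 5:10] += 1.0 * X.ri[:, None]
            mats[f"m{s}"] = make_matrix(Y)
            covs[f"m{s}"] = X
        res = rs.RoutineRegression(mats, covs).fit()
        assert res.B("ri").shape == (6, 15)
        cres = res.cluster_test(n_perm=300, seed=0)
        assert all(0 < c.p <= 1 for c in cres.clusters)
        auc = res.auc_test((0.0, 14 / 30.0))
        assert set(auc.p_values) == {"se", "bv", "ri"}
        assert "beta_ri" in res.summary() or "beta_ri" in str(auc.weights.columns.tolist())

    def test_mismatched_time_axes_rejected(self, rng):
        X = make_covariates(rng, 20)
        m1 = make_matrix(rng.normal(size=(20, 10)))
        m2 = make_matrix(rng.normal(size=(20, 12)))
        with pytest.raises(ValueError):
            rs.RoutineRegression({"a": m1, "b": m2}, {"a": X, "b": X})
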