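"""Mixture likelihood, E-step, penalized M-step and the EM driver."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import trajmix as tm
from trajmix.mixture import (
    ClusterParams,
    EmptyClusterError,
    FitConfig,
    MixtureModel,
    ParameterError,
    _component_logliks,
    penalized_mask_for,
)

from _oracles import lmm_ml_bruteforce, mvn_logpdf_direct, random_intercept_cov


def make_params(beta, d, sigma2, pi=1.0):
    return ClusterParams(beta=np.asarray(beta, float), d=d, sigma2=sigma2, pi=pi)


class TestMarginalCovariance:
    def test_random_intercept_identity(self):
        V = tm.marginal_covariance(np.ones((3, 1)), [[1.0]], 1.0)
        np.testing.assert_allclose(V, np.ones((3, 3)) + np.eye(3))

    def test_zero_random_variance(self):
        Z = np.random.default_rng(0).normal(size=(4, 2))
        V = tm.marginal_covariance(Z, np.zeros((2, 2)), 2.5)
        np.testing.assert_allclose(V, 2.5 * np.eye(4))

    def test_scalar_case(self):
        V = tm.marginal_covariance(np.ones((1, 1)), [[0.5]], 2.0)
        np.testing.assert_allclose(V, [[3.0]])

    def test_non_psd_rejected(self):
        with pytest.raises(ParameterError):
            tm.marginal_covariance(np.ones((2, 1)), [[-1.0]], 1.0)


class TestSubjectLoglik:
    def test_zero_residual(self):
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        beta = np.array([3.0, 1.0])
        y = X @ beta
        theta = make_params(beta, 0.0, 1.0)
        ll = tm.subject_loglik(y, X, np.ones((2, 1)), theta)
        assert ll == pytest.approx(-np.log(2 * np.pi))

    def test_matches_direct_density_oracle(self):
        y = np.array([1.2, -0.7, 2.5])
        X = np.array([[1.0, 0.0, 0.3], [1.0, 1.0, -1.2], [1.0, 2.0, 0.8]])
        beta = np.array([0.5, 0.4, -1.0])
        theta = make_params(beta, 0.5, 2.0)
        expect = mvn_logpdf_direct(y, X @ beta, random_intercept_cov(3, 0.5, 2.0))
        assert tm.subject_loglik(y, X, np.ones((3, 1)), theta) == pytest.approx(
            expect, rel=1e-12
        )

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=3)
        X = np.column_stack([np.ones(3), rng.normal(size=(3, 2))])
        theta = make_params(rng.normal(size=3), 0.8, 1.5)
        perm = [2, 0, 1]
        a = tm.subject_loglik(y, X, np.ones((3, 1)), theta)
        b = tm.subject_loglik(y[perm], X[perm], np.ones((3, 1)), theta)
        assert a == pytest.approx(b, rel=1e-12)

    def test_fast_path_agrees_with_generic(self, small_cohort):
        data, _ = small_cohort
        theta = make_params(np.zeros(data.n_covariates) + 0.3, 0.7, 4.0)
        fast = _component_logliks(data, [theta])[:, 0]
        slow = np.array(
            [
                tm.subject_loglik(data.y_i(i), data.X_i(i), data.Z_i(i), theta)
                for i in range(data.n_subjects)
            ]
        )
        np.testing.assert_allclose(fast, slow, rtol=1e-10)


class TestMixtureLoglik:
    def test_single_component_reduction(self, small_cohort):
        data, _ = small_cohort
        theta = make_params(np.ones(data.n_covariates), 0.5, 4.0, pi=1.0)
        model = MixtureModel(G=1, components=[theta])
        total = sum(
            tm.subject_loglik(data.y_i(i), data.X_i(i), data.Z_i(i), theta)
            for i in range(data.n_subjects)
        )
        assert tm.mixture_loglik(data, model) == pytest.approx(total, rel=1e-10)

    def test_duplicating_subjects_doubles(self, small_cohort):
        data, _ = small_cohort
        theta = make_params(np.ones(data.n_covariates), 0.5, 4.0, pi=1.0)
        model = MixtureModel(G=1, components=[theta])
        doubled = tm.LongitudinalDataset(
            subject_ids=np.concatenate(
                [data.subject_ids, np.char.add(data.subject_ids.astype(str), "_b")]
            ),
            y=np.concatenate([data.y, data.y]),
            X=np.vstack([data.X, data.X]),
            wave=np.concatenate([data.wave, data.wave]),
            covariate_names=data.covariate_names,
            starts=np.concatenate([data.starts, data.starts[1:] + data.n_obs]),
        )
        assert tm.mixture_loglik(doubled, model) == pytest.approx(
            2 * tm.mixture_loglik(data, model), rel=1e-12
        )

    def test_two_component_brute_force(self, small_cohort):
        data, _ = small_cohort
        p = data.n_covariates
        t1 = make_params(np.full(p, 0.5), 0.4, 3.0, pi=0.3)
        t2 = make_params(np.full(p, -0.2), 0.9, 6.0, pi=0.7)
        model = MixtureModel(G=2, components=[t1, t2])
        expect = 0.0
        for i in range(data.n_subjects):
            n_i = len(data.y_i(i))
            dens = 0.0
            for t in (t1, t2):
                dens += t.pi * np.exp(
                    mvn_logpdf_direct(
                        data.y_i(i),
                        data.X_i(i) @ t.beta,
                        random_intercept_cov(n_i, t.d, t.sigma2),
                    )
                )
            expect += np.log(dens)
        assert tm.mixture_loglik(data, model) == pytest.approx(expect, rel=1e-9)

    def test_label_permutation_invariance(self, small_cohort):
        data, _ = small_cohort
        p = data.n_covariates
        comps = [
            make_params(np.full(p, 0.5), 0.4, 3.0, pi=0.3),
            make_params(np.full(p, -0.2), 0.9, 6.0, pi=0.7),
        ]
        a = tm.mixture_loglik(data, MixtureModel(G=2, components=comps))
        b = tm.mixture_loglik(data, MixtureModel(G=2, components=comps[::-1]))
        assert a == pytest.approx(b, rel=1e-12)


class TestEStep:
    def test_identical_components_symmetric(self, small_cohort):
        data, _ = small_cohort
        p = data.n_covariates
        comps = [make_params(np.ones(p), 0.5, 4.0, pi=0.5) for _ in range(2)]
        W, pi = tm.e_step(data, MixtureModel(G=2, components=comps))
        np.testing.assert_allclose(W, 0.5)
        np.testing.assert_allclose(pi, 0.5)

    def test_degenerate_prior(self, small_cohort):
        data, _ = small_cohort
        p = data.n_covariates
        comps = [
            make_params(np.ones(p), 0.5, 4.0, pi=1.0),
            make_params(np.zeros(p), 0.5, 4.0, pi=0.0),
        ]
        W, pi = tm.e_step(data, MixtureModel(G=2, components=comps))
        np.testing.assert_allclose(W[:, 0], 1.0)
        np.testing.assert_allclose(W[:, 1], 0.0)

    def test_matches_hand_bayes_rule(self):
        # two subjects, one observation each: posterior by direct arithmetic
        data = tm.LongitudinalDataset(
            subject_ids=np.array(["a", "b"]),
            y=np.array([0.0, 3.0]),
            X=np.array([[1.0, 0.0], [1.0, 0.0]]),
            wave=np.array([0, 0]),
            covariate_names=["intercept", "wave"],
            starts=np.array([0, 1, 2]),
        )
        t1 = make_params([0.0, 0.0], 0.0, 1.0, pi=0.6)
        t2 = make_params([2.0, 0.0], 0.0, 1.0, pi=0.4)
        W, pi = tm.e_step(data, MixtureModel(G=2, components=[t1, t2]))
        from scipy.stats import norm

        for i, yv in enumerate([0.0, 3.0]):
            num = 0.6 * norm.pdf(yv, 0.0, 1.0)
            den = num + 0.4 * norm.pdf(yv, 2.0, 1.0)
            assert W[i, 0] == pytest.approx(num / den, rel=1e-12)
        np.testing.assert_allclose(pi, W.mean(axis=0))

    def test_rows_sum_to_one(self, medium_cohort):
        data, _ = medium_cohort
        p = data.n_covariates
        rng = np.random.default_rng(0)
        comps = [
            make_params(rng.normal(size=p), 0.5, 9.0, pi=w)
            for w in (0.2, 0.5, 0.3)
        ]
        W, pi = tm.e_step(data, MixtureModel(G=3, components=comps))
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,lam,expect", [(3.0, 1.0, 2.0), (-3.0, 1.0, -2.0), (0.5, 1.0, 0.0)]
    )
    def test_closed_form(self, z, lam, expect):
        assert tm.soft_threshold(z, lam) == expect

    @given(
        st.floats(-1e6, 1e6, allow_nan=False),
        st.floats(0, 1e6, allow_nan=False),
    )
    def test_shrinkage_properties(self, z, lam):
        s = tm.soft_threshold(z, lam)
        assert abs(s) <= abs(z)
        assert s * z >= 0
        assert abs(abs(z) - abs(s)) <= lam + 1e-9 * abs(z)


class TestMStep:
    def test_lambda_above_max_zeroes_all(self, medium_cohort):
        data, _ = medium_cohort
        std, _ = tm.standardize_covariates(data)
        cfg = FitConfig(seed=0)
        W = np.ones((std.n_subjects, 1))
        lam_max = tm.compute_lambda_max(std, 1, cfg)
        comps = tm.m_step(std, W, lam_max * 1.0001, cfg)
        pen = penalized_mask_for(std, cfg)
        assert np.all(comps[0].beta[pen] == 0.0)

    def test_single_cluster_matches_bruteforce_ml(self, small_cohort):
        data, _ = small_cohort
        cfg = FitConfig(seed=0, tol=1e-12, max_iter=3000, d_xatol=1e-12)
        model = tm.fit_em(data, 1, 0.0, cfg)
        comp = model.components[0]
        y_list = [data.y_i(i) for i in range(data.n_subjects)]
        X_list = [data.X_i(i) for i in range(data.n_subjects)]
        beta_o, d_o, s2_o, _ = lmm_ml_bruteforce(y_list, X_list)
        np.testing.assert_allclose(comp.beta, beta_o, rtol=1e-4, atol=1e-6)
        assert comp.d == pytest.approx(d_o, rel=1e-3, abs=1e-6)
        assert comp.sigma2 == pytest.approx(s2_o, rel=1e-4)

    def test_single_cluster_matches_statsmodels(self, small_cohort):
        """Cross-check against an independent ML LMM implementation."""
        import statsmodels.formula.api as smf

        data, _ = small_cohort
        cfg = FitConfig(seed=0, tol=1e-12, max_iter=3000)
        comp = tm.fit_em(data, 1, 0.0, cfg).components[0]
        df = data.to_frame()
        covs = [c for c in data.covariate_names if c != "intercept"]
        fit = smf.mixedlm(
            f"{data.outcome_name} ~ {' + '.join(covs)}", df, groups=df["subject_id"]
        ).fit(reml=False)
        np.testing.assert_allclose(
            comp.beta, fit.fe_params.to_numpy(), rtol=1e-3, atol=1e-4
        )
        # statsmodels reports the random-intercept variance sigma_b^2 = sigma^2 d
        assert comp.sigma2 * comp.d == pytest.approx(
            float(fit.cov_re.iloc[0, 0]), rel=5e-3
        )

    def test_hard_partition_separability(self, two_cluster_cohort):
        data, truth = two_cluster_cohort
        labels = truth["cluster"].to_numpy()
        W = np.zeros((data.n_subjects, 2))
        W[np.arange(data.n_subjects), labels] = 1.0
        cfg = FitConfig(seed=0)
        warm = [
            tm.ClusterParams(np.zeros(data.n_covariates), 0.5, 25.0, 0.5)
            for _ in range(2)
        ]
        joint = tm.m_step(data, W, 1.0, cfg, warm=warm)
        for g in range(2):
            sub = data.subset(np.where(labels == g)[0])
            solo = tm.m_step(
                sub, np.ones((sub.n_subjects, 1)), 1.0, cfg, warm=[warm[g]]
            )
            np.testing.assert_allclose(joint[g].beta, solo[0].beta, atol=1e-8)
            assert joint[g].sigma2 == pytest.approx(solo[0].sigma2, rel=1e-6)
            assert joint[g].d == pytest.approx(solo[0].d, rel=1e-4, abs=1e-6)

    def test_empty_cluster_signal(self, small_cohort):
        data, _ = small_cohort
        W = np.zeros((data.n_subjects, 2))
        W[:, 0] = 1.0  # cluster 1 empty
        with pytest.raises(EmptyClusterError):
            tm.m_step(data, W, 0.0, FitConfig(seed=0))


class TestFitEM:
    def test_single_component_reduction(self, small_cohort):
        data, _ = small_cohort
        model = tm.fit_em(data, 1, 0.0, FitConfig(seed=0))
        assert model.G == 1
        np.testing.assert_allclose(model.W, 1.0)
        assert model.components[0].pi == pytest.approx(1.0)

    def test_two_separated_clusters_recovered(self, two_cluster_cohort):
        data, truth = two_cluster_cohort
        std, _ = tm.standardize_covariates(data)
        model = tm.fit_em(std, 2, 0.0, FitConfig(seed=0, n_starts=2))
        labels = tm.assign_hard_labels(model.W)
        assert tm.adjusted_rand_index(labels, truth["cluster"]) == 1.0

    def test_trace_nondecreasing(self, medium_cohort):
        data, _ = medium_cohort
        std, _ = tm.standardize_covariates(data)
        for lam in (0.0, 2.0):
            model = tm.fit_em(std, 3, lam, FitConfig(seed=1, n_starts=2))
            for trace in model.all_traces:
                assert np.all(np.diff(trace) >= -1e-8)

    def test_g_exceeding_subjects_rejected(self, small_cohort):
        data, _ = small_cohort
        with pytest.raises(ParameterError):
            tm.fit_em(data, data.n_subjects + 1, 0.0, FitConfig(seed=0))

    def test_lambda_max_mixture_endpoint(self, medium_cohort):
        data, _ = medium_cohort
        std, _ = tm.standardize_covariates(data)
        cfg = FitConfig(seed=0, n_starts=2)
        lam_max = tm.compute_lambda_max(std, 3, cfg)
        model = tm.fit_em(std, 3, lam_max, cfg)
        pen = model.penalized_mask
        for c in model.components:
            assert np.all(c.beta[pen] == 0.0)


class TestAssignHardLabels:
    def test_argmax_and_tie_break(self):
        W = np.array([[0.9, 0.1], [0.5, 0.5], [0.1, 0.9]])
        np.testing.assert_array_equal(tm.assign_hard_labels(W), [0, 0, 1])

    def test_identity_matrix(self):
        np.testing.assert_array_equal(tm.assign_hard_labels(np.eye(4)), [0, 1, 2, 3])
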