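import json

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from twodem import (
    ExpressionMatrix,
    FeatureMatrixSet,
    MixtureModel2D,
    Responsibilities,
    adjusted_rand_index,
    e_step_2d,
    fit_2dem,
    fit_em_1d,
    fit_filter,
    log_likelihood_2d,
    log_matrix_density,
    m_step_2d,
    predict,
)
from twodem.em_core import regularize_covariance
from twodem.synthetic import (
    VectorMixtureSpec,
    simulate_matrix_mixture,
    simulate_vector_mixture,
    two_cluster_matrix_spec,
)


def _fms(mats):
    mats = np.asarray(mats, dtype=float)
    return FeatureMatrixSet(mats, [f"S{i}" for i in range(mats.shape[0])])


def _rand_pd(rng, m):
    A = rng.standard_normal((m, m))
    return A @ A.T + m * np.eye(m)


class TestLogMatrixDensity:
    def test_scalar_standard_normal(self):
        ld = log_matrix_density([[0.0]], [[0.0]], [[1.0]], mode="matrix_normal_exact")
        assert ld == pytest.approx(np.log(1 / np.sqrt(2 * np.pi)), abs=1e-12)

    def test_zero_quadratic_at_mean(self):
        rng = np.random.default_rng(0)
        C = _rand_pd(rng, 3)
        X = rng.standard_normal((3, 2))
        logdet = np.linalg.slogdet(C)[1]
        ld = log_matrix_density(X, X, C, mode="paper_literal")
        assert ld == pytest.approx(-0.5 * logdet, abs=1e-12)

    @pytest.mark.parametrize("mq", [(1, 1), (2, 3), (3, 3), (4, 2)])
    def test_kronecker_oracle(self, mq):
        # exact mode == mq-dimensional Gaussian with covariance I_q (x) C
        m, q = mq
        rng = np.random.default_rng(m * 10 + q)
        for _ in range(25):
            C = _rand_pd(rng, m)
            X = rng.standard_normal((m, q))
            M = rng.standard_normal((m, q))
            ld = log_matrix_density(X, M, C, mode="matrix_normal_exact")
            big = np.kron(np.eye(q), C)
            ref = multivariate_normal(mean=M.T.ravel(), cov=big).logpdf(X.T.ravel())
            assert ld == pytest.approx(ref, abs=1e-10)

    def test_singular_covariance_signals(self):
        with pytest.raises(np.linalg.LinAlgError):
            log_matrix_density([[0.0, 0.0]], [[0.0, 0.0]], [[0.0]])


class TestEStep:
    def test_identical_components_split_evenly(self):
        rng = np.random.default_rng(1)
        data = _fms(rng.standard_normal((4, 2, 2)))
        M = rng.standard_normal((2, 2))
        C = _rand_pd(rng, 2)
        model = MixtureModel2D(2, np.array([0.5, 0.5]), np.stack([M, M]), np.stack([C, C]))
        phi = e_step_2d(data, model).values
        np.testing.assert_allclose(phi, 0.5, atol=1e-12)

    def test_zero_prior_gets_zero_responsibility(self):
        rng = np.random.default_rng(2)
        data = _fms(rng.standard_normal((4, 2, 2)))
        Ms = rng.standard_normal((2, 2, 2))
        C = _rand_pd(rng, 2)
        model = MixtureModel2D(2, np.array([1.0, 0.0]), Ms, np.stack([C, C]))
        phi = e_step_2d(data, model).values
        np.testing.assert_array_equal(phi[:, 1], 0.0)

    def test_matches_direct_ratio_oracle(self):
        # hand evaluation without log-space of the responsibility ratio
        rng = np.random.default_rng(3)
        data = _fms(rng.standard_normal((3, 2, 2)))
        Ms = rng.standard_normal((2, 2, 2))
        Cs = np.stack([_rand_pd(rng, 2), _rand_pd(rng, 2)])
        pri = np.array([0.3, 0.7])
        model = MixtureModel2D(2, pri, Ms, Cs, mode="paper_literal")
        phi = e_step_2d(data, model).values
        for k in range(3):
            raw = []
            for i in range(2):
                R = data.matrices[k] - Ms[i]
                quad = np.trace(R.T @ np.linalg.inv(Cs[i]) @ R)
                raw.append(np.linalg.det(Cs[i]) ** -0.5 * np.exp(-0.5 * quad) * pri[i])
            np.testing.assert_allclose(phi[k], np.array(raw) / sum(raw), atol=1e-12)


class TestMStep:
    def test_uniform_weights_give_plain_moments(self):
        rng = np.random.default_rng(4)
        data = _fms(rng.standard_normal((6, 3, 3)))
        resp = Responsibilities(np.column_stack([np.ones(6), np.zeros(6)]))
        model = m_step_2d(data, resp)
        np.testing.assert_allclose(model.means[0], data.matrices.mean(axis=0), atol=1e-12)
        R = data.matrices - data.matrices.mean(axis=0)
        scatter = np.einsum("kij,klj->il", R, R) / 6
        np.testing.assert_allclose(model.covariances[0], regularize_covariance(scatter), atol=1e-12)

    def test_identical_matrices_floor_to_scaled_identity(self):
        X = np.ones((2, 2, 2))
        resp = Responsibilities(np.ones((2, 1)))
        model = m_step_2d(_fms(X), resp, reg=1e-6)
        np.testing.assert_allclose(model.covariances[0], 1e-6 * np.eye(2), atol=1e-15)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        data = _fms(rng.standard_normal((5, 2, 2)))
        phi = rng.dirichlet(np.ones(2), size=5)
        model = m_step_2d(data, Responsibilities(phi))
        for i in range(2):
            mass = phi[:, i].sum()
            M = sum(phi[k, i] * data.matrices[k] for k in range(5)) / mass
            S = sum(
                phi[k, i] * (data.matrices[k] - M) @ (data.matrices[k] - M).T for k in range(5)
            ) / mass
            np.testing.assert_allclose(model.priors[i], mass / 5, atol=1e-12)
            np.testing.assert_allclose(model.means[i], M, atol=1e-12)
            np.testing.assert_allclose(model.covariances[i], regularize_covariance(S), atol=1e-12)

    def test_covariances_symmetric_pd(self):
        rng = np.random.default_rng(6)
        data = _fms(rng.standard_normal((10, 3, 3)))
        phi = rng.dirichlet(np.ones(3), size=10)
        model = m_step_2d(data, Responsibilities(phi))
        for C in model.covariances:
            np.testing.assert_allclose(C, C.T, atol=1e-12)
            np.linalg.cholesky(C)


class TestLogLikelihood:
    def test_all_at_mean_identity_covariance(self):
        m = q = 2
        X = np.zeros((4, m, q))
        model = MixtureModel2D(
            1, np.array([1.0]), np.zeros((1, m, q)), np.eye(m)[None],
            mode="matrix_normal_exact",
        )
        L = log_likelihood_2d(_fms(X), model)
        assert L == pytest.approx(4 * (-(m * q / 2) * np.log(2 * np.pi)), abs=1e-10)

    def test_empty_cluster_leaves_likelihood_unchanged(self):
        rng = np.random.default_rng(7)
        data = _fms(rng.standard_normal((4, 2, 2)))
        M = rng.standard_normal((2, 2))
        C = _rand_pd(rng, 2)
        m1 = MixtureModel2D(1, np.array([1.0]), M[None], C[None])
        m2 = MixtureModel2D(2, np.array([1.0, 0.0]), np.stack([M, M + 1]), np.stack([C, C]))
        assert log_likelihood_2d(data, m1) == pytest.approx(log_likelihood_2d(data, m2), abs=1e-10)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(8)
        data = _fms(rng.standard_normal((5, 2, 2)))
        Ms = rng.standard_normal((2, 2, 2))
        Cs = np.stack([_rand_pd(rng, 2), _rand_pd(rng, 2)])
        model = MixtureModel2D(2, np.array([0.4, 0.6]), Ms, Cs, mode="matrix_normal_exact")
        ref = 0.0
        for k in range(5):
            tot = 0.0
            for i in range(2):
                tot += model.priors[i] * np.exp(
                    log_matrix_density(data.matrices[k], Ms[i], Cs[i], "matrix_normal_exact")
                )
            ref += np.log(tot)
        assert log_likelihood_2d(data, model) == pytest.approx(ref, abs=1e-10)


class TestFit2DEM:
    def test_single_cluster_closed_form(self):
        rng = np.random.default_rng(9)
        data = _fms(rng.standard_normal((8, 2, 2)))
        res = fit_2dem(data, 1, seed=0, n_restarts=1)
        np.testing.assert_allclose(res.model.means[0], data.matrices.mean(axis=0), atol=1e-10)
        assert res.model.priors[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["paper_literal", "matrix_normal_exact"])
    def test_loglik_trace_monotone(self, mode):
        spec = two_cluster_matrix_spec((20, 20), m=3, separation=3.0, seed=10)
        data, _ = simulate_matrix_mixture(spec)
        res = fit_2dem(data, 2, seed=1, n_restarts=3, mode=mode)
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs >= -1e-8 * np.abs(res.loglik_trace[:-1]))

    def test_separated_clusters_recovered(self):
        spec = two_cluster_matrix_spec((40, 40), m=4, separation=8.0, seed=11)
        data, truth = simulate_matrix_mixture(spec)
        res = fit_2dem(data, 2, seed=2, n_restarts=5, mode="matrix_normal_exact")
        assert adjusted_rand_index(res.labels, truth) >= 0.95

    def test_labels_are_argmax_responsibilities(self):
        spec = two_cluster_matrix_spec((15, 15), m=3, separation=4.0, seed=12)
        data, _ = simulate_matrix_mixture(spec)
        res = fit_2dem(data, 2, seed=3, n_restarts=2)
        np.testing.assert_array_equal(res.labels.labels, res.responsibilities.values.argmax(1))

    def test_c_exceeding_n_errors(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError):
            fit_2dem(_fms(rng.standard_normal((3, 2, 2))), 4)

    def test_restart_records_allow_averaging(self):
        spec = two_cluster_matrix_spec((10, 10), m=2, separation=5.0, seed=14)
        data, _ = simulate_matrix_mixture(spec)
        res = fit_2dem(data, 2, seed=4, n_restarts=4)
        assert len(res.restart_logliks) == 4
        assert max(res.restart_logliks) == pytest.approx(res.loglik_trace[-1])
        assert all(len(lab) == data.n for lab in res.restart_labels)

    def test_same_seed_reproducible(self):
        spec = two_cluster_matrix_spec((10, 10), m=3, separation=3.0, seed=15)
        data, _ = simulate_matrix_mixture(spec)
        r1 = fit_2dem(data, 2, seed=5, n_restarts=3)
        r2 = fit_2dem(data, 2, seed=5, n_restarts=3)
        np.testing.assert_array_equal(r1.labels.labels, r2.labels.labels)
        np.testing.assert_array_equal(r1.loglik_trace, r2.loglik_trace)


class TestReductionToVectorEM:
    def test_q1_trajectories_match_classical_em(self):
        # folding an n x m table as m x 1 matrices must reproduce vector EM
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(2.5, 1, (20, 3))])
        data = FeatureMatrixSet(X.reshape(40, 3, 1), [f"S{i}" for i in range(40)])
        r2 = fit_2dem(
            data, 2, seed=6, n_restarts=1, mode="matrix_normal_exact",
            record_params=True, tol=1e-12, max_iter=40,
        )
        r1 = fit_em_1d(X, 2, seed=6, n_restarts=1, record_params=True, tol=1e-12, max_iter=40)
        assert len(r2.param_trace) == len(r1.param_trace)
        for (p2, m2, c2), (p1, m1, c1) in zip(r2.param_trace, r1.param_trace):
            np.testing.assert_allclose(p2, p1, atol=1e-8)
            np.testing.assert_allclose(m2[:, :, 0], m1, atol=1e-8)
            np.testing.assert_allclose(c2, c1, atol=1e-8)
        np.testing.assert_allclose(r2.loglik_trace, r1.loglik_trace, atol=1e-8)

    def test_1d_recovers_separated_means(self):
        rng = np.random.default_rng(17)
        X = np.concatenate([rng.normal(0, 1, 60), rng.normal(6, 1, 60)])[:, None]
        res = fit_em_1d(X, 2, seed=7, n_restarts=3)
        mus = np.sort(res.model.means.ravel())
        # within 3 standard errors of the component means
        se = 1 / np.sqrt(60)
        assert abs(mus[0] - 0) < 3 * se and abs(mus[1] - 6) < 3 * se

    def test_1d_single_cluster_closed_form(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((20, 2))
        res = fit_em_1d(X, 1, seed=8, n_restarts=1)
        np.testing.assert_allclose(res.model.means[0], X.mean(axis=0), atol=1e-10)


class TestPermutationEquivariance:
    def test_cluster_relabeling_permutes_output(self):
        spec = two_cluster_matrix_spec((12, 12), m=2, separation=6.0, seed=19)
        data, _ = simulate_matrix_mixture(spec)
        phi0 = np.zeros((24, 2))
        phi0[:12, 0] = phi0[12:, 1] = 1.0
        m_a = m_step_2d(data, Responsibilities(phi0))
        m_b = m_step_2d(data, Responsibilities(phi0[:, ::-1].copy()))
        np.testing.assert_allclose(m_a.means, m_b.means[::-1], atol=1e-12)
        np.testing.assert_allclose(m_a.covariances, m_b.covariances[::-1], atol=1e-12)
        phi_a = e_step_2d(data, m_a).values
        phi_b = e_step_2d(data, m_b).values
        np.testing.assert_allclose(phi_a, phi_b[:, ::-1], atol=1e-12)


@pytest.fixture(scope="module")
def fitted_pipeline():
    spec = VectorMixtureSpec(n_per_cluster=(25, 25), d=800, n_informative=16, effect=5.0, seed=20)
    E, truth, _ = simulate_vector_mixture(spec)
    filt, fms = fit_filter(E, 2, cutoff=0.01)
    res = fit_2dem(fms, 2, seed=9, n_restarts=5)
    return E, truth, filt, res


class TestPredict:
    def test_training_matrix_reproduces_fit_labels(self, fitted_pipeline):
        E, _, filt, res = fitted_pipeline
        lv = predict(res.model, filt, E)
        np.testing.assert_array_equal(lv.labels, res.labels.labels)

    def test_shuffled_columns_same_labels(self, fitted_pipeline):
        E, _, filt, res = fitted_pipeline
        perm = np.random.default_rng(21).permutation(E.d)
        Eshuf = ExpressionMatrix(
            E.values[:, perm], list(E.sample_ids), [E.feature_ids[j] for j in perm]
        )
        np.testing.assert_array_equal(predict(res.model, filt, Eshuf).labels, res.labels.labels)

    def test_missing_features_error(self, fitted_pipeline):
        E, _, filt, res = fitted_pipeline
        Esub = ExpressionMatrix(E.values[:, :3], list(E.sample_ids), E.feature_ids[:3])
        with pytest.raises(ValueError, match="selected features"):
            predict(res.model, filt, Esub)

    def test_sample_at_component_mean_assigned_there(self):
        rng = np.random.default_rng(22)
        Ms = rng.standard_normal((2, 2, 2)) * 5
        C = np.eye(2)
        model = MixtureModel2D(2, np.array([0.5, 0.5]), Ms, np.stack([C, C]))
        data = _fms(Ms.copy())
        phi = e_step_2d(data, model).values
        assert phi.argmax(1).tolist() == [0, 1]


class TestModelSerialization:
    def test_json_roundtrip(self, tmp_path, fitted_pipeline):
        _, _, _, res = fitted_pipeline
        p = tmp_path / "model.json"
        with open(p, "w") as fh:
            json.dump(res.model.to_json_dict(), fh)
        back = MixtureModel2D.from_json_dict(json.loads(p.read_text()))
        np.testing.assert_array_equal(back.priors, res.model.priors)
        np.testing.assert_array_equal(back.means, res.model.means)
        np.testing.assert_array_equal(back.covariances, res.model.covariances)
        assert back.mode == res.model.mode
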