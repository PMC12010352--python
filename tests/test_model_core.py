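import numpy as np
import pytest
import scipy.optimize
import scipy.stats

from snchamp.model_core import (
    LeadField,
    NoiseModel,
    SensorDataset,
    champagne_cost,
    compute_model_covariance,
    compute_posterior_sources,
    update_source_variances,
)

from conftest import random_problem, random_spd


class TestLeadField:
    def test_rejects_bad_norms_when_flagged(self, rng):
        g = rng.standard_normal((4, 6))
        with pytest.raises(ValueError, match="unit-norm"):
            LeadField(g, np.zeros((6, 3)), normalized=True)

    def test_rejects_zero_column_on_normalize(self, rng):
        g = rng.standard_normal((4, 6))
        g[:, 2] = 0.0
        lf = LeadField(g, np.zeros((6, 3)))
        with pytest.raises(ValueError, match="zero column"):
            lf.normalized_copy()

    def test_normalized_copy_unit_columns(self, rng):
        lf = LeadField(rng.standard_normal((5, 8)), np.zeros((8, 3)))
        norms = np.linalg.norm(lf.normalized_copy().gain, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-12)

    def test_coord_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="voxel_coords"):
            LeadField(rng.standard_normal((4, 6)), np.zeros((5, 3)))


class TestSensorDataset:
    def test_times_default_spacing(self):
        d = SensorDataset(np.zeros((3, 10)), fs=100.0)
        assert np.allclose(np.diff(d.times), 0.01)

    def test_bad_times_rejected(self):
        with pytest.raises(ValueError, match="1/fs"):
            SensorDataset(np.zeros((2, 4)), fs=100.0, times=np.array([0, 1, 2, 3.0]))

    def test_nonfinite_rejected(self):
        y = np.zeros((2, 3))
        y[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            SensorDataset(y, fs=100.0)


class TestNoiseModel:
    def test_precision_inverts(self, rng):
        cov = random_spd(rng, 5)
        nm = NoiseModel(cov)
        assert np.allclose(nm.precision @ cov, np.eye(5), atol=1e-6)

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            NoiseModel(rng.standard_normal((4, 4)))

    def test_negative_eigenvalues_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            NoiseModel(np.diag([1.0, -0.5]))


class TestModelCovariance:
    def test_zero_variances_give_noise(self, rng):
        data, lf, noise = random_problem(rng)
        Sy = compute_model_covariance(lf, np.zeros(lf.n), noise)
        assert np.allclose(Sy, noise.covariance)

    def test_identity_case(self):
        lf = LeadField(np.eye(3), np.zeros((3, 3)), normalized=True)
        Sy = compute_model_covariance(lf, np.ones(3), NoiseModel(np.eye(3)))
        assert np.allclose(Sy, 2 * np.eye(3))

    def test_monte_carlo_oracle(self):
        # K -> infinity sample covariance of simulated generative-model data
        rng = np.random.default_rng(7)
        m, n, K = 6, 10, 200_000
        L = rng.standard_normal((m, n))
        lf = LeadField(L, np.zeros((n, 3)))
        v = rng.uniform(0.1, 2.0, size=n)
        noise_cov = random_spd(rng, m) / m
        Sy = compute_model_covariance(lf, v, NoiseModel(noise_cov))
        x = rng.standard_normal((n, K)) * np.sqrt(v)[:, None]
        z = np.linalg.cholesky(noise_cov) @ rng.standard_normal((m, K))
        y = L @ x + z
        sample = (y @ y.T) / K
        rel = np.linalg.norm(sample - Sy) / np.linalg.norm(Sy)
        assert rel < 0.02

    def test_dimension_mismatch(self, rng):
        data, lf, noise = random_problem(rng, m=4, n=6)
        with pytest.raises(ValueError, match="length"):
            compute_model_covariance(lf, np.ones(5), noise)

    def test_nonfinite_variances(self, rng):
        data, lf, noise = random_problem(rng)
        v = np.ones(lf.n)
        v[0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            compute_model_covariance(lf, v, noise)

    def test_symmetry_preserved(self, rng):
        data, lf, noise = random_problem(rng)
        Sy = compute_model_covariance(lf, rng.uniform(0, 1, lf.n), noise)
        assert np.array_equal(Sy, Sy.T)


class TestPosteriorSources:
    def test_zero_variances_zero_posterior(self, rng):
        data, lf, noise = random_problem(rng)
        xbar, _ = compute_posterior_sources(data, lf, np.zeros(lf.n), noise)
        assert np.array_equal(xbar, np.zeros((lf.n, data.K)))

    def test_scalar_wiener_filter(self):
        lf = LeadField([[1.0]], np.zeros((1, 3)), normalized=True)
        data = SensorDataset([[2.0]], fs=1.0)
        xbar, _ = compute_posterior_sources(data, lf, np.ones(1), NoiseModel([[1.0]]))
        assert xbar[0, 0] == pytest.approx(1.0)  # 2 * 1/(1+1)

    def test_inversion_lemma_oracle(self):
        # diag(v) L^T Sigma_y^-1 y  ==  Gamma^-1 L^T Lambda y  (active voxels)
        rng = np.random.default_rng(11)
        for _ in range(20):
            data, lf, noise = random_problem(rng, m=5, n=8, K=3)
            v = rng.uniform(0.05, 2.0, size=lf.n)
            xbar, info = compute_posterior_sources(
                data, lf, v, noise, return_precision=True
            )
            gamma = info["posterior_precision"]
            alt = np.linalg.solve(gamma, lf.gain.T @ noise.precision @ data.y)
            assert np.max(np.abs(xbar - alt)) < 1e-9

    def test_posterior_precision_excludes_pruned(self, rng):
        data, lf, noise = random_problem(rng, m=4, n=6, K=5)
        v = np.array([1.0, 0.0, 0.5, 0.0, 2.0, 1.0])
        xbar, info = compute_posterior_sources(data, lf, v, noise, return_precision=True)
        assert info["posterior_precision"].shape == (4, 4)
        assert np.array_equal(xbar[~info["active"]], np.zeros((2, data.K)))


class TestChampagneCost:
    def test_zero_data_logdet(self, rng):
        Sy = random_spd(rng, 4)
        data = SensorDataset(np.zeros((4, 6)), fs=100.0)
        assert champagne_cost(data, Sy) == pytest.approx(np.linalg.slogdet(Sy)[1])

    def test_scalar_case(self):
        data = SensorDataset([[2.0]], fs=1.0)
        assert champagne_cost(data, np.array([[1.0]])) == pytest.approx(4.0)

    def test_log_density_oracle(self, rng):
        # F == -(2/K) * joint log-density - m log(2 pi)
        for _ in range(10):
            m, K = int(rng.integers(2, 6)), int(rng.integers(2, 9))
            Sy = random_spd(rng, m)
            data = SensorDataset(rng.standard_normal((m, K)), fs=100.0)
            logp = scipy.stats.multivariate_normal(np.zeros(m), Sy).logpdf(data.y.T)
            oracle = -(2.0 / K) * np.sum(logp) - m * np.log(2 * np.pi)
            assert champagne_cost(data, Sy) == pytest.approx(oracle, abs=1e-9)


class TestVarianceUpdate:
    def test_zero_row_gives_zero_variance(self, rng):
        data, lf, noise = random_problem(rng, m=4, n=6, K=5)
        Sy = compute_model_covariance(lf, np.ones(lf.n), noise)
        xbar = rng.standard_normal((lf.n, 5))
        xbar[2] = 0.0
        v, g = update_source_variances(xbar, lf, Sy)
        assert v[2] == 0.0
        assert np.all(v >= 0)
        assert np.all(g > 0)

    def test_grid_search_oracle(self):
        # scalar bound h(v) = mean(xbar^2)/v + g v; update must hit its argmin
        rng = np.random.default_rng(3)
        lf = LeadField([[1.0]], np.zeros((1, 3)), normalized=True)
        for _ in range(5):
            K = 7
            y = rng.standard_normal((1, K)) * 2
            noise = NoiseModel([[0.3]])
            v0 = float(rng.uniform(0.5, 2.0))
            Sy = compute_model_covariance(lf, [v0], noise)
            data = SensorDataset(y, fs=1.0)
            xbar, _ = compute_posterior_sources(data, lf, [v0], noise, Sigma_y=Sy)
            v_new, g = update_source_variances(xbar, lf, Sy)
            msq = float(np.mean(xbar**2))
            grid = np.linspace(1e-6, 10, 200_001)
            h = msq / grid + g[0] * grid
            v_grid = grid[np.argmin(h)]
            res = scipy.optimize.minimize_scalar(
                lambda v: msq / v + g[0] * v, bracket=(v_grid / 2, v_grid, v_grid * 2)
            )
            assert v_new[0] == pytest.approx(res.x, rel=1e-6)

    def test_zero_leadfield_column_warns(self, rng):
        g = rng.standard_normal((4, 5))
        g[:, 1] = 0.0
        lf = LeadField(g, np.zeros((5, 3)))
        noise = NoiseModel(np.eye(4))
        Sy = compute_model_covariance(lf, np.ones(5), noise)
        with pytest.warns(RuntimeWarning, match="zero lead-field"):
            v, _ = update_source_variances(rng.standard_normal((5, 3)), lf, Sy)
        assert v[1] == 0.0

    def test_as_printed_mode_differs(self, rng):
        data, lf, noise = random_problem(rng, m=4, n=6, K=10)
        Sy = compute_model_covariance(lf, np.ones(lf.n), noise)
        xbar, _ = compute_posterior_sources(data, lf, np.ones(lf.n), noise, Sigma_y=Sy)
        v_sqrt, g = update_source_variances(xbar, lf, Sy, variance_update="sqrt")
        v_raw, _ = update_source_variances(xbar, lf, Sy, variance_update="as_printed")
        # sqrt form is the square root of the printed form's ratio
        assert np.allclose(v_sqrt, np.sqrt(v_raw), atol=1e-12)
        assert not np.allclose(v_sqrt, v_raw)


def test_full_sweep_monotonicity(rng):
    # 100 random instances, several sweeps each: cost never increases
    for _ in range(100):
        data, lf, noise = random_problem(rng)
        v = np.ones(lf.n)
        prev = None
        for _ in range(5):
            Sy = compute_model_covariance(lf, v, noise)
            cost = champagne_cost(data, Sy)
            if prev is not None:
                assert cost <= prev + 1e-8 * abs(prev)
            prev = cost
            xbar, _ = compute_posterior_sources(data, lf, v, noise, Sigma_y=Sy)
            v, _ = update_source_variances(xbar, lf, Sy)


def test_single_source_concentration_noiseless_limit():
    # with Sigma_n = sigma^2 I, sigma^2 -> 0, power concentrates on the true voxel
    rng = np.random.default_rng(21)
    m, n, K = 12, 30, 40
    L = rng.standard_normal((m, n))
    L /= np.linalg.norm(L, axis=0)
    lf = LeadField(L, np.zeros((n, 3)), normalized=True)
    s = np.sin(2 * np.pi * 5 * np.arange(K) / 100)
    data = SensorDataset(np.outer(L[:, 7], s), fs=100.0)
    noise = NoiseModel(1e-8 * np.eye(m))
    v = np.ones(n)
    for _ in range(200):
        Sy = compute_model_covariance(lf, v, noise)
        xbar, _ = compute_posterior_sources(data, lf, v, noise, Sigma_y=Sy)
        v, _ = update_source_variances(xbar, lf, Sy)
    power = np.mean(xbar**2, axis=1)
    assert np.argmax(power) == 7
    assert power[7] > 100 * np.sort(power)[-2]
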