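"""Gaussian host model: closed-form fit, log-density scoring, persistence.

The scoring path (Cholesky solve) is checked against two independent
oracles: an explicit inverse/determinant implementation and
scipy.stats.multivariate_normal.
"""

import numpy as np
import pytest
from scipy import stats

from phagehost import VirusHostGaussian, VirusHostGaussianResults
from phagehost.errors import (
    EmptyTrainingError,
    InvalidInputError,
    ModelFormatError,
    SingularModelError,
)

_LOG_2PI = np.log(2.0 * np.pi)


def explicit_log_density(x, mean, cov):
    """Independent oracle: explicit matrix inverse and determinant."""
    d = len(mean)
    diff = np.asarray(x, float) - mean
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    return -0.5 * (d * _LOG_2PI + logdet + diff @ np.linalg.inv(cov) @ diff)


def random_wellconditioned_results(rng, d):
    """A random fitted-model stand-in with a well-conditioned covariance."""
    A = rng.standard_normal((d, d))
    cov = A @ A.T / d + np.eye(d)
    cov = (cov + cov.T) / 2.0
    mean = rng.standard_normal(d) * 0.1
    return VirusHostGaussianResults(
        mean=mean, covariance=cov, reg_covar=0.0, k=None, n_train=d
    )


class TestFit:
    def test_single_row_gives_point_mean_and_diagonal_covariance(self, rng):
        x = rng.standard_normal(8)
        res = VirusHostGaussian(x[None, :]).fit(reg_covar=1e-3)
        assert np.array_equal(res.mean, x)
        assert np.array_equal(res.covariance, 1e-3 * np.eye(8))

    def test_one_dimensional_mle(self):
        # rows {0, 2}: mean 1, ML variance ((0-1)^2 + (2-1)^2)/2 = 1
        res = VirusHostGaussian(np.array([[0.0], [2.0]])).fit(reg_covar=0.0)
        assert res.mean[0] == pytest.approx(1.0)
        assert res.covariance[0, 0] == pytest.approx(1.0)

    def test_mle_divides_by_n_not_n_minus_1(self, rng):
        X = rng.standard_normal((7, 3))
        res = VirusHostGaussian(X).fit(reg_covar=0.0)
        assert np.allclose(res.covariance, np.cov(X.T, bias=True), atol=1e-12)

    def test_parameter_recovery_from_known_gaussian(self, rng):
        d = 5
        mean = rng.standard_normal(d)
        A = rng.standard_normal((d, d))
        cov = A @ A.T / d + np.eye(d)
        X = rng.multivariate_normal(mean, cov, size=2000)
        res = VirusHostGaussian(X).fit(reg_covar=0.0)
        marg_sd = np.sqrt(np.diag(cov))
        assert (np.abs(res.mean - mean) < 0.1 * marg_sd).all()
        rel = np.linalg.norm(res.covariance - cov) / np.linalg.norm(cov)
        assert rel < 0.10

    def test_empty_training_rejected(self):
        with pytest.raises(EmptyTrainingError):
            VirusHostGaussian(np.empty((0, 4))).fit()

    def test_singular_without_regularization(self, rng):
        row = rng.standard_normal(6)
        X = np.tile(row, (5, 1))  # zero scatter
        with pytest.raises(SingularModelError, match="reg_covar"):
            VirusHostGaussian(X).fit(reg_covar=0.0)
        # the same data fits fine once regularized
        VirusHostGaussian(X).fit(reg_covar=1e-6)

    def test_negative_reg_covar_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            VirusHostGaussian(rng.standard_normal((3, 2))).fit(reg_covar=-1.0)

    def test_k_dimension_consistency(self, rng):
        with pytest.raises(InvalidInputError):
            VirusHostGaussian(rng.standard_normal((3, 10)), k=4)


class TestLogScore:
    def test_standard_normal_mode(self):
        res = VirusHostGaussianResults(
            mean=np.zeros(1), covariance=np.eye(1), reg_covar=0.0, k=None, n_train=1
        )
        assert res.log_score(np.zeros(1)) == pytest.approx(-0.918939, abs=1e-6)

    def test_identity_covariance_at_mean_d256(self):
        res = VirusHostGaussianResults(
            mean=np.zeros(256), covariance=np.eye(256), reg_covar=0.0, k=4, n_train=1
        )
        assert res.log_score(np.zeros(256)) == pytest.approx(-128 * _LOG_2PI)

    def test_matches_explicit_inverse_oracle(self, rng):
        res = random_wellconditioned_results(rng, 5)
        for _ in range(100):
            x = rng.standard_normal(5)
            assert res.log_score(x) == pytest.approx(
                explicit_log_density(x, res.mean, res.covariance), abs=1e-8
            )

    def test_matches_scipy_multivariate_normal(self, rng):
        res = random_wellconditioned_results(rng, 12)
        mvn = stats.multivariate_normal(mean=res.mean, cov=res.covariance)
        X = rng.standard_normal((50, 12))
        assert np.allclose(res.log_score_batch(X), mvn.logpdf(X), atol=1e-8)

    def test_batch_equals_scalar(self, rng):
        res = random_wellconditioned_results(rng, 7)
        X = rng.standard_normal((20, 7))
        batch = res.log_score_batch(X)
        assert np.allclose(batch, [res.log_score(x) for x in X], atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        res = random_wellconditioned_results(rng, 4)
        with pytest.raises(InvalidInputError):
            res.log_score(np.zeros(5))
        with pytest.raises(InvalidInputError):
            res.log_score_batch(np.zeros((3, 5)))

    def test_maximized_at_mean(self, rng):
        res = random_wellconditioned_results(rng, 10)
        at_mode = res.log_score(res.mean)
        perturbed = res.mean + rng.standard_normal((1000, 10)) * 0.5
        assert (res.log_score_batch(perturbed) < at_mode).all()

    def test_ranking_equals_negative_mahalanobis(self, rng):
        res = random_wellconditioned_results(rng, 6)
        inv = np.linalg.inv(res.covariance)
        X = rng.standard_normal((40, 6))
        maha = np.array([(x - res.mean) @ inv @ (x - res.mean) for x in X])
        by_score = np.argsort(-res.log_score_batch(X))
        by_maha = np.argsort(maha)
        assert np.array_equal(by_score, by_maha)

    def test_log_det_monotone_in_reg_covar(self, rng):
        X = rng.standard_normal((20, 8))
        model = VirusHostGaussian(X)
        log_dets = [model.fit(reg_covar=r).log_det_cov for r in (0.0, 1e-6, 1e-3, 1e-1, 1.0)]
        assert all(a <= b + 1e-12 for a, b in zip(log_dets, log_dets[1:]))


class TestPersistence:
    def test_round_trip_is_bit_identical(self, rng, tmp_path):
        X = rng.standard_normal((30, 16))
        res = VirusHostGaussian(X, k=2).fit(reg_covar=1e-6, label="unit")
        path = tmp_path / "model.npz"
        res.save(path)
        loaded = VirusHostGaussianResults.load(path)
        assert loaded.k == 2 and loaded.d == 16 and loaded.n_train == 30
        assert loaded.reg_covar == res.reg_covar
        assert np.array_equal(loaded.mean, res.mean)
        assert np.array_equal(loaded.covariance, res.covariance)
        probes = rng.standard_normal((10, 16))
        assert np.array_equal(res.log_score_batch(probes), loaded.log_score_batch(probes))
        assert loaded.metadata["training_label"] == "unit"

    def test_inconsistent_k_d_rejected(self, rng, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(
            path,
            format_version=np.int64(1),
            k=np.int64(4),
            d=np.int64(10),  # != 4**4
            reg_covar=np.float64(1e-6),
            n_train=np.int64(3),
            mean=np.zeros(10),
            covariance=np.eye(10),
            metadata_json=np.str_("{}"),
        )
        with pytest.raises(ModelFormatError, match="4\\*\\*4"):
            VirusHostGaussianResults.load(path)

    def test_truncated_file_is_a_format_error(self, rng, tmp_path):
        res = VirusHostGaussian(rng.standard_normal((5, 4))).fit()
        path = tmp_path / "model.npz"
        res.save(path)
        blob = path.read_bytes()
        trunc = tmp_path / "trunc.npz"
        trunc.write_bytes(blob[: len(blob) // 2])
        with pytest.raises(ModelFormatError):
            VirusHostGaussianResults.load(trunc)

    def test_garbage_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "garbage.npz"
        path.write_text("this is not a model")
        with pytest.raises(ModelFormatError):
            VirusHostGaussianResults.load(path)


def test_results_reject_asymmetric_covariance():
    cov = np.eye(3)
    cov[0, 1] = 1e-6  # asymmetry above the 1e-10 tolerance
    with pytest.raises(InvalidInputError, match="symmetric"):
        VirusHostGaussianResults(
            mean=np.zeros(3), covariance=cov, reg_covar=0.0, k=None, n_train=1
        )


def test_summary_mentions_key_quantities(rng):
    res = VirusHostGaussian(rng.standard_normal((12, 16)), k=2).fit(label="demo")
    text = res.summary()
    for token in ("16", "12", "reg_covar", "demo", "log|covariance|"):
        assert token in text
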