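"""Feature embedding, free energy, and the variational-Laplace scheme."""

import numpy as np
import pytest

from synaptrack.inversion import (
    FeatureVector,
    InversionSettings,
    defeaturize,
    featurize,
    free_energy,
    variational_laplace,
)


def random_hermitian_stack(rng, n_w=5, n_f=7, n_ch=2):
    raw = rng.standard_normal((n_w, n_f, n_ch, n_ch)) + 1j * rng.standard_normal(
        (n_w, n_f, n_ch, n_ch)
    )
    return raw + raw.conj().swapaxes(-1, -2)


class TestFeaturize:
    def test_round_trip_on_random_hermitian_stacks(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            csd = random_hermitian_stack(rng)
            fv = featurize(csd)
            assert np.allclose(defeaturize(fv), csd)

    def test_canonical_length(self):
        rng = np.random.default_rng(1)
        csd = random_hermitian_stack(rng, n_w=18, n_f=41, n_ch=2)
        fv = featurize(csd)
        # 3 real + 1 imaginary components per 2x2 Hermitian matrix
        assert fv.values.size == 18 * 41 * 4
        assert fv.n_components == 4

    def test_real_csd_has_zero_imaginary_block(self):
        rng = np.random.default_rng(2)
        csd = random_hermitian_stack(rng).real.astype(complex)
        fv = featurize(csd)
        comps = fv.values.reshape(fv.n_windows, fv.n_freqs, fv.n_components)
        assert np.allclose(comps[..., len(fv.re_pairs):], 0.0)

    def test_index_map_is_lossless(self):
        rng = np.random.default_rng(3)
        csd = random_hermitian_stack(rng, n_w=2, n_f=3)
        fv = featurize(csd)
        idx = fv.index_map()
        rebuilt = np.zeros_like(csd)
        for val, (w, f, i, j, im) in zip(fv.values, idx):
            if im:
                rebuilt[w, f, i, j] += 1j * val
                rebuilt[w, f, j, i] += -1j * val
            else:
                rebuilt[w, f, i, j] += val
                if i != j:
                    rebuilt[w, f, j, i] += val
        assert np.allclose(rebuilt, csd)


def conjugate_posterior(X, y, mu0, Sigma0, sig2):
    Pi = X.T @ X / sig2 + np.linalg.inv(Sigma0)
    cov = np.linalg.inv(Pi)
    mean = cov @ (X.T @ y / sig2 + np.linalg.inv(Sigma0) @ mu0)
    return mean, cov


def gaussian_log_evidence(X, y, mu0, Sigma0, sig2):
    N = y.size
    Sy = X @ Sigma0 @ X.T + sig2 * np.eye(N)
    e = y - X @ mu0
    return -0.5 * (N * np.log(2 * np.pi) + np.linalg.slogdet(Sy)[1] + e @ np.linalg.solve(Sy, e))


@pytest.fixture(scope="module")
def linear_toy():
    rng = np.random.default_rng(42)
    n, N = 3, 40
    X = rng.standard_normal((N, n))
    Sigma0 = np.diag([0.5, 1.0, 2.0])
    mu0 = np.array([0.1, -0.2, 0.3])
    sig2 = 0.3
    theta = rng.multivariate_normal(mu0, Sigma0)
    y = X @ theta + rng.normal(0, np.sqrt(sig2), N)
    return X, y, mu0, Sigma0, sig2


class TestFreeEnergy:
    def test_complexity_zero_when_posterior_equals_prior(self, linear_toy):
        X, y, mu0, Sigma0, sig2 = linear_toy
        fe = free_energy(mu0, Sigma0, y, lambda th: X @ th, mu0, Sigma0, 1.0 / sig2)
        assert fe.complexity == pytest.approx(0.0, abs=1e-10)

    def test_converged_f_equals_closed_form_evidence(self, linear_toy):
        X, y, mu0, Sigma0, sig2 = linear_toy
        mean, cov = conjugate_posterior(X, y, mu0, Sigma0, sig2)
        fe = free_energy(mean, cov, y, lambda th: X @ th, mu0, Sigma0, 1.0 / sig2)
        assert fe.total == pytest.approx(gaussian_log_evidence(X, y, mu0, Sigma0, sig2), abs=1e-6)

    def test_prior_widening_changes_complexity_by_analytic_kl(self, linear_toy):
        X, y, mu0, Sigma0, sig2 = linear_toy
        mean, cov = conjugate_posterior(X, y, mu0, Sigma0, sig2)
        f1 = free_energy(mean, cov, y, lambda th: X @ th, mu0, Sigma0, 1.0 / sig2)
        wide = np.e * Sigma0
        f2 = free_energy(mean, cov, y, lambda th: X @ th, mu0, wide, 1.0 / sig2)

        def kl(Sp):
            Pi = np.linalg.inv(Sp)
            e = mean - mu0
            return 0.5 * (
                np.trace(Pi @ cov) + e @ Pi @ e - mu0.size
                + np.linalg.slogdet(Sp)[1] - np.linalg.slogdet(cov)[1]
            )

        assert f2.complexity - f1.complexity == pytest.approx(kl(wide) - kl(Sigma0), abs=1e-9)


class TestVariationalLaplace:
    def test_matches_conjugate_closed_forms(self, linear_toy):
        """Linear-Gaussian model with fixed noise: posterior mean, covariance
        and free energy agree with the conjugate solution to 1e-6."""
        X, y, mu0, Sigma0, sig2 = linear_toy
        res = variational_laplace(
            y, lambda th: X @ th, mu0, Sigma0,
            InversionSettings(max_iter=32, tol=1e-10, n_converged=2),
            fixed_noise_precision=1.0 / sig2,
        )
        mean, cov = conjugate_posterior(X, y, mu0, Sigma0, sig2)
        assert res.converged
        assert np.abs(res.mean - mean).max() < 1e-6
        assert np.abs(res.cov - cov).max() < 1e-6
        assert res.F == pytest.approx(gaussian_log_evidence(X, y, mu0, Sigma0, sig2), abs=1e-6)

    def test_sequential_update_equals_joint_inversion(self, linear_toy):
        """Using the first half's posterior as the second half's prior
        reproduces the joint posterior (conjugate sequential oracle)."""
        X, y, mu0, Sigma0, sig2 = linear_toy
        st = InversionSettings(max_iter=32, tol=1e-12, n_converged=2)
        half = y.size // 2
        r1 = variational_laplace(y[:half], lambda th: X[:half] @ th, mu0, Sigma0, st,
                                 fixed_noise_precision=1.0 / sig2)
        r2 = variational_laplace(y[half:], lambda th: X[half:] @ th, r1.mean, r1.cov, st,
                                 fixed_noise_precision=1.0 / sig2)
        joint = variational_laplace(y, lambda th: X @ th, mu0, Sigma0, st,
                                    fixed_noise_precision=1.0 / sig2)
        assert np.abs(r2.mean - joint.mean).max() < 1e-6
        assert np.abs(r2.cov - joint.cov).max() < 1e-6

    def test_nonlinear_model_trace_monotone_and_cov_psd(self):
        rng = np.random.default_rng(5)
        theta_true = np.array([0.6, -0.4])
        t = np.linspace(0, 1, 30)

        def h(th):
            return np.exp(th[0] * t) * np.sin(3 * t + th[1])

        y = h(theta_true) + 0.05 * rng.standard_normal(t.size)
        res = variational_laplace(
            y, h, np.zeros(2), np.eye(2), InversionSettings(max_iter=32),
            fixed_noise_precision=1.0 / 0.05**2,
        )
        assert np.all(np.diff(res.trace) >= 0)
        assert np.linalg.eigvalsh(res.cov).min() > -1e-10
        assert np.abs(res.mean - theta_true).max() < 0.05

    def test_noise_precision_estimated_per_band(self):
        rng = np.random.default_rng(6)
        N = 400
        X = rng.standard_normal((N, 2))
        y = X @ np.array([1.0, -1.0]) + np.concatenate(
            [rng.normal(0, 0.1, N // 2), rng.normal(0, 0.5, N // 2)]
        )
        masks = [np.arange(N) < N // 2, np.arange(N) >= N // 2]
        res = variational_laplace(y, lambda th: X @ th, np.zeros(2), 4 * np.eye(2),
                                  InversionSettings(max_iter=32), band_masks=masks)
        est_sd = np.exp(-res.lam / 2)
        assert est_sd[0] == pytest.approx(0.1, rel=0.3)
        assert est_sd[1] == pytest.approx(0.5, rel=0.3)


class TestCMCInversionStructure:
    """Structural contracts on a real (small) spectral inversion."""

    def test_fixed_parameters_never_move(self, quick_inversion):
        post = quick_inversion["posterior"]
        # untracked intrinsic edges have zero prior variance: not free
        assert post.index_of("intrinsic", (0, 0)) is None
        assert post.variance_of("intrinsic", (0, 0)) == 0.0
        assert post.mean_of("intrinsic", (0, 0)) == 0.0

    def test_trace_non_decreasing(self, quick_inversion):
        trace = quick_inversion["posterior"].trace
        assert np.all(np.diff(trace) >= 0)

    def test_posterior_covariance_psd(self, quick_inversion):
        cov = quick_inversion["posterior"].cov
        assert np.linalg.eigvalsh(cov).min() >= -1e-10

    def test_hdf5_round_trip(self, quick_inversion, tmp_path):
        from synaptrack.inversion import Posterior

        post = quick_inversion["posterior"]
        path = tmp_path / "post.h5"
        post.to_hdf5(path)
        back = Posterior.from_hdf5(path)
        assert np.allclose(back.mean, post.mean)
        assert np.allclose(back.cov, post.cov)
        assert back.base_entries == post.base_entries
        assert back.coef_slices == post.coef_slices
        assert back.free_energy == pytest.approx(post.free_energy)


class TestSelfConsistency:
    def test_noiseless_data_at_prior_means_keeps_posterior_there(self):
        """Data generated exactly at the prior expectations with no noise:
        the free log-scalings stay within 0.05 of zero."""
        from synaptrack.inversion import invert
        from synaptrack.model_space import ModelSpec
        from synaptrack.synthetic import generate_dataset, true_trajectories

        truth = true_trajectories(amplitudes={})  # no changes anywhere
        ds = generate_dataset(truth, snr=np.inf, seed=0)
        spec = ModelSpec(flags=(False, False, False, False))
        post = invert(ds.data, spec, settings=InversionSettings(max_iter=8))
        assert np.abs(post.mean).max() < 0.05
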