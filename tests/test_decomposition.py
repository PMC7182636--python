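import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from sfica.decomposition import (ComplexFastICA, ComplexPCA, complex_fastica,
                                 complex_pca, fourier_ica, unmix)


def _matched_abs_corr(est: np.ndarray, truth: np.ndarray) -> float:
    """Min over optimally matched pairs of |corr| between magnitude rows."""
    k = truth.shape[0]
    C = np.abs(np.corrcoef(np.abs(est), np.abs(truth))[:est.shape[0], est.shape[0]:])
    rows, cols = linear_sum_assignment(-C)
    return C[rows, cols].min()


def _complex_laplacian_sources(k, n, rng):
    mag = rng.exponential(1.0, (k, n))
    return mag * np.exp(2j * np.pi * rng.uniform(size=(k, n)))


class TestComplexPCA:
    def test_whitened_covariance_is_identity(self, rng):
        X0 = rng.standard_normal((20, 500)) + 1j * rng.standard_normal(
            (20, 500))
        Z, _, _, _ = complex_pca(X0, order=10)
        cov = Z @ Z.conj().T / Z.shape[1]
        assert np.abs(cov - np.eye(10)).max() < 1e-8

    def test_low_rank_reconstruction(self, rng):
        A = rng.standard_normal((12, 3)) + 1j * rng.standard_normal((12, 3))
        S = rng.standard_normal((3, 300)) + 1j * rng.standard_normal((3, 300))
        X0 = A @ S
        Z, K, Kinv, _ = complex_pca(X0, order=3)
        Xc = X0 - X0.mean(axis=1, keepdims=True)
        rel = np.linalg.norm(Kinv @ Z - Xc) / np.linalg.norm(Xc)
        assert rel < 1e-8

    def test_eigenvalues_match_svd_oracle(self, rng):
        X0 = rng.standard_normal((6, 40)) + 1j * rng.standard_normal((6, 40))
        _, _, _, eigvals = complex_pca(X0, order=6)
        Xc = X0 - X0.mean(axis=1, keepdims=True)
        sv = np.linalg.svd(Xc, compute_uv=False)
        assert np.allclose(eigvals, sv ** 2 / 40, atol=1e-10)

    def test_order_beyond_rank_reports_rank(self, rng):
        A = rng.standard_normal((10, 3))
        X0 = A @ rng.standard_normal((3, 200))
        with pytest.raises(ValueError, match="rank 3"):
            complex_pca(X0, order=5)

    def test_sklearn_style_roundtrip(self, rng):
        X = rng.standard_normal((200, 8)) + 1j * rng.standard_normal((200, 8))
        pca = ComplexPCA(n_components=8)
        Z = pca.fit_transform(X)
        assert np.allclose(pca.inverse_transform(Z), X, atol=1e-8)
        assert pca.get_params() == {"n_components": 8}


class TestComplexFastICA:
    def test_recovers_unitary_mixture(self, rng):
        S = _complex_laplacian_sources(4, 20000, rng)
        Q = np.linalg.qr(rng.standard_normal((4, 4))
                         + 1j * rng.standard_normal((4, 4)))[0]
        dec = fourier_ica(Q @ S, order=4, seed=1)
        assert _matched_abs_corr(dec.S_hat, S) > 0.95

    def test_unmixing_matrix_is_unitary(self, rng):
        Z, *_ = complex_pca(
            rng.standard_normal((8, 2000)) + 1j * rng.standard_normal(
                (8, 2000)), order=6)
        W = complex_fastica(Z, seed=0).matrix
        assert np.abs(W @ W.conj().T - np.eye(6)).max() < 1e-8

    def test_same_seed_reproduces_exactly(self, rng):
        Z, *_ = complex_pca(_complex_laplacian_sources(3, 5000, rng)
                            * 1.0, order=3)
        W1 = complex_fastica(Z, seed=7).matrix
        W2 = complex_fastica(Z, seed=7).matrix
        assert np.array_equal(W1, W2)

    def test_seeds_agree_up_to_permutation_and_phase(self, rng):
        S = _complex_laplacian_sources(3, 50000, rng)
        A = rng.standard_normal((10, 3)) + 1j * rng.standard_normal((10, 3))
        X0 = A @ S + 0.001 * (rng.standard_normal((10, 50000))
                              + 1j * rng.standard_normal((10, 50000)))
        Z, *_ = complex_pca(X0, order=3)
        S1 = complex_fastica(Z, seed=1).matrix @ Z
        S2 = complex_fastica(Z, seed=2).matrix @ Z
        assert _matched_abs_corr(S1, S2) > 0.999

    def test_unwhitened_input_rejected(self, rng):
        Z = 5.0 * rng.standard_normal((4, 1000))
        with pytest.raises(ValueError, match="whiten"):
            complex_fastica(Z)


class TestUnmix:
    def test_full_order_reconstruction_is_exact(self, rng):
        X0 = (rng.standard_normal((6, 500))
              + 1j * rng.standard_normal((6, 500)))
        dec = fourier_ica(X0, order=6, seed=0)
        assert np.linalg.norm(dec.reconstruct() - X0) \
            < 1e-8 * np.linalg.norm(X0)

    def test_residual_equals_eigenvalue_tail(self, rng):
        A = rng.standard_normal((30, 5)) + 1j * rng.standard_normal((30, 5))
        S = _complex_laplacian_sources(5, 3000, rng)
        X0 = A @ S + 0.1 * (rng.standard_normal((30, 3000))
                            + 1j * rng.standard_normal((30, 3000)))
        dec = fourier_ica(X0, order=5, seed=0)
        Xc = X0 - X0.mean(axis=1, keepdims=True)
        resid = np.linalg.norm(Xc - dec.A_hat @ dec.S_hat) ** 2
        tail = dec.eigenvalues[5:].sum() * X0.shape[1]
        assert abs(resid / np.linalg.norm(Xc) ** 2
                   - tail / (dec.eigenvalues.sum() * X0.shape[1])) < 1e-6

    def test_scaling_is_linear(self, rng):
        X0 = _complex_laplacian_sources(4, 2000, rng)
        c = 2.0 - 1.5j
        d1 = fourier_ica(X0, order=4, seed=3)
        d2 = fourier_ica(c * X0, order=4, seed=3)
        assert np.allclose(d2.reconstruct(), c * d1.reconstruct(), atol=1e-6)

    def test_planted_network_energy_concentrates(self, small_subject):
        dm = small_subject["dm"]
        truth = small_subject["truth"]
        dec = fourier_ica(dm.X0, order=6, seed=3)
        freqs = dm.freqs
        net = truth.networks[0]
        # pick the component whose spatial power matches the planted map
        best, best_r = 0, 0.0
        for k in range(6):
            row = dec.S_hat[k].reshape(dm.n_sources, dm.n_freqs)
            power = np.mean(np.abs(row) ** 2, axis=1)
            r = abs(np.corrcoef(power, net.weights ** 2)[0, 1])
            if r > best_r:
                best, best_r = k, r
        row = dec.S_hat[best].reshape(dm.n_sources, dm.n_freqs)
        support_v = net.weights > 0.1 * net.weights.max()
        fbin = int(np.argmin(np.abs(freqs - net.carrier_freq)))
        sel = np.abs(row[support_v, max(0, fbin - 2):fbin + 3]) ** 2
        assert sel.sum() / (np.abs(row) ** 2).sum() >= 0.5

    def test_sklearn_estimator_orientation(self, rng):
        # fit on X0.T: mixing_ columns are temporal envelopes
        S = _complex_laplacian_sources(3, 4000, rng)
        A = rng.standard_normal((50, 3)) + 1j * rng.standard_normal((50, 3))
        est = ComplexFastICA(n_components=3, random_state=0)
        sources = est.fit_transform((A @ S).T)
        assert est.mixing_.shape == (50, 3)
        assert sources.shape == (4000, 3)
        assert _matched_abs_corr(sources.T, S) > 0.95
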