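"""Complex-valued PCA and FastICA for spatial Fourier-ICA.

The design matrix X0 (n_times x n_freqs*n_sources) is modelled as
X0 = A S: each row (one 1-s STFT window) is a linear mixture of a small
number of spatial-spectral patterns (rows of S), with complex temporal
mixing weights (columns of A) whose moduli are amplitude-envelope time
courses.

Estimators follow the scikit-learn convention (samples in rows), so they
are fit on ``X0.T``; :func:`complex_pca` / :func:`complex_fastica` /
:func:`unmix` expose the same computation in the X0 = A S orientation.

The FastICA variant is the fixed-point algorithm for circular complex
sources with the robust contrast G(u) = sqrt(eps + u) on u = |w^H z|^2 and
symmetric (parallel) orthogonalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ComplexPCA", "ComplexFastICA", "FourierICADecomposition",
           "complex_pca", "complex_fastica", "unmix", "fourier_ica"]


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """Return (W W^H)^(-1/2) W (rows become orthonormal)."""
    vals, vecs = np.linalg.eigh(W @ W.conj().T)
    vals = np.maximum(vals, 1e-300)
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.conj().T @ W


class ComplexPCA:
    """PCA by Hermitian eigendecomposition of complex data.

    Parameters
    ----------
    n_components : int or None
        Dimension to keep (all if None).

    Attributes
    ----------
    mean_ : (n_features,) complex
        Per-feature mean removed before the covariance.
    eigenvalues_ : (n_components,) float
        Real nonnegative covariance eigenvalues, descending.
    all_eigenvalues_ : (n_features,) float
        Full spectrum (for reconstruction-error accounting).
    whitener_ : (n_components, n_features) complex
        ``z = whitener_ @ x`` has identity covariance.
    dewhitener_ : (n_features, n_components) complex
        Maps whitened data back: ``x ~ dewhitener_ @ z + mean_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "ComplexPCA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "ComplexPCA":
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        n, d = X.shape
        k = d if self.n_components is None else int(self.n_components)
        if k < 1 or k > d:
            raise ValueError("n_components out of range")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        C = (Xc.T @ Xc.conj()) / n           # Hermitian (d x d)
        vals, vecs = np.linalg.eigh(C)
        vals = np.maximum(vals[::-1].real, 0.0)
        vecs = vecs[:, ::-1]
        tol = max(n, d) * np.finfo(float).eps * (vals[0] if vals.size else 0.0)
        rank = int((vals > tol).sum())
        if k > rank:
            raise ValueError(
                f"n_components={k} exceeds numerical rank {rank}")
        self.all_eigenvalues_ = vals
        self.eigenvalues_ = vals[:k]
        E = vecs[:, :k]
        self.whitener_ = (E / np.sqrt(vals[:k])).conj().T
        self.dewhitener_ = E * np.sqrt(vals[:k])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean_) @ self.whitener_.T

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z) @ self.dewhitener_.T + self.mean_


class ComplexFastICA:
    """Complex FastICA with whitening, in scikit-learn orientation.

    ``fit(X)`` with X (n_samples, n_features) estimates
    ``X = sources @ mixing_.T + mean_``; for spatial Fourier-ICA, pass
    ``X0.T`` so that ``mixing_`` is the temporal mixing matrix A
    (n_times x n_components) and ``sources_.T`` holds the spatial-spectral
    patterns S.

    Parameters
    ----------
    n_components : int or None
        Number of components (PCA order).
    eps : float
        Stabilizer of the contrast G(u) = sqrt(eps + u).
    max_iter, tol : convergence controls
        Iteration stops when ``1 - min_j |<w_j_new, w_j_old>| < tol``.
    random_state : int or Generator
        Seeds the random unitary initialization.
    """

    def __init__(self, n_components: int | None = None, *, eps: float = 0.1,
                 max_iter: int = 1000, tol: float = 1e-6,
                 random_state: int | None = None):
        self.n_components = n_components
        self.eps = eps
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "eps": self.eps,
                "max_iter": self.max_iter, "tol": self.tol,
                "random_state": self.random_state}

    def set_params(self, **params) -> "ComplexFastICA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "ComplexFastICA":
        self.fit_transform(X)
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        X = np.asarray(X)
        self.pca_ = ComplexPCA(self.n_components).fit(X)
        Z = self.pca_.transform(X)                # (n, k) white
        W = complex_fastica(Z.T, seed=self.random_state,
                            max_iter=self.max_iter, tol=self.tol,
                            eps=self.eps)
        self.W_ = W.matrix
        self.n_iter_ = W.n_iter
        self.converged_ = W.converged
        self.components_ = self.W_ @ self.pca_.whitener_
        self.mixing_ = self.pca_.dewhitener_ @ self.W_.conj().T
        self.mean_ = self.pca_.mean_
        sources = Z @ self.W_.T
        self.sources_ = sources
        return sources

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean_) @ self.components_.T


@dataclass
class _UnitaryResult:
    matrix: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class FourierICADecomposition:
    """Result of complex ICA on the design matrix (X0 = A S orientation)."""

    A_hat: np.ndarray          # (n_times, n_components) complex mixing
    S_hat: np.ndarray          # (n_components, n_samples) complex sources
    whitener: np.ndarray
    dewhitener: np.ndarray
    row_means: np.ndarray      # per-row mean of X0 removed before PCA
    eigenvalues: np.ndarray    # full covariance spectrum
    n_iter: int = 0
    converged: bool = True
    seed: int | None = None

    @property
    def n_components(self) -> int:
        return self.S_hat.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Rank-k reconstruction of X0 (row means restored)."""
        return self.A_hat @ self.S_hat + self.row_means[:, None]


def complex_pca(X0: np.ndarray, order: int = 20):
    """Whiten the design matrix in the X0 = A S orientation.

    Returns ``(Z, whitener, dewhitener, eigvals)`` with Z (order, m),
    whitener (order, n_times), dewhitener (n_times, order); ``eigvals``
    is the full real, nonnegative, descending covariance spectrum.
    """
    pca = ComplexPCA(order).fit(np.asarray(X0).T)
    Z = pca.transform(np.asarray(X0).T).T
    return Z, pca.whitener_, pca.dewhitener_, pca.all_eigenvalues_


def complex_fastica(Z: np.ndarray, seed=None, max_iter: int = 1000,
                    tol: float = 1e-6, eps: float = 0.1) -> _UnitaryResult:
    """Fixed-point complex FastICA on whitened data Z (order, n_samples).

    Returns the unitary unmixing matrix W (rows are unit vectors,
    ``W W^H = I``) together with the iteration count and convergence flag.
    Estimated sources are ``W @ Z``.
    """
    Z = np.asarray(Z)
    k, n = Z.shape
    cov = Z @ Z.conj().T / n
    if np.abs(cov - np.eye(k)).max() > 1e-3:
        raise ValueError("input to complex_fastica must be whitened")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((k, k)) + 1j * rng.standard_normal((k, k))
    W = _sym_decorrelate(W)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Y = W @ Z
        U = np.abs(Y) ** 2
        g = 1.0 / (2.0 * np.sqrt(eps + U))
        gp = -1.0 / (4.0 * (eps + U) ** 1.5)
        W1 = (Y * g) @ Z.conj().T / n \
            - np.mean(g + U * gp, axis=1)[:, None] * W
        W1 = _sym_decorrelate(W1)
        crit = 1.0 - np.abs(np.diag(W1 @ W.conj().T)).min()
        W = W1
        if crit < tol:
            converged = True
            break
    return _UnitaryResult(matrix=W, n_iter=it, converged=converged)


def unmix(X0: np.ndarray, whitener: np.ndarray, dewhitener: np.ndarray,
          W, eigenvalues: np.ndarray | None = None,
          seed: int | None = None) -> FourierICADecomposition:
    """Assemble the decomposition: S = W K (X0 - means), A = K^+ W^H."""
    X0 = np.asarray(X0)
    Wm = W.matrix if isinstance(W, _UnitaryResult) else np.asarray(W)
    if whitener.shape[1] != X0.shape[0] or Wm.shape[1] != whitener.shape[0]:
        raise ValueError("inconsistent shapes in unmix")
    row_means = X0.mean(axis=1)
    Z = whitener @ (X0 - row_means[:, None])
    S_hat = Wm @ Z
    A_hat = dewhitener @ Wm.conj().T
    n_iter = W.n_iter if isinstance(W, _UnitaryResult) else 0
    converged = W.converged if isinstance(W, _UnitaryResult) else True
    if eigenvalues is None:
        eigenvalues = np.array([])
    return FourierICADecomposition(
        A_hat=A_hat, S_hat=S_hat, whitener=whitener, dewhitener=dewhitener,
        row_means=row_means, eigenvalues=np.asarray(eigenvalues),
        n_iter=n_iter, converged=converged, seed=seed)


def fourier_ica(X0: np.ndarray, order: int = 20, seed: int | None = None,
                max_iter: int = 1000, tol: float = 1e-6,
                eps: float = 0.1) -> FourierICADecomposition:
    """One-shot complex PCA + FastICA of a design matrix."""
    Z, K, Kinv, eigvals = complex_pca(X0, order)
    W = complex_fastica(Z, seed=seed, max_iter=max_iter, tol=tol, eps=eps)
    return unmix(X0, K, Kinv, W, eigenvalues=eigvals, seed=seed)
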