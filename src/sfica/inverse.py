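"""Minimum-norm inverse operator with depth weighting.

Maps sensor data (real or complex) to distributed source amplitudes:

    G = R L' (L R L' + lambda2 * c * I)^-1

with diagonal depth weights R_vv = ||L[:, v]||^(-2 * depth_gamma) and
c = trace(L R L') / Nc, so lambda2 is scale-free (identity noise
covariance; no noise modelling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LeadField", "InverseOperator", "compute_inverse_operator",
           "apply_inverse"]


@dataclass
class LeadField:
    """Forward gain matrix L (n_channels x n_sources)."""

    L: np.ndarray
    source_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.ndim != 2:
            raise ValueError("L must be 2-D")
        if not np.isfinite(self.L).all():
            raise ValueError("L contains non-finite entries")
        nc, ns = self.L.shape
        if ns < nc:
            raise ValueError("expect n_sources >= n_channels")

    @property
    def n_channels(self) -> int:
        return self.L.shape[0]

    @property
    def n_sources(self) -> int:
        return self.L.shape[1]


@dataclass
class InverseOperator:
    """Linear inverse G (n_sources x n_channels) with its settings."""

    G: np.ndarray
    lambda2: float
    depth_gamma: float


def compute_inverse_operator(lf: LeadField | np.ndarray,
                             lambda2: float = 0.1,
                             depth_gamma: float = 0.8) -> InverseOperator:
    """Build the depth-weighted, trace-normalized ridge inverse.

    ``depth_gamma = 0`` disables depth weighting; ``lambda2 -> 0`` with a
    full-row-rank lead field approaches the Moore–Penrose pseudoinverse.
    """
    if not isinstance(lf, LeadField):
        lf = LeadField(L=lf)
    L = lf.L
    nc = lf.n_channels
    col_norms = np.linalg.norm(L, axis=0)
    if lambda2 < 0:
        raise ValueError("lambda2 must be nonnegative")
    if depth_gamma != 0 and (col_norms == 0).any():
        raise ValueError("zero lead-field column; depth weighting undefined")
    r = col_norms ** (-2.0 * depth_gamma) if depth_gamma != 0 \
        else np.ones(lf.n_sources)
    RLt = r[:, None] * L.T                     # R L'
    gram = L @ RLt                             # L R L'
    c = np.trace(gram) / nc
    A = gram + lambda2 * c * np.eye(nc)
    if lambda2 == 0 and np.linalg.matrix_rank(gram) < nc:
        raise np.linalg.LinAlgError(
            "rank-deficient lead field with lambda2=0 is not invertible")
    G = RLt @ np.linalg.solve(A, np.eye(nc))
    return InverseOperator(G=G, lambda2=lambda2, depth_gamma=depth_gamma)


def apply_inverse(inv: InverseOperator, Y: np.ndarray) -> np.ndarray:
    """Project sensor data to source space: ``G @ Y`` (complex allowed)."""
    Y = np.asarray(Y)
    if Y.shape[0] != inv.G.shape[1]:
        raise ValueError(
            f"Y has {Y.shape[0]} rows but inverse expects {inv.G.shape[1]}")
    return inv.G @ Y
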