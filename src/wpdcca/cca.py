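"""Canonical correlation analysis as second-order blind source separation.

Given a multichannel matrix ``X`` (here: the wavelet packet sub-band
components of a single channel), a surrogate set ``Y`` is formed from the sum
of each channel's temporal neighbours, ``y_t = x_{t-1} + x_{t+1}``.  CCA then
finds weight vectors ``w_x`` maximizing the correlation between ``w_x^T X``
and ``w_y^T Y``; because ``Y`` is a lag structure of ``X`` itself, the
canonical sources ``S = W X`` are maximally autocorrelated and mutually
uncorrelated.  The canonical correlations are the square roots of the
eigenvalues of ``Cxx^-1 Cxy Cyy^-1 Cyx``; only this x-side eigenproblem needs
solving.

Artifact sources are removed by zeroing rows of ``S`` and back-projecting
through ``W^-1``; summing the back-projected channels collapses the sub-band
matrix back into a single cleaned signal.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg

from .errors import DataError, NumericalError

__all__ = [
    "CCADecomposition",
    "neighbor_surrogate",
    "cca_fit",
    "remix",
    "collapse",
]

#: Ridge added to the within-set covariances (scaled by trace/M); wavelet
#: sub-band channels can be near-collinear.
COV_RIDGE = 1e-10


def neighbor_surrogate(X: np.ndarray) -> np.ndarray:
    """Neighbour-sum surrogate ``y_t = x_{t-1} + x_{t+1}``, per channel.

    Returns the surrogate for the interior samples only, shape ``(M, T-2)``;
    pair it with ``X[:, 1:-1]`` for covariance computation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 3:
        raise DataError(f"need at least 3 samples for the neighbour surrogate, "
                        f"got {X.shape[1]}")
    return X[:, :-2] + X[:, 2:]


@dataclasses.dataclass
class CCADecomposition:
    """Un-mixing result: sources ``S = W (X - mean)``, correlations descending.

    Sources are unit-variance with sign fixed so that each correlates
    non-negatively with the summed input channels (pure conventions; the
    back-projection is invariant to them).
    """

    sources: np.ndarray
    W: np.ndarray
    rho: np.ndarray
    means: np.ndarray
    _W_pinv: "np.ndarray | None" = dataclasses.field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return int(self.W.shape[0])

    @property
    def W_inv(self) -> np.ndarray:
        """Pseudo-inverse of the un-mixing matrix (tolerates rank deficiency)."""
        if self._W_pinv is None:
            self._W_pinv = np.linalg.pinv(self.W)
        return self._W_pinv


def cca_fit(X: np.ndarray) -> CCADecomposition:
    """Fit CCA between ``X`` and its neighbour-sum surrogate.

    ``X`` is ``M x T`` with ``M >= 2`` channels.  The x-side generalized
    eigenproblem is solved in whitened coordinates (Cholesky of the
    regularized ``Cxx``), which keeps the problem symmetric and the
    eigenvalues real.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    M, T = X.shape
    if M < 2:
        raise DataError(f"CCA needs at least two input channels, got {M}")
    if T - 2 <= M:
        raise DataError(f"record too short for CCA: T={T}, M={M}")
    means = X.mean(axis=1)
    Xc = X - means[:, None]
    Xi = Xc[:, 1:-1]
    Y = Xc[:, :-2] + Xc[:, 2:]
    Xi = Xi - Xi.mean(axis=1, keepdims=True)
    Y = Y - Y.mean(axis=1, keepdims=True)
    n = T - 2
    Cxx = (Xi @ Xi.T) / n
    Cyy = (Y @ Y.T) / n
    Cxy = (Xi @ Y.T) / n
    Cxx += (COV_RIDGE * np.trace(Cxx) / M) * np.eye(M)
    Cyy += (COV_RIDGE * np.trace(Cyy) / M) * np.eye(M)
    try:
        Lx = linalg.cholesky(Cxx, lower=True)
        A = linalg.solve_triangular(Lx, Cxy, lower=True)       # Lx^-1 Cxy
        B = A @ linalg.solve(Cyy, A.T, assume_a="pos")          # symmetric PSD
    except linalg.LinAlgError as exc:
        raise NumericalError(f"singular covariance in CCA fit: {exc}") from exc
    B = (B + B.T) / 2.0
    eigvals, U = linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    rho = np.sqrt(np.clip(eigvals[order], 0.0, 1.0))
    # back-transform whitened eigenvectors to w_x; rows of W
    Wx = linalg.solve_triangular(Lx.T, U[:, order], lower=False)
    W = Wx.T
    sources = W @ Xc
    sd = sources.std(axis=1)
    sd[sd == 0] = 1.0
    W = W / sd[:, None]
    sources = sources / sd[:, None]
    channel_sum = Xc.sum(axis=0)
    for k in range(M):
        c = float(sources[k] @ channel_sum)
        if c < 0:
            W[k] = -W[k]
            sources[k] = -sources[k]
    return CCADecomposition(sources=sources, W=W, rho=rho, means=means)


def remix(dec: CCADecomposition, removed: "set[int] | frozenset[int]") -> np.ndarray:
    """Back-project sources to channel space with the given rows zeroed."""
    removed = frozenset(int(k) for k in removed)
    M = dec.n_components
    if not removed <= frozenset(range(M)):
        raise DataError(f"removed indices {sorted(removed)} outside 0..{M - 1}")
    if len(removed) == M:
        raise DataError("refusing to remove every component "
                        "(result would be the channel means only)")
    S = dec.sources.copy()
    if removed:
        S[sorted(removed), :] = 0.0
    return dec.W_inv @ S + dec.means[:, None]


def collapse(X_hat: np.ndarray) -> np.ndarray:
    """Sum the back-projected channels into a single signal."""
    return np.asarray(X_hat, dtype=float).sum(axis=0)
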