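"""PCA baseline: explained-variance curve per number of latent variables.

PCA decomposes a data matrix into loadings and scores, ``X = W @ T``,
capturing the maximum variance per latent variable; it is the standard
tool for the latent structure of flux data and the natural benchmark for
a mode-constrained decomposition.  Because the mode decomposition's
explained variance uses the uncentered total sum of squares, the default
curve here is likewise uncentered (cumulative squared singular values
over the squared Frobenius norm), making the two curves directly
comparable; conventional column-centering is available via ``centered``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import ValidationError

__all__ = ["PCAResult", "pca_variance_curve"]


@dataclass(frozen=True)
class PCAResult:
    """Cumulative explained-variance curve plus loadings and scores.

    ``loadings[:, :k] @ scores[:k, :]`` is the best rank-``k``
    approximation of the (optionally centered) data.
    """

    variance_curve: tuple[float, ...]
    loadings: np.ndarray      # fluxes x n_lv
    scores: np.ndarray        # n_lv x experiments
    centered: bool
    row_means: np.ndarray


def pca_variance_curve(V_mes: np.ndarray, max_lv: int | None = None, centered: bool = False) -> PCAResult:
    """Explained-variance curve of PCA on a flux matrix (fluxes x experiments).

    Uncentered mode: curve ``k`` is the sum of the top-``k`` squared
    singular values over the total squared Frobenius norm.  Centered mode
    subtracts each flux row's mean first (variance is then measured about
    the mean).
    """
    X = np.asarray(V_mes, dtype=float)
    if X.ndim != 2:
        raise ValidationError("flux matrix must be 2-D")
    if np.all(X == 0.0):
        raise ValidationError("flux matrix is identically zero")
    row_means = X.mean(axis=1, keepdims=True) if centered else np.zeros((X.shape[0], 1))
    Xc = X - row_means
    rank_cap = min(X.shape)
    if max_lv is None:
        max_lv = rank_cap
    if max_lv > rank_cap:
        raise ValidationError(f"max_lv={max_lv} exceeds min(n_fluxes, n_experiments)={rank_cap}")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tss = float(np.sum(Xc * Xc))
    if tss == 0.0:
        raise ValidationError("centered flux matrix has zero variance")
    curve = tuple(np.cumsum(s[:max_lv] ** 2) / tss)
    return PCAResult(
        variance_curve=curve,
        loadings=U[:, :max_lv],
        scores=s[:max_lv, None] * Vt[:max_lv, :],
        centered=centered,
        row_means=row_means,
    )
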