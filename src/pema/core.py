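"""Sequential nonnegative deflation of flux data onto unit-norm modes.

Given unit-norm candidate columns ``e_n`` and a residual flux matrix
``V``, the per-experiment weights of a mode are its clipped projections

    p_n = max(e_n^T V, 0)

(negative raw weights conflict with the nonnegativity of mode
contributions and are zeroed).  The mode's contribution is the rank-one
outer product ``e_n p_n^T`` and its merit is the explained variance

    theta = 1 - ||V_mes - V_est||_F^2 / ||V_mes||_F^2

which, for contributions produced by this project-clip-deflate sequence,
reduces to the accumulated ``sum(p_n^2) / ||V_mes||_F^2``.  The greedy
("best first") decomposition repeatedly scores every remaining candidate
on the current residual, selects the best, subtracts its contribution
and iterates, stopping at the requested factor count or at the number of
measured fluxes, whichever comes first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import ValidationError
from .preprocess import ScaledProblem

__all__ = [
    "GreedyTrace",
    "project_weights",
    "contribution",
    "explained_variance_direct",
    "explained_variance_fast",
    "deflate",
    "mode_gains",
    "greedy_fit",
]


@dataclass(frozen=True)
class GreedyTrace:
    """Outcome of the greedy decomposition.

    ``theta_curve[i]`` is the cumulative explained-variance fraction
    after ``i + 1`` selected modes; ``weights_norm`` are the per-mode,
    per-experiment clipped projections on the unit-norm columns and
    ``weights`` the same divided by the original column norms.
    """

    selected_ids: tuple[str, ...]
    theta_curve: tuple[float, ...]
    weights_norm: np.ndarray      # n_selected x n_d
    weights: np.ndarray           # n_selected x n_d, unscaled
    residual: np.ndarray          # n_mes x n_d


def project_weights(e_n: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Clipped projection weights of a unit-norm mode onto each experiment."""
    e_n = np.asarray(e_n, dtype=float)
    if abs(np.linalg.norm(e_n) - 1.0) > 1e-12:
        raise ValidationError("mode vector must have unit 2-norm")
    if e_n.shape[0] != V.shape[0]:
        raise ValidationError(f"shape mismatch: mode {e_n.shape} vs data {V.shape}")
    return np.maximum(e_n @ V, 0.0)


def contribution(e_n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Rank-one flux contribution ``e_n p^T`` of a mode with weights *p*."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValidationError("weights must be nonnegative")
    return np.outer(e_n, p)


def explained_variance_direct(V_mes: np.ndarray, V_est: np.ndarray) -> float:
    """Explained variance of an estimate: ``1 - RSS / TSS`` (uncentered).

    May be negative for a poor estimate; never clamped.
    """
    if V_mes.shape != V_est.shape:
        raise ValidationError("shape mismatch between data and estimate")
    tss = float(np.sum(V_mes * V_mes))
    if tss == 0.0:
        raise ValidationError("total sum of squares is zero")
    rss = float(np.sum((V_mes - V_est) ** 2))
    return 1.0 - rss / tss


def explained_variance_fast(weights_norm, V_mes: np.ndarray) -> float:
    """Explained variance from accumulated clipped projections.

    For weights produced by the project-clip-deflate sequence this equals
    :func:`explained_variance_direct` of the cumulative reconstruction:
    each deflation removes exactly ``sum(p^2)`` of squared Frobenius norm.
    """
    tss = float(np.sum(V_mes * V_mes))
    if tss == 0.0:
        raise ValidationError("total sum of squares is zero")
    W = np.asarray(weights_norm, dtype=float)
    if W.size == 0:
        return 0.0
    return float(np.sum(W * W)) / tss


def deflate(V_iter: np.ndarray, V_est_selected: np.ndarray) -> np.ndarray:
    """Subtract a selected mode's contribution from the running residual."""
    if V_iter.shape != V_est_selected.shape:
        raise ValidationError("shape mismatch in deflation")
    return V_iter - V_est_selected


def mode_gains(E_norm: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Captured squared norm ``sum_k max(e_j^T V_k, 0)^2`` for every column.

    Vectorized kernel used by both the greedy and the branch-and-bound
    searches: one matrix product scores all candidates on a residual.
    """
    P = np.maximum(E_norm.T @ V, 0.0)
    return np.einsum("jk,jk->j", P, P)


def _argbest(gains: np.ndarray, ids, tie_tol: float) -> int:
    """Index of the largest gain; ties within *tie_tol* -> lowest id."""
    best = float(np.max(gains))
    tied = np.flatnonzero(gains >= best - tie_tol)
    return int(min(tied, key=lambda i: ids[i]))


def greedy_fit(problem: ScaledProblem, n_fac: int, tie_tol: float = 1e-12) -> GreedyTrace:
    """Best-first decomposition of the scaled data onto candidate modes.

    At each iteration every remaining candidate is scored by its variance
    gain on the current residual; the best (ties broken by lowest mode
    id) is selected and its contribution deflated.  The iteration count
    is capped at ``min(n_fac, number of measured fluxes)``.
    """
    if n_fac < 1:
        raise ValidationError("n_fac must be >= 1")
    if problem.m_prime == 0:
        raise ValidationError("problem has no candidate modes")
    n_steps = min(n_fac, problem.n_mes)
    tss = problem.total_ss
    V = problem.V.copy()
    remaining = list(range(problem.m_prime))
    selected: list[int] = []
    curve: list[float] = []
    weights_norm: list[np.ndarray] = []
    captured = 0.0
    for _ in range(n_steps):
        if not remaining:
            break
        gains = mode_gains(problem.E_norm[:, remaining], V)
        ids = [problem.kept_mode_ids[i] for i in remaining]
        pick = remaining[_argbest(gains, ids, tie_tol * tss)]
        e = problem.E_norm[:, pick]
        p = project_weights(e, V)
        V = deflate(V, contribution(e, p))
        captured += float(np.sum(p * p))
        selected.append(pick)
        remaining.remove(pick)
        weights_norm.append(p)
        curve.append(captured / tss)
    W = np.array(weights_norm) if weights_norm else np.zeros((0, problem.n_d))
    norms = problem.column_norms[selected] if selected else np.zeros(0)
    return GreedyTrace(
        selected_ids=tuple(problem.kept_mode_ids[i] for i in selected),
        theta_curve=tuple(curve),
        weights_norm=W,
        weights=W / norms[:, None] if selected else W,
        residual=V,
    )
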