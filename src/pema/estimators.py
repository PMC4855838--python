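"""Scikit-learn style estimators wrapping the decomposition pipeline.

:class:`PEMA` is dictionary-constrained: like
:class:`sklearn.decomposition.SparseCoder` it takes a fixed component
matrix (the candidate elementary modes) and fits only the subset
selection and the nonnegative weights.  ``X`` follows the scikit-learn
orientation, samples (experiments) in rows and features (measured
fluxes) in columns; internally the flux algebra uses the transposed
fluxes-by-experiments layout.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .baseline_pca import pca_variance_curve
from .bnb import PEMAResult, branch_and_bound_fit
from .core import greedy_fit, mode_gains
from .io_model import EMSet, FluxData, PEMAConfig
from .preprocess import build_problem

__all__ = ["PEMA", "FluxPCA"]


class PEMA(TransformerMixin, BaseEstimator):
    """Principal elementary mode analysis as a transformer.

    Selects, per factor count up to ``n_fac``, the combination of
    candidate modes whose sequential nonnegative decomposition explains
    the most variance of the measured fluxes, via greedy initialization
    and branch-and-bound refinement (``method="greedy"`` skips the
    refinement).

    Parameters
    ----------
    ems : EMSet
        Candidate mode matrix (the fixed dictionary).
    n_fac : int
        Number of factors (modes to combine).
    method : {"bnb", "greedy"}
    flux_ids : sequence of str, optional
        Names of the measured fluxes, i.e. of the columns of ``X``.
        Defaults to ``ems.reaction_ids`` (all reactions measured).
    scaling_mode, direction_filter_mode, ambiguity_tol, direction_tol,
    tie_tol, prune_tol, max_evals, seed :
        Forwarded to :class:`~pema.io_model.PEMAConfig`.

    Attributes
    ----------
    result_ : PEMAResult
        Per-factor selections, explained variance and weights
        (``method="bnb"`` only).
    selected_ids_ : tuple of str
        Modes selected at ``n_fac`` factors.
    theta_curve_ : ndarray
        Cumulative explained-variance fractions per factor count.
    components_ : ndarray of shape (k, n_measured_fluxes)
        Unit-norm measured restrictions of the selected modes.
    problem_ : ScaledProblem
        The preprocessed problem (scaling factors, ambiguity groups,
        removal lists).

    Examples
    --------
    >>> from pema.synthetic import toy_fixtures
    >>> _, ems, flux, truth = toy_fixtures("greedy_trap")
    >>> est = PEMA(ems=ems, n_fac=2).fit(flux.values.T, flux_ids=flux.flux_ids)
    >>> sorted(est.selected_ids_)
    ['a', 'b']
    """

    def __init__(
        self,
        ems: EMSet = None,
        n_fac: int = 1,
        method: str = "bnb",
        flux_ids=None,
        scaling_mode: str = "abs_mean",
        direction_filter_mode: str = "global",
        ambiguity_tol: float = 1e-9,
        direction_tol: float = 1e-9,
        tie_tol: float = 1e-12,
        prune_tol: float = 1e-12,
        max_evals: int | None = None,
        seed: int = 0,
    ):
        self.ems = ems
        self.n_fac = n_fac
        self.method = method
        self.flux_ids = flux_ids
        self.scaling_mode = scaling_mode
        self.direction_filter_mode = direction_filter_mode
        self.ambiguity_tol = ambiguity_tol
        self.direction_tol = direction_tol
        self.tie_tol = tie_tol
        self.prune_tol = prune_tol
        self.max_evals = max_evals
        self.seed = seed

    def _config(self) -> PEMAConfig:
        return PEMAConfig(
            n_fac=self.n_fac,
            tie_tol=self.tie_tol,
            ambiguity_tol=self.ambiguity_tol,
            direction_tol=self.direction_tol,
            prune_tol=self.prune_tol,
            direction_filter_mode=self.direction_filter_mode,
            scaling_mode=self.scaling_mode,
            seed=self.seed,
            max_evals=self.max_evals,
        )

    def _as_flux_data(self, X, flux_ids) -> FluxData:
        X = check_array(X, dtype=float)
        ids = tuple(flux_ids) if flux_ids is not None else (
            tuple(self.flux_ids) if self.flux_ids is not None else self.ems.reaction_ids
        )
        if len(ids) != X.shape[1]:
            raise ValueError(f"X has {X.shape[1]} feature columns but {len(ids)} flux ids")
        return FluxData(X.T, ids, tuple(f"sample{i}" for i in range(X.shape[0])))

    def fit(self, X, y=None, flux_ids=None):
        """Fit the selection on ``X`` (experiments x measured fluxes)."""
        if self.ems is None:
            raise ValueError("PEMA requires a candidate EMSet (ems=...)")
        if self.method not in ("bnb", "greedy"):
            raise ValueError("method must be 'bnb' or 'greedy'")
        flux = self._as_flux_data(X, flux_ids)
        config = self._config()
        self.problem_ = build_problem(flux, self.ems, config)
        if self.method == "bnb":
            self.result_: PEMAResult = branch_and_bound_fit(self.problem_, config)
            final = self.result_.factors[-1]
            self.selected_ids_ = final.selected_ids
            self.theta_curve_ = np.array(self.result_.theta_curve)
            self.weights_ = final.weights_norm.T
        else:
            trace = greedy_fit(self.problem_, config.n_fac, config.tie_tol)
            self.greedy_trace_ = trace
            self.selected_ids_ = trace.selected_ids
            self.theta_curve_ = np.array(trace.theta_curve)
            self.weights_ = trace.weights_norm.T
        cols = [self.problem_.mode_index(m) for m in self.selected_ids_]
        self.components_ = self.problem_.E_norm[:, cols].T
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else len(X[0])
        return self

    def transform(self, X, flux_ids=None):
        """Nonnegative weights of the selected modes for new experiments.

        Applies the fitted scaling, then the same sequential
        project-clip-deflate pass restricted to the selected modes, in
        their fitted order.  Returns an array of shape
        ``(n_samples, k)``.
        """
        check_is_fitted(self, "selected_ids_")
        flux = self._as_flux_data(X, flux_ids)
        prob = self.problem_
        if tuple(flux.flux_ids) != tuple(prob.flux_ids):
            # align and scale new data exactly as the training data
            rows = [flux.flux_ids.index(f) for f in prob.flux_ids]
            V = flux.values[rows, :]
        else:
            V = flux.values
        factors = np.array([prob.scale_factors[f] for f in prob.flux_ids])[:, None]
        V = V / factors
        W = np.zeros((len(self.selected_ids_), V.shape[1]))
        for row, mid in enumerate(self.selected_ids_):
            e = prob.E_norm[:, prob.mode_index(mid)]
            p = np.maximum(e @ V, 0.0)
            V = V - np.outer(e, p)
            W[row] = p
        return W.T

    def score(self, X, y=None, flux_ids=None):
        """Explained-variance fraction of ``X`` under the fitted selection."""
        check_is_fitted(self, "selected_ids_")
        flux = self._as_flux_data(X, flux_ids)
        factors = np.array([self.problem_.scale_factors[f] for f in self.problem_.flux_ids])[:, None]
        rows = [flux.flux_ids.index(f) for f in self.problem_.flux_ids]
        V = flux.values[rows, :] / factors
        W = self.transform(X, flux_ids=flux_ids).T
        return float(np.sum(W * W) / np.sum(V * V))


class FluxPCA(TransformerMixin, BaseEstimator):
    """Uncentered-by-default PCA baseline with an explained-variance curve.

    Thin wrapper over the singular value decomposition producing a curve
    directly comparable to :class:`PEMA`'s: cumulative top-``k`` squared
    singular values over the uncentered total sum of squares.
    """

    def __init__(self, n_components: int | None = None, centered: bool = False):
        self.n_components = n_components
        self.centered = centered

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        res = pca_variance_curve(X.T, self.n_components, self.centered)
        self.pca_result_ = res
        self.variance_curve_ = np.array(res.variance_curve)
        self.components_ = res.loadings.T   # n_lv x fluxes
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "pca_result_")
        X = check_array(X, dtype=float)
        Xc = X.T - self.pca_result_.row_means
        return (self.pca_result_.loadings.T @ Xc).T
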