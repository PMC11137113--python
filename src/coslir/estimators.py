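"""Scikit-learn style estimators for two-stage interaction inference.

``COSLIR`` fits the sparse transition matrix from the cells of two
consecutive stages (or directly from precomputed moments);
``BootstrapCOSLIR`` wraps it with cell-resampling and sign-confidence
edge filtering.  Both follow the scikit-learn contract: parameters in
``__init__``, ``fit(X, y)`` with cells in rows, fitted attributes with a
trailing underscore, and compatibility with ``clone``/``get_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .bootstrap import bootstrap_grn
from .moments import MomentSummary, StageSample, estimate_moments
from .selection import apply_clipping
from .solver import SolverConfig, admm_fit

__all__ = ["COSLIR", "BootstrapCOSLIR"]


def _split_stages(X, y, stages):
    X = check_array(X, dtype=float)
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have inconsistent lengths")
    labels = np.unique(y) if stages is None else np.asarray(stages)
    if labels.size != 2:
        raise ValueError(
            f"need exactly two stage labels, got {labels.tolist()}"
        )
    masks = [y == lab for lab in labels]
    for lab, m in zip(labels, masks):
        if m.sum() < 2:
            raise ValueError(f"stage {lab!r} has fewer than 2 cells")
    return X, labels, masks


class COSLIR(BaseEstimator):
    """Sparse interaction-matrix estimator from two-stage expression data.

    Infers a signed, weighted, directed gene-gene interaction matrix
    ``A`` (rows = targets, columns = regulators) such that the first two
    moments of the later stage match those of the earlier stage pushed
    through ``A + I``.

    Parameters
    ----------
    lam : float
        l1 penalty weight.
    eta : float
        Weight of the mean-matching term.
    alpha : float
        Identity-blend weight for the covariance correction.
    clip : float or None
        Clipping threshold applied to the fitted matrix; ``None`` or 0
        disables clipping.
    stages : tuple of length 2 or None
        Stage labels in temporal order.  ``None`` uses the sorted unique
        labels of ``y``.
    ddof : int
        Covariance divisor offset (1 = unbiased ``n-1``).
    log_transform : bool
        Apply ``log(x+1)`` before moment estimation.
    Remaining parameters are forwarded to the ADMM solver; see
    :class:`~coslir.solver.SolverConfig`.

    Attributes
    ----------
    interaction_matrix_ : ndarray of shape (p, p)
        Fitted (clipped) interaction matrix.
    converged_ : bool
    n_iter_ : int
    objective_ : float
    e_sigma_, e_mu_, s0_ : float
        Model-selection indices of the unclipped estimate.

    Examples
    --------
    >>> from coslir import COSLIR
    >>> from coslir.simulate import generate_truth, sample_cells
    >>> truth = generate_truth(p=10, sparsity=0.1, seed=0)
    >>> s_t, s_t1 = sample_cells(truth, 2000, 2000, seed=1)
    >>> import numpy as np
    >>> X = np.hstack([s_t.values, s_t1.values]).T
    >>> y = np.array(["t"] * 2000 + ["t1"] * 2000)
    >>> model = COSLIR(stages=("t", "t1")).fit(X, y)
    >>> model.interaction_matrix_.shape
    (10, 10)
    """

    def __init__(self, lam=1e-6, eta=5.0, rho=None, alpha=0.01, clip=0.01,
                 stages=None, max_iter=5000, tol_primal=1e-6,
                 tol_change=1e-8, adapt_rho=True, init="continuation",
                 refine=True, ddof=1, log_transform=False):
        self.lam = lam
        self.eta = eta
        self.rho = rho
        self.alpha = alpha
        self.clip = clip
        self.stages = stages
        self.max_iter = max_iter
        self.tol_primal = tol_primal
        self.tol_change = tol_change
        self.adapt_rho = adapt_rho
        self.init = init
        self.refine = refine
        self.ddof = ddof
        self.log_transform = log_transform

    def _solver_config(self) -> SolverConfig:
        return SolverConfig(
            lam=self.lam, eta=self.eta, rho=self.rho,
            max_iter=self.max_iter, tol_primal=self.tol_primal,
            tol_change=self.tol_change, adapt_rho=self.adapt_rho,
            init=self.init, refine=self.refine,
        )

    def fit(self, X, y):
        """Fit from stacked cells.

        Parameters
        ----------
        X : array-like of shape (n_cells_total, p)
            Expression of all cells of both stages, cells in rows.
        y : array-like of shape (n_cells_total,)
            Stage label of each cell; exactly two distinct labels.
        """
        X, labels, masks = _split_stages(X, y, self.stages)
        names = [f"g{i}" for i in range(X.shape[1])]
        moments = []
        for lab, m in zip(labels, masks):
            sample = StageSample(values=X[m].T, gene_names=names,
                                 stage_label=str(lab))
            moments.append(estimate_moments(
                sample, alpha=self.alpha, ddof=self.ddof,
                log_transform=self.log_transform))
        self.stages_ = tuple(labels.tolist())
        return self.fit_moments(*moments)

    def fit_moments(self, m_t: MomentSummary, m_t1: MomentSummary):
        """Fit directly from two stages' (possibly exact) moments."""
        est = admm_fit(m_t, m_t1, self._solver_config())
        self.n_features_in_ = m_t.n_genes
        self.interaction_matrix_raw_ = est.A
        clip = self.clip or 0.0
        self.interaction_matrix_ = apply_clipping(est.A, clip)
        self.converged_ = est.converged
        self.n_iter_ = est.n_iter
        self.objective_ = est.objective
        self.e_sigma_ = est.e_sigma
        self.e_mu_ = est.e_mu
        self.s0_ = est.s0
        self.diagnostics_ = est.diagnostics
        self.mean_t_ = m_t.mean
        self.mean_t1_ = m_t1.mean
        return self

    def transform(self, X):
        """Propagate expression profiles one stage forward: ``X (A+I)^T``."""
        check_is_fitted(self, "interaction_matrix_")
        X = check_array(X, dtype=float)
        G = self.interaction_matrix_ + np.eye(self.n_features_in_)
        return X @ G.T


class BootstrapCOSLIR(BaseEstimator):
    """COSLIR with cell bootstrapping and sign-confidence filtering.

    Refits the solver on ``n_resamples`` with-replacement resamples of
    the cells at each stage and keeps an edge only when more than
    ``confidence_threshold`` of the replicates agree on its sign.

    Attributes
    ----------
    interaction_matrix_ : ndarray
        Confidence-filtered final estimator.
    confidence_ : ndarray
        Per-entry sign confidence in [0, 1].
    """

    def __init__(self, lam=1e-6, eta=5.0, alpha=0.01, clip=0.01,
                 stages=None, n_resamples=50, confidence_threshold=0.9,
                 random_state=0, max_iter=5000, init="continuation",
                 clip_mode="per_replicate", mean_mode="majority_sign",
                 ddof=1, log_transform=False):
        self.lam = lam
        self.eta = eta
        self.alpha = alpha
        self.clip = clip
        self.stages = stages
        self.n_resamples = n_resamples
        self.confidence_threshold = confidence_threshold
        self.random_state = random_state
        self.max_iter = max_iter
        self.init = init
        self.clip_mode = clip_mode
        self.mean_mode = mean_mode
        self.ddof = ddof
        self.log_transform = log_transform

    def fit(self, X, y):
        X, labels, masks = _split_stages(X, y, self.stages)
        names = [f"g{i}" for i in range(X.shape[1])]
        samples = []
        for lab, m in zip(labels, masks):
            vals = X[m].T
            if self.log_transform:
                vals = np.log1p(vals)
            samples.append(StageSample(values=vals, gene_names=names,
                                       stage_label=str(lab)))
        cfg = SolverConfig(lam=self.lam, eta=self.eta,
                           max_iter=self.max_iter, init=self.init)
        result = bootstrap_grn(
            samples[0], samples[1], cfg,
            epsilon=self.clip or 0.0,
            n_reps=self.n_resamples,
            conf_threshold=self.confidence_threshold,
            base_seed=self.random_state,
            alpha=self.alpha, ddof=self.ddof,
            clip_mode=self.clip_mode, mean_mode=self.mean_mode,
        )
        self.n_features_in_ = X.shape[1]
        self.stages_ = tuple(labels.tolist())
        self.interaction_matrix_ = result.final
        self.confidence_ = result.confidence
        self.bootstrap_result_ = result
        return self
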