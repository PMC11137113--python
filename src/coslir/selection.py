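"""Model-selection indices, clipping, and hyperparameter choice.

Because the two stages are never observed in the same cell, there is no
held-out likelihood to cross-validate against.  Model selection instead
relies on three indices of a candidate matrix ``A``:

* ``e_sigma`` — residual covariance mismatch, relative to the raw
  between-stage covariance difference;
* ``e_mu`` — residual mean mismatch, relative to the raw mean difference;
* ``s0`` — fraction of nonzero entries.

A good model is the sparsest one whose two error indices stay below a
user-set ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .moments import MomentSummary
from .solver import SolverConfig, _Problem, admm_fit

__all__ = [
    "SelectionIndices",
    "ClippingChoice",
    "compute_indices",
    "apply_clipping",
    "select_clipping_threshold",
    "select_hyperparameters",
]


@dataclass
class SelectionIndices:
    e_sigma: float
    e_mu: float
    s0: float


@dataclass
class ClippingChoice:
    epsilon: float
    indices_at_epsilon: SelectionIndices
    score: float
    ceiling_met: bool = True
    table: pd.DataFrame | None = field(default=None, repr=False)


def compute_indices(A, m_t: MomentSummary, m_t1: MomentSummary) -> SelectionIndices:
    """Covariance error, mean error and sparsity of a candidate ``A``."""
    prob = _Problem(m_t, m_t1, eta=0.0)
    A = np.asarray(A, dtype=float)
    if A.shape != (prob.p, prob.p):
        raise ValueError("A has the wrong shape")
    G = A + prob.I
    e_sigma = float(np.linalg.norm(prob.S2 - G @ prob.S1 @ G.T)
                    / np.sqrt(prob.dS))
    e_mu = float(np.linalg.norm(prob.mu2 - G @ prob.mu1) / np.sqrt(prob.dm))
    s0 = float(np.count_nonzero(A) / A.size)
    return SelectionIndices(e_sigma=e_sigma, e_mu=e_mu, s0=s0)


def apply_clipping(A, epsilon: float) -> np.ndarray:
    """Zero entries with magnitude strictly below ``epsilon``.

    Entries exactly equal to ``epsilon`` survive.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    A = np.asarray(A, dtype=float)
    return np.where(np.abs(A) < epsilon, 0.0, A)


def select_clipping_threshold(
    A,
    m_t: MomentSummary,
    m_t1: MomentSummary,
    eta: float = 5.0,
    eps_grid=None,
    score_ceiling: float = 0.5,
) -> ClippingChoice:
    """Choose the clipping threshold on the full-sample estimate.

    Scores each grid point by ``(e_sigma + eta * e_mu) / (1 + eta)`` (so a
    ceiling of 1 corresponds to the zero-matrix score) and returns the
    sparsest clipped matrix whose score stays at or below
    ``score_ceiling``; ties go to the largest threshold.  If no grid point
    qualifies, the minimal-score point is returned with
    ``ceiling_met=False``.
    """
    A = np.asarray(A, dtype=float)
    if eps_grid is None:
        eps_grid = np.concatenate([[0.0], np.geomspace(1e-4, 1.0, 17)])
    eps_grid = np.asarray(list(eps_grid), dtype=float)
    if eps_grid.size == 0:
        raise ValueError("eps_grid must be non-empty")
    rows = []
    for eps in eps_grid:
        idx = compute_indices(apply_clipping(A, eps), m_t, m_t1)
        score = (idx.e_sigma + eta * idx.e_mu) / (1.0 + eta)
        rows.append((float(eps), idx, score))
    table = pd.DataFrame(
        [(e, i.e_sigma, i.e_mu, i.s0, s) for e, i, s in rows],
        columns=["epsilon", "e_sigma", "e_mu", "s0", "score"],
    )
    ok = [r for r in rows if r[2] <= score_ceiling]
    if ok:
        # sparsest; ties -> largest epsilon
        best = min(ok, key=lambda r: (r[1].s0, -r[0]))
        return ClippingChoice(epsilon=best[0], indices_at_epsilon=best[1],
                              score=best[2], ceiling_met=True, table=table)
    best = min(rows, key=lambda r: (r[2], -r[0]))
    return ClippingChoice(epsilon=best[0], indices_at_epsilon=best[1],
                          score=best[2], ceiling_met=False, table=table)


def select_hyperparameters(
    m_t: MomentSummary,
    m_t1: MomentSummary,
    lam_grid=(1e-6,),
    eta_grid=(5.0,),
    score_ceiling: float = 0.3,
    cfg: SolverConfig | None = None,
):
    """Grid-select ``(lam, eta)`` on the full-sample moments.

    Fits the solver at every grid point, then returns the pair with the
    sparsest estimate among those whose ``e_sigma`` and ``e_mu`` are both
    at or below ``score_ceiling``; ties prefer larger ``lam`` (sparser
    penalty), then larger ``eta``.  Solver failures are recorded in the
    returned table rather than raised.

    Returns ``(lam, eta, table)`` with one table row per grid point.
    """
    lam_grid = list(lam_grid)
    eta_grid = list(eta_grid)
    if not lam_grid or not eta_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    base = cfg or SolverConfig()
    rows = []
    for lam in lam_grid:
        for eta in eta_grid:
            from dataclasses import replace
            c = replace(base, lam=float(lam), eta=float(eta))
            try:
                est = admm_fit(m_t, m_t1, c)
                rows.append({
                    "lam": float(lam), "eta": float(eta),
                    "e_sigma": est.e_sigma, "e_mu": est.e_mu, "s0": est.s0,
                    "converged": est.converged, "error": "",
                })
            except Exception as err:  # noqa: BLE001 - recorded per grid point
                rows.append({
                    "lam": float(lam), "eta": float(eta),
                    "e_sigma": np.nan, "e_mu": np.nan, "s0": np.nan,
                    "converged": False, "error": str(err),
                })
    table = pd.DataFrame(rows)
    ok = table[(table["error"] == "")
               & (table["e_sigma"] <= score_ceiling)
               & (table["e_mu"] <= score_ceiling)]
    if len(ok):
        best = ok.sort_values(["s0", "lam", "eta"],
                              ascending=[True, False, False]).iloc[0]
    else:
        valid = table[table["error"] == ""]
        if not len(valid):
            raise RuntimeError("all hyperparameter fits failed")
        score = valid["e_sigma"] + valid["e_mu"]
        best = valid.loc[score.idxmin()]
    return float(best["lam"]), float(best["eta"]), table
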