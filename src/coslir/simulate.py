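"""Synthetic ground truth and unlinked two-stage samples.

The generator draws a sparse interaction matrix ``A`` (a configurable
fraction of entries nonzero, values standard normal), a stage-t mean with
entries N(0, 100) and a positive-definite stage-t covariance
``Sigma_t = P Lambda P^T`` with ``Lambda_ii = exp(i/p)`` and ``P = I + R``,
``R`` standard normal.  Stage-(t+1) moments follow the linear transition

    mu_{t+1}    = (A + I) mu_t + l,
    Sigma_{t+1} = (A + I) Sigma_t (A + I)^T + D,

with a constant noise mean ``l = 0.1`` per gene and diagonal noise
covariance ``D = 0.01 I``.  Cells at the two stages are sampled from the
two multivariate normals with *independent* random streams, so there is no
cell-level linkage between stages — the defining feature of time-stamped
cross-sectional data.

The generator emulates the moment structure of a linear transition, not
realistic scRNA-seq counts: there is no dropout, no library-size
variation, and values may be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .moments import MomentSummary, StageSample

__all__ = ["SimulationTruth", "generate_truth", "propagate_moments", "sample_cells"]

#: noise mean per gene (constant environmental drift)
DEFAULT_NOISE_MEAN = 0.1
#: diagonal of the noise covariance
DEFAULT_NOISE_VAR = 0.01


@dataclass
class SimulationTruth:
    """Ground-truth transition and the implied two-stage moments."""

    A_true: np.ndarray
    mu_t: np.ndarray
    Sigma_t: np.ndarray
    noise_mean: np.ndarray
    noise_cov: np.ndarray
    mu_t1: np.ndarray
    Sigma_t1: np.ndarray
    seed: int
    gene_names: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.A_true.shape[0]

    def moment_summaries(self) -> tuple[MomentSummary, MomentSummary]:
        """Exact stage moments, for oracle-case inference."""
        return (
            MomentSummary.from_exact(self.mu_t, self.Sigma_t, "t"),
            MomentSummary.from_exact(self.mu_t1, self.Sigma_t1, "t+1"),
        )


def propagate_moments(A, mu_t, Sigma_t, noise_mean, noise_cov):
    """Map stage-t moments through the linear transition.

    Returns ``(mu_t1, Sigma_t1)``; the covariance is symmetrised to kill
    round-off asymmetry.
    """
    A = np.asarray(A, dtype=float)
    mu_t = np.asarray(mu_t, dtype=float).ravel()
    Sigma_t = np.asarray(Sigma_t, dtype=float)
    p = mu_t.size
    if A.shape != (p, p) or Sigma_t.shape != (p, p):
        raise ValueError("shapes of A, mu_t, Sigma_t are not conformable")
    if not np.allclose(Sigma_t, Sigma_t.T, rtol=1e-8, atol=1e-8):
        raise ValueError("Sigma_t is not symmetric")
    noise_mean = np.broadcast_to(np.asarray(noise_mean, dtype=float), (p,))
    noise_cov = np.asarray(noise_cov, dtype=float)
    if noise_cov.ndim == 0:
        noise_cov = float(noise_cov) * np.eye(p)
    G = A + np.eye(p)
    mu_t1 = G @ mu_t + noise_mean
    Sigma_t1 = G @ Sigma_t @ G.T + noise_cov
    Sigma_t1 = (Sigma_t1 + Sigma_t1.T) / 2.0
    return mu_t1, Sigma_t1


def generate_truth(
    p: int,
    sparsity: float = 0.1,
    seed: int = 0,
    noise_mean: float = DEFAULT_NOISE_MEAN,
    noise_var: float = DEFAULT_NOISE_VAR,
    support_mode: str = "exact",
    max_condition: float = 1e12,
) -> SimulationTruth:
    """Draw a ground-truth transition instance.

    Parameters
    ----------
    p : int
        Number of genes (p >= 2).
    sparsity : float in (0, 1)
        Fraction of the p*p entries of ``A`` that are nonzero.  With
        ``support_mode="exact"`` (default) exactly ``round(sparsity * p**2)``
        entries are nonzero; ``"bernoulli"`` flips an independent coin per
        entry instead.
    seed : int
        Seed for all draws; the instance is a deterministic function of it.
    noise_mean, noise_var : float
        Constant noise mean per gene and diagonal noise variance.  Set both
        to 0 for a noise-free (oracle-exact) transition.
    max_condition : float
        If the drawn ``P = I + R`` has a condition number above this, ``R``
        is redrawn from an incremented sub-seed.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0.0 < sparsity < 1.0:
        raise ValueError("sparsity must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if support_mode == "exact":
        k = int(round(sparsity * p * p))
        support = rng.choice(p * p, size=k, replace=False)
        flat = np.zeros(p * p)
        flat[support] = rng.standard_normal(k)
        A = flat.reshape(p, p)
    elif support_mode == "bernoulli":
        mask = rng.random((p, p)) < sparsity
        A = np.where(mask, rng.standard_normal((p, p)), 0.0)
    else:
        raise ValueError(f"unknown support_mode {support_mode!r}")
    mu_t = rng.normal(0.0, 10.0, p)  # variance 100
    Lam = np.diag(np.exp(np.arange(1, p + 1) / p))
    for attempt in range(100):
        R = rng.standard_normal((p, p))
        P = np.eye(p) + R
        if np.linalg.cond(P) <= max_condition:
            break
        warnings.warn(
            f"P = I + R numerically singular (attempt {attempt}); redrawing R"
        )
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("could not draw a well-conditioned P")
    Sigma_t = P @ Lam @ P.T
    Sigma_t = (Sigma_t + Sigma_t.T) / 2.0
    l = np.full(p, float(noise_mean))
    D = float(noise_var) * np.eye(p)
    mu_t1, Sigma_t1 = propagate_moments(A, mu_t, Sigma_t, l, D)
    return SimulationTruth(
        A_true=A,
        mu_t=mu_t,
        Sigma_t=Sigma_t,
        noise_mean=l,
        noise_cov=D,
        mu_t1=mu_t1,
        Sigma_t1=Sigma_t1,
        seed=seed,
        gene_names=[f"g{i}" for i in range(p)],
    )


def _draw_stage(rng, mean, cov, n, label, gene_names):
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < -1e-8 * max(1.0, abs(float(np.trace(cov)))):
        raise ValueError(
            f"covariance of stage {label!r} is not positive-semidefinite "
            f"(smallest eigenvalue {eigmin:.3e})"
        )
    try:
        cells = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    except np.linalg.LinAlgError:
        cells = rng.multivariate_normal(mean, cov, size=n, method="eigh")
    return StageSample(values=cells.T, gene_names=gene_names, stage_label=label)


def sample_cells(
    truth: SimulationTruth,
    n_t: int = 5000,
    n_t1: int = 5000,
    seed: int = 0,
) -> tuple[StageSample, StageSample]:
    """Draw unlinked cell samples for the two stages.

    The two stages use independent child streams spawned from ``seed``,
    so there is no correspondence between cell ``i`` at stage t and cell
    ``i`` at stage t+1.
    """
    if n_t < 2 or n_t1 < 2:
        raise ValueError("need at least 2 cells per stage")
    ss = np.random.SeedSequence(seed)
    child_t, child_t1 = ss.spawn(2)
    names = truth.gene_names or [f"g{i}" for i in range(truth.p)]
    s_t = _draw_stage(np.random.default_rng(child_t), truth.mu_t,
                      truth.Sigma_t, n_t, "t", names)
    s_t1 = _draw_stage(np.random.default_rng(child_t1), truth.mu_t1,
                       truth.Sigma_t1, n_t1, "t+1", names)
    return s_t, s_t1
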