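"""First- and second-moment estimation for a single cell stage.

The inference downstream never sees individual cells: everything it needs
from a stage is the per-gene mean vector and the gene-gene covariance
matrix.  Because the raw sample covariance of single-cell expression data
can be rank-deficient (more genes than cells, collinear genes), the
covariance handed to the solver is a convex blend with the identity,

    Sigma_tilde = (1 - alpha) * Sigma_hat + alpha * I,

which is positive-definite for any alpha in (0, 1] whenever Sigma_hat is
positive-semidefinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StageSample", "MomentSummary", "estimate_moments"]


@dataclass
class StageSample:
    """Expression matrix for one developmental stage.

    Parameters
    ----------
    values : ndarray of shape (p, n_cells)
        Expression values, genes in rows and cells in columns.
    gene_names : list of str
        Unique identifiers for the ``p`` genes.
    stage_label : str
        Name of the stage (e.g. a time point such as ``"12h"``).
    """

    values: np.ndarray
    gene_names: list[str]
    stage_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells matrix")
        self.gene_names = list(self.gene_names)
        if len(self.gene_names) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_names)} gene names for "
                f"{self.values.shape[0]} rows"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            dupes = sorted(
                {g for g in self.gene_names if self.gene_names.count(g) > 1}
            )
            raise ValueError(f"duplicate gene names: {dupes}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite expression value for gene {self.gene_names[i]!r} "
                f"(row {i}), cell column {j}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class MomentSummary:
    """Mean vector and (corrected) covariance matrix of one stage.

    ``covariance`` is the identity-blended matrix actually used by the
    solver; ``covariance_raw`` is the plain sample covariance.  ``alpha=0``
    is allowed here so that exact (oracle) moments can be represented.
    """

    mean: np.ndarray
    covariance_raw: np.ndarray
    covariance: np.ndarray
    alpha: float
    n_cells: int = 0
    stage_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance_raw = np.asarray(self.covariance_raw, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        p = self.mean.size
        if self.covariance.shape != (p, p) or self.covariance_raw.shape != (p, p):
            raise ValueError("covariance shape inconsistent with mean length")
        if not np.allclose(self.covariance_raw, self.covariance_raw.T,
                           rtol=1e-8, atol=1e-8):
            raise ValueError("covariance_raw is not symmetric")

    @property
    def n_genes(self) -> int:
        return self.mean.size

    @classmethod
    def from_exact(cls, mean, covariance, stage_label: str = "") -> "MomentSummary":
        """Wrap exact (population) moments, bypassing the identity blend."""
        covariance = np.asarray(covariance, dtype=float)
        return cls(
            mean=mean,
            covariance_raw=covariance,
            covariance=covariance.copy(),
            alpha=0.0,
            n_cells=0,
            stage_label=stage_label,
            metadata={"exact": True},
        )


def estimate_moments(
    sample: StageSample,
    alpha: float = 0.01,
    ddof: int = 1,
    log_transform: bool = False,
) -> MomentSummary:
    """Estimate the mean and identity-blended covariance of a stage.

    Parameters
    ----------
    sample : StageSample
        Genes x cells expression matrix for one stage.
    alpha : float in (0, 1]
        Weight of the identity in the covariance blend.  The default 0.01
        perturbs the sample covariance just enough to guarantee positive
        definiteness.
    ddof : int
        Delta degrees of freedom of the sample covariance; 1 (default)
        gives the unbiased n-1 divisor, 0 the population divisor.
    log_transform : bool
        If True, apply ``log(x + 1)`` (natural log) to the expression
        values before estimating moments.

    Returns
    -------
    MomentSummary
    """
    if sample.n_cells < 2:
        raise ValueError(
            f"insufficient cells: need at least 2, got {sample.n_cells}"
        )
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    values = sample.values
    if log_transform:
        if (values < 0).any():
            raise ValueError("log transform requires non-negative expression")
        values = np.log1p(values)
    mean = values.mean(axis=1)
    cov_raw = np.cov(values, ddof=ddof)
    cov_raw = np.atleast_2d(cov_raw)
    cov = (1.0 - alpha) * cov_raw + alpha * np.eye(sample.n_genes)
    return MomentSummary(
        mean=mean,
        covariance_raw=cov_raw,
        covariance=cov,
        alpha=alpha,
        n_cells=sample.n_cells,
        stage_label=sample.stage_label,
        metadata={"ddof": ddof, "log_transform": log_transform},
    )
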