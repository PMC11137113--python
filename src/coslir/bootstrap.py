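"""Bootstrap over cells with sign-confidence edge filtering.

The solver's estimate from one finite sample is noisy.  Resampling cells
with replacement at each stage independently and refitting gives an
ensemble of estimates; an edge is kept only when a clear majority of
replicates agree it is nonzero *with the same sign*.  The confidence of
entry (i, j) is the larger of the two sign fractions, and the final
estimator averages the entry over the replicates that carry the majority
sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .moments import StageSample, estimate_moments
from .selection import apply_clipping
from .solver import SolverConfig, admm_fit

__all__ = ["BootstrapResult", "resample_stage", "bootstrap_grn",
           "aggregate_replicates"]


@dataclass
class BootstrapResult:
    """Replicate ensemble and the confidence-filtered final estimator."""

    replicates: np.ndarray            # (n_reps, p, p), clipped per replicate
    confidence: np.ndarray            # (p, p) in [0, 1]
    final: np.ndarray                 # (p, p)
    conf_threshold: float
    n_replicates: int
    base_seed: int
    n_dropped: int = 0
    gene_names: list = field(default_factory=list)

    def filtered(self, conf_threshold: float) -> np.ndarray:
        """Final estimator at a different confidence threshold.

        Reuses the stored replicates; raising the threshold can only
        remove edges, never change a surviving entry's value.
        """
        final, _ = aggregate_replicates(self.replicates, conf_threshold)
        return final


def resample_stage(sample: StageSample, seed) -> StageSample:
    """Resample the cells of one stage with replacement.

    Deterministic given ``seed`` (an int or a Generator).
    """
    if sample.n_cells < 2:
        raise ValueError(
            f"insufficient cells: need at least 2, got {sample.n_cells}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, sample.n_cells, size=sample.n_cells)
    return StageSample(
        values=sample.values[:, idx],
        gene_names=sample.gene_names,
        stage_label=sample.stage_label,
    )


def aggregate_replicates(replicates: np.ndarray, conf_threshold: float,
                         mean_mode: str = "majority_sign"):
    """Sign-confidence filter an ensemble of (clipped) estimates.

    Returns ``(final, confidence)``.  ``confidence[i, j]`` is the larger
    of the fractions of replicates in which the entry is positive or
    negative; ``final[i, j]`` is nonzero only when that fraction strictly
    exceeds ``conf_threshold`` and is then the mean over the
    majority-sign replicates (``mean_mode="majority_sign"``) or over all
    replicates (``mean_mode="all"``).
    """
    if not 0.5 < conf_threshold <= 1.0:
        raise ValueError("conf_threshold must be in (0.5, 1]")
    reps = np.asarray(replicates, dtype=float)
    n = reps.shape[0]
    pos = (reps > 0).sum(axis=0) / n
    neg = (reps < 0).sum(axis=0) / n
    confidence = np.maximum(pos, neg)
    majority = np.where(pos >= neg, 1.0, -1.0)
    keep = confidence > conf_threshold
    if mean_mode == "majority_sign":
        match = np.sign(reps) == majority[None, :, :]
        cnt = match.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(cnt > 0, (reps * match).sum(axis=0)
                            / np.maximum(cnt, 1), 0.0)
    elif mean_mode == "all":
        mean = reps.mean(axis=0)
    else:
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    final = np.where(keep, mean, 0.0)
    return final, confidence


def bootstrap_grn(
    sample_t: StageSample,
    sample_t1: StageSample,
    cfg: SolverConfig | None = None,
    epsilon: float = 0.01,
    n_reps: int = 50,
    conf_threshold: float = 0.9,
    base_seed: int = 0,
    alpha: float = 0.01,
    ddof: int = 1,
    clip_mode: str = "per_replicate",
    mean_mode: str = "majority_sign",
    max_drop_fraction: float = 0.2,
) -> BootstrapResult:
    """Bootstrap the two-stage fit and keep sign-stable edges.

    ``epsilon`` (the clipping threshold) and the solver hyperparameters
    are meant to be fixed beforehand on the full sample.  Replicate ``r``
    resamples both stages with seed ``base_seed + r``, so the run is
    reproducible and replicates are independent of their order.

    ``clip_mode="per_replicate"`` (default) clips each replicate before
    sign counting; ``"final"`` counts signs on raw replicates and clips
    only the aggregated estimate.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not 0.5 < conf_threshold <= 1.0:
        raise ValueError("conf_threshold must be in (0.5, 1]")
    if clip_mode not in ("per_replicate", "final"):
        raise ValueError(f"unknown clip_mode {clip_mode!r}")
    cfg = cfg or SolverConfig()
    p = sample_t.n_genes
    if sample_t1.n_genes != p:
        raise ValueError("stages have different numbers of genes")
    reps = []
    dropped = 0
    for r in range(n_reps):
        seed = base_seed + r
        child_t, child_t1 = np.random.SeedSequence(seed).spawn(2)
        try:
            rs_t = resample_stage(sample_t, child_t)
            rs_t1 = resample_stage(sample_t1, child_t1)
            m_t = estimate_moments(rs_t, alpha=alpha, ddof=ddof)
            m_t1 = estimate_moments(rs_t1, alpha=alpha, ddof=ddof)
            est = admm_fit(m_t, m_t1, cfg)
        except (ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"bootstrap replicate {r} failed and was dropped: {err}")
            dropped += 1
            continue
        A = est.A
        if clip_mode == "per_replicate":
            A = apply_clipping(A, epsilon)
        reps.append(A)
    if dropped > max_drop_fraction * n_reps:
        raise RuntimeError(
            f"{dropped}/{n_reps} bootstrap replicates failed "
            f"(more than {max_drop_fraction:.0%})"
        )
    replicates = np.stack(reps)
    final, confidence = aggregate_replicates(replicates, conf_threshold,
                                             mean_mode=mean_mode)
    if clip_mode == "final":
        final = apply_clipping(final, epsilon)
    return BootstrapResult(
        replicates=replicates,
        confidence=confidence,
        final=final,
        conf_threshold=conf_threshold,
        n_replicates=len(reps),
        base_seed=base_seed,
        n_dropped=dropped,
        gene_names=list(sample_t.gene_names),
    )
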