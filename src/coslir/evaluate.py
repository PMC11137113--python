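"""Sign-aware precision/recall, early precision and rescaled edge ranking."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvalReport",
    "RescaledMatrix",
    "precision_recall",
    "early_precision",
    "early_precision_curve",
    "rank_edges",
    "rescale_matrix",
]


@dataclass
class EvalReport:
    """Edge-recovery counts and the derived precision/recall.

    ``precision`` is NaN (undefined) when nothing was predicted — never
    silently 0 or 1.
    """

    n_predicted: int
    n_true: int
    n_correct: int
    early_precision: dict = field(default_factory=dict)

    @property
    def precision(self) -> float:
        if self.n_predicted == 0:
            return float("nan")
        return self.n_correct / self.n_predicted

    @property
    def recall(self) -> float:
        if self.n_true == 0:
            return float("nan")
        return self.n_correct / self.n_true


def precision_recall(A_hat: np.ndarray, A_true: np.ndarray) -> EvalReport:
    """Sign-aware edge recovery of ``A_hat`` against ``A_true``.

    An entry counts as correctly recovered when it is nonzero in both
    matrices with the same sign.
    """
    A_hat = np.asarray(A_hat, dtype=float)
    A_true = np.asarray(A_true, dtype=float)
    if A_hat.shape != A_true.shape:
        raise ValueError(f"shape mismatch: {A_hat.shape} vs {A_true.shape}")
    pred = A_hat != 0
    true = A_true != 0
    correct = pred & true & (np.sign(A_hat) == np.sign(A_true))
    return EvalReport(
        n_predicted=int(pred.sum()),
        n_true=int(true.sum()),
        n_correct=int(correct.sum()),
    )


def rank_edges(A: np.ndarray, gene_names=None):
    """Rank nonzero entries of ``A`` by decreasing magnitude.

    Ties are broken by regulator (column) index, then target (row) index,
    so the ranking is a deterministic function of the matrix.  Returns a
    list of ``(regulator, target, value)`` where regulator/target are gene
    names if given, else integer indices.
    """
    A = np.asarray(A, dtype=float)
    rows, cols = np.nonzero(A)
    vals = A[rows, cols]
    order = sorted(range(len(vals)),
                   key=lambda k: (-abs(vals[k]), cols[k], rows[k]))
    if gene_names is None:
        return [(int(cols[k]), int(rows[k]), float(vals[k])) for k in order]
    return [(gene_names[cols[k]], gene_names[rows[k]], float(vals[k]))
            for k in order]


def _normalise_reference(reference_edges):
    """Accept (reg, target) or (reg, target, sign) tuples."""
    unsigned = set()
    signed = {}
    for e in reference_edges:
        if len(e) == 2:
            unsigned.add((e[0], e[1]))
        else:
            unsigned.add((e[0], e[1]))
            signed[(e[0], e[1])] = np.sign(e[2])
    return unsigned, signed


def early_precision(ranked_edges, reference_edges, k: int,
                    sign_aware: bool = False) -> float:
    """Fraction of the ``k`` highest-ranked edges present in the reference.

    ``ranked_edges`` is an ordered list of ``(regulator, target[, value])``;
    the match is on the directed (regulator, target) pair, and on the sign
    of the value only when ``sign_aware`` and the reference carries signs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    unsigned, signed = _normalise_reference(reference_edges)
    if k > len(ranked_edges):
        warnings.warn(
            f"k={k} exceeds the {len(ranked_edges)} ranked edges; "
            "evaluating at all available edges"
        )
        k = len(ranked_edges)
        if k == 0:
            return float("nan")
    hits = 0
    for e in ranked_edges[:k]:
        key = (e[0], e[1])
        if key not in unsigned:
            continue
        if sign_aware and key in signed and len(e) > 2:
            if np.sign(e[2]) != signed[key]:
                continue
        hits += 1
    return hits / k


def early_precision_curve(ranked_edges, reference_edges, ks,
                          sign_aware: bool = False) -> dict:
    return {int(k): early_precision(ranked_edges, reference_edges, int(k),
                                    sign_aware=sign_aware)
            for k in ks}


@dataclass
class RescaledMatrix:
    """Edge weights rescaled by their contribution to mean-expression change."""

    values: np.ndarray
    undefined_rows: list


def rescale_matrix(A_hat, mu_1, mu_2, tol: float = 1e-12) -> RescaledMatrix:
    """Rescale |A_hat| to reflect contribution to each target's mean shift.

    Entry (i, j) becomes ``|A_hat[i, j]| * |mu_1[j]| / |mu_1[i] - mu_2[i]|``.
    Rows whose mean change is below ``tol`` are zeroed and reported in
    ``undefined_rows``.
    """
    A_hat = np.asarray(A_hat, dtype=float)
    mu_1 = np.asarray(mu_1, dtype=float).ravel()
    mu_2 = np.asarray(mu_2, dtype=float).ravel()
    p = A_hat.shape[0]
    if A_hat.shape != (p, p) or mu_1.size != p or mu_2.size != p:
        raise ValueError("inconsistent shapes")
    dmu = np.abs(mu_1 - mu_2)
    defined = dmu >= tol
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.abs(A_hat) * np.abs(mu_1)[None, :] / dmu[:, None]
    vals[~defined, :] = 0.0
    return RescaledMatrix(values=vals,
                          undefined_rows=list(np.nonzero(~defined)[0]))
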