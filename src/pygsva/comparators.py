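"""The three competing unsupervised single-sample enrichment methods.

* PLAGE — pathway activity as the coefficients of the first
  right-singular vector of the row-standardized gene-set submatrix.
* Combined z-score — Stouffer combination of the row-standardized
  values: per sample, sum of in-set z-scores over sqrt(set size).
* ssGSEA — per-sample running-sum difference between the weighted
  in-set rank ECDF and the unweighted out-of-set ECDF, integrated over
  the ranking and normalized by the global score range.

PLAGE and the combined z-score are parametric and assume roughly normal
continuous data; when handed counts they operate on the values as-is
with a warning.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (
    COUNTS,
    EnrichmentMatrix,
    ExpressionMatrix,
    GeneSetCollection,
)
from .gsva_core import membership_matrix

logger = logging.getLogger(__name__)

__all__ = ["plage", "combined_zscore", "ssgsea"]


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row z-scores (mean 0, unit SD, ddof=1) and a constant-row mask."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    safe = np.where(sd == 0, 1.0, sd)
    return (x - mu) / safe, constant


def _warn_counts(expr: ExpressionMatrix, method: str) -> None:
    if expr.value_kind == COUNTS:
        logger.warning(
            "%s assumes continuous data; applying it to raw counts as-is", method
        )


def plage(expr: ExpressionMatrix, gsc: GeneSetCollection) -> EnrichmentMatrix:
    """Pathway Level Analysis of Gene Expression.

    Per set: standardize each member's profile across samples, take the
    SVD of the resulting |set| x n submatrix, and report the first
    right-singular vector as the activity profile (unit Euclidean norm
    across samples).  The SVD sign is fixed so that the profile
    correlates non-negatively with the per-sample mean of the
    standardized member rows.  Members with zero variance are dropped
    with a warning; a set losing all members yields an all-zero row.
    """
    if expr.n_samples < 2:
        raise ValueError("plage requires at least 2 samples")
    _warn_counts(expr, "plage")
    member = membership_matrix(gsc, expr.gene_ids, allow_full=True)
    zs, constant = _standardize_rows(expr.values)
    scores = np.zeros((len(gsc), expr.n_samples))
    for k in range(member.shape[0]):
        rows = np.flatnonzero(member[k] & ~constant)
        n_const = int(member[k].sum() - rows.size)
        if n_const:
            logger.warning(
                "plage: dropped %d constant gene(s) from set %r",
                n_const, gsc.sets[k].name,
            )
        if rows.size == 0:
            logger.warning("plage: set %r has no variable genes; scores set to 0",
                           gsc.sets[k].name)
            continue
        sub = zs[rows]
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        v = vt[0]
        if np.dot(v, sub.mean(axis=0)) < 0:
            v = -v
        scores[k] = v
    return EnrichmentMatrix(
        scores=scores,
        set_names=gsc.names,
        sample_ids=list(expr.sample_ids),
        method="plage",
        params={},
    )


def combined_zscore(expr: ExpressionMatrix, gsc: GeneSetCollection) -> EnrichmentMatrix:
    """Stouffer-combined per-sample z-scores of the set members.

    Per set and sample: ``sum_{i in set} z_ij / sqrt(|set|)`` with z the
    row-standardized expression.  Constant genes are dropped from the
    set (they carry no information); the sqrt uses the retained size.
    """
    if expr.n_samples < 2:
        raise ValueError("combined_zscore requires at least 2 samples")
    _warn_counts(expr, "combined_zscore")
    member = membership_matrix(gsc, expr.gene_ids, allow_full=True)
    zs, constant = _standardize_rows(expr.values)
    effective = member & ~constant[None, :]
    sizes = effective.sum(axis=1)
    dropped = member.sum(axis=1) - sizes
    if dropped.any():
        logger.warning("combined_zscore: dropped %d constant gene(s) across sets",
                       int(dropped.sum()))
    scores = np.zeros((len(gsc), expr.n_samples))
    nonempty = sizes > 0
    scores[nonempty] = (effective[nonempty].astype(float) @ zs) / np.sqrt(
        sizes[nonempty]
    )[:, None]
    return EnrichmentMatrix(
        scores=scores,
        set_names=gsc.names,
        sample_ids=list(expr.sample_ids),
        method="zscore",
        params={},
    )


def ssgsea(
    expr: ExpressionMatrix,
    gsc: GeneSetCollection,
    weight_exponent: float = 0.25,
    normalize: bool = True,
) -> EnrichmentMatrix:
    """Single-sample GSEA.

    Per sample, genes are ranked by expression (largest value gets rank
    p; ties broken by row order) and traversed in decreasing rank order.
    The score is the integrated difference between the in-set ECDF
    weighted by ``rank ** weight_exponent`` and the unweighted
    out-of-set ECDF — a running sum over the whole ranking, not a
    maximum deviation.  When ``normalize`` is true the final matrix is
    divided by its global range across all sets and samples.
    """
    member = membership_matrix(gsc, expr.gene_ids)
    x = expr.values
    p, n = x.shape
    asc = np.argsort(x, axis=0, kind="stable")
    ranks = np.empty((p, n), dtype=np.int64)
    np.put_along_axis(ranks, asc, np.arange(1, p + 1, dtype=np.int64)[:, None], axis=0)
    order = asc[::-1, :]
    sizes = member.sum(axis=1)
    scores = np.empty((len(gsc), n))
    for j in range(n):
        ordj = order[:, j]
        w = ranks[ordj, j].astype(float) ** weight_exponent
        M = member[:, ordj]
        cin = np.cumsum(M * w[None, :], axis=1)
        cin /= cin[:, -1][:, None]
        cout = np.cumsum(~M, axis=1) / (p - sizes)[:, None]
        scores[:, j] = (cin - cout).sum(axis=1)
    if normalize:
        spread = scores.max() - scores.min()
        if spread > 0:
            scores = scores / spread
    return EnrichmentMatrix(
        scores=scores,
        set_names=gsc.names,
        sample_ids=list(expr.sample_ids),
        method="ssgsea",
        params={"weight_exponent": weight_exponent, "normalize": normalize},
    )
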