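"""The KS-like random walk and the GSVA enrichment scores.

For each sample, genes are traversed in decreasing order of their
expression-level statistic.  The walk accumulates the tau-weighted
symmetric-rank mass of in-set genes (normalized by the total in-set
mass) minus the fraction of out-of-set genes seen so far:

    nu(l) = sum_{i<=l, in set} |r_i|^tau / sum_{in set} |r_i|^tau
          - #{i<=l, not in set} / (p - |set|)

Both cumulative terms reach 1 at l = p, so every trajectory ends at 0.
Two summaries turn the trajectory into an enrichment score: the maximum
deviation from zero (``max``; bimodal under the null) and the sum of the
largest positive and largest negative excursions (``diff``; excursions
in opposite directions cancel, giving an approximately normal,
zero-centred null).
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (
    EnrichmentMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    KcdfConfig,
    RankMatrix,
    WalkConfig,
    WalkTrajectory,
)
from .expression_stat import gaussian_kcdf, kernel_cdf, symmetric_ranks

logger = logging.getLogger(__name__)

__all__ = [
    "random_walk",
    "es_max",
    "es_diff",
    "gsva",
    "gsva_scores",
    "membership_matrix",
    "walk_extrema",
    "null_score_distribution",
]


def membership_matrix(
    gsc: GeneSetCollection, gene_ids: list[str], allow_full: bool = False
) -> np.ndarray:
    """Boolean (n_sets, p) matrix mapping each set onto matrix rows.

    Every set must map to at least one gene.  Unless ``allow_full`` is
    set (appropriate for methods without an out-of-set term), a set must
    also leave at least one gene outside it, because the out-of-set walk
    term is undefined otherwise.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    p = len(gene_ids)
    member = np.zeros((len(gsc), p), dtype=bool)
    for k, s in enumerate(gsc):
        rows = [index[g] for g in s.members if g in index]
        if not rows:
            raise ValueError(f"gene set {s.name!r} maps to no genes in the matrix")
        if len(rows) == p and not allow_full:
            raise ValueError(
                f"gene set {s.name!r} covers all genes: out-of-set term undefined"
            )
        member[k, rows] = True
    return member


def _walk_matrix(
    rm: RankMatrix, member: np.ndarray, tau: float, sample: int
) -> np.ndarray:
    """All trajectories (n_sets, p) for one sample; vectorized over sets."""
    p = rm.n_genes
    ordj = rm.order[:, sample]
    w = rm.sym[ordj, sample] ** tau
    M = member[:, ordj]
    sizes = member.sum(axis=1)
    cin = np.cumsum(M * w[None, :], axis=1)
    tot = cin[:, -1].copy()
    degenerate = tot == 0
    if degenerate.any():
        logger.warning(
            "%d gene set(s) have zero total tail weight; falling back to "
            "unweighted in-set fractions", int(degenerate.sum()),
        )
        cin[degenerate] = np.cumsum(M[degenerate], axis=1)
        tot[degenerate] = sizes[degenerate]
    cout = np.cumsum(~M, axis=1)
    return cin / tot[:, None] - cout / (p - sizes)[:, None]


def random_walk(
    rm: RankMatrix,
    sample: int,
    gene_set: np.ndarray,
    cfg: WalkConfig | None = None,
    set_name: str = "",
    sample_id: str = "",
) -> WalkTrajectory:
    """Compute the walk for one sample and one gene set.

    ``gene_set`` is either a boolean mask of length p or an array of
    gene row indices.
    """
    cfg = cfg or WalkConfig()
    p = rm.n_genes
    mask = np.zeros(p, dtype=bool)
    gene_set = np.asarray(gene_set)
    if gene_set.dtype == bool:
        mask[:] = gene_set
    else:
        mask[gene_set] = True
    size = int(mask.sum())
    if size < 1:
        raise ValueError("gene set is empty")
    if size >= p:
        raise ValueError("gene set covers all genes: out-of-set term undefined")
    nu = _walk_matrix(rm, mask[None, :], cfg.tau, sample)[0]
    return WalkTrajectory(nu=nu, set_name=set_name, sample_id=sample_id)


def es_max(tr: WalkTrajectory) -> float:
    """Maximum deviation from zero, sign kept; positive wins exact ties."""
    vmax = float(tr.nu.max())
    vmin = float(tr.nu.min())
    return vmax if vmax >= -vmin else vmin


def es_diff(tr: WalkTrajectory) -> float:
    """Largest positive excursion plus largest negative excursion.

    Equal two-sided excursions cancel to zero; a one-sided trajectory
    reduces to its extreme value.
    """
    return max(0.0, float(tr.nu.max())) + min(0.0, float(tr.nu.min()))


def walk_extrema(
    rm: RankMatrix, member: np.ndarray, tau: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per (set, sample) maxima and minima of the walk, vectorized.

    Returns ``(vmax, vmin)`` of shape (n_sets, n_samples); both
    enrichment-score modes are cheap functions of these.
    """
    m = member.shape[0]
    n = rm.n_samples
    vmax = np.empty((m, n))
    vmin = np.empty((m, n))
    for j in range(n):
        nu = _walk_matrix(rm, member, tau, j)
        vmax[:, j] = nu.max(axis=1)
        vmin[:, j] = nu.min(axis=1)
    return vmax, vmin


def _es_from_extrema(vmax: np.ndarray, vmin: np.ndarray, es_mode: str) -> np.ndarray:
    if es_mode == "max":
        return np.where(vmax >= -vmin, vmax, vmin)
    return np.maximum(vmax, 0.0) + np.minimum(vmin, 0.0)


def gsva_scores(
    rm: RankMatrix, member: np.ndarray, wcfg: WalkConfig | None = None
) -> np.ndarray:
    """Enrichment scores (n_sets, n_samples) from precomputed ranks."""
    wcfg = wcfg or WalkConfig()
    vmax, vmin = walk_extrema(rm, member, wcfg.tau)
    return _es_from_extrema(vmax, vmin, wcfg.es_mode)


def gsva(
    expr: ExpressionMatrix,
    gsc: GeneSetCollection,
    kcfg: KcdfConfig | None = None,
    wcfg: WalkConfig | None = None,
) -> EnrichmentMatrix:
    """Full pipeline: kernel CDF -> symmetric ranks -> walk -> score.

    ``gsc`` should already be size-filtered against ``expr`` (see
    :func:`pygsva.genesets_io.apply_size_filter`); members absent from
    the matrix are ignored here.  Scores lie in [-1, 1].
    """
    kcfg = kcfg or KcdfConfig()
    wcfg = wcfg or WalkConfig()
    z = kernel_cdf(expr, kcfg)
    rm = symmetric_ranks(z)
    member = membership_matrix(gsc, expr.gene_ids)
    scores = gsva_scores(rm, member, wcfg)
    kernel = kcfg.kernel
    if kernel == "auto":
        kernel = "gaussian" if expr.value_kind == "continuous" else "poisson"
    return EnrichmentMatrix(
        scores=scores,
        set_names=gsc.names,
        sample_ids=list(expr.sample_ids),
        method="gsva",
        params={
            "kernel": kernel,
            "bandwidth_factor": kcfg.bandwidth_factor,
            "poisson_r": kcfg.poisson_r,
            "tau": wcfg.tau,
            "es_mode": wcfg.es_mode,
        },
    )


def null_score_distribution(
    p: int = 20000,
    n: int = 30,
    m: int = 100,
    size_range: tuple[int, int] = (10, 100),
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Score distributions under a label-free null, for both ES modes.

    Standard Gaussian deviates for ``p`` genes by ``n`` samples are
    scored against ``m`` random gene sets with sizes drawn uniformly
    from ``size_range``.  Returns the flattened max-mode and diff-mode
    score collections (each of length ``m * n``), computed from one
    shared set of walk trajectories.  The max-mode scores are bimodal by
    construction of the statistic; the diff-mode scores are unimodal and
    approximately normal around zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.standard_normal((p, n))
    expr = ExpressionMatrix(
        values=x,
        gene_ids=[f"g{i}" for i in range(p)],
        sample_ids=[f"s{j}" for j in range(n)],
        value_kind="continuous",
    )
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=m)
    member = np.zeros((m, p), dtype=bool)
    for k, sz in enumerate(sizes):
        member[k, rng.choice(p, size=sz, replace=False)] = True
    z = gaussian_kcdf(expr)
    rm = symmetric_ranks(z)
    vmax, vmin = walk_extrema(rm, member, tau=1.0)
    es_max_scores = _es_from_extrema(vmax, vmin, "max").ravel()
    es_diff_scores = _es_from_extrema(vmax, vmin, "diff").ravel()
    return es_max_scores, es_diff_scores
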