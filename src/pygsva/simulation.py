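"""Synthetic expression data and the benchmark studies.

Expression data follow a linear additive model for normalized
(microarray-scale) values in a two-group design:

    y_ij = alpha_i + beta_j + eps_ij

with a gene effect alpha_i ~ N(0, 1) (mimicking e.g. probe effects),
a per-sample effect beta_j, and noise eps_ij ~ N(0, 1).  For
non-differential genes beta_j ~ N(0, 1) in both groups; differentially
expressed (DE) genes replace the sample effect in group 2 by a draw
from N(mu2, sigma2), one draw per group-2 sample, so the DE shift acts
only on DE rows.  The weak and strong effects are mu2 = 0.5 and
mu2 = 1 with sigma2 = 0.5.

Three studies built on the generator benchmark the scoring methods:

* power / type-I error — p = 1000 genes, a 30-gene DE set and a
  30-gene non-DE set, two-sample t-tests on the per-set score rows;
* differential-set calling — genome-scale replicates scored for many
  sets, per-set t-tests with Benjamini-Hochberg control, performance as
  the AUC of the binary calls against the true set labels;
* survival — group-dependent normal survival times with independent
  normal censoring, Cox proportional-hazards models on score rows and
  concordance on held-out data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .comparators import combined_zscore, plage, ssgsea
from .containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    KcdfConfig,
    WalkConfig,
)
from .gsva_core import gsva

logger = logging.getLogger(__name__)

__all__ = [
    "AdditiveModelParams",
    "SimulationScenario",
    "SurvivalParams",
    "simulate_additive",
    "score_with_method",
    "power_type1_study",
    "auc_study",
    "simulate_survival",
    "survival_study",
    "METHODS",
]

#: method name -> scorer(expr, gsc) for the benchmark loops
METHODS = ("gsva", "plage", "zscore", "ssgsea")

WEAK_EFFECT = 0.5
STRONG_EFFECT = 1.0
DE_SIGMA = 0.5


@dataclass
class AdditiveModelParams:
    """Parameters of the two-group linear additive generator."""

    p: int = 1000
    n1: int = 30
    n2: int = 30
    de_gene_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    mu2_de: float = STRONG_EFFECT
    sigma2_de: float = DE_SIGMA

    def __post_init__(self) -> None:
        self.de_gene_indices = np.asarray(self.de_gene_indices, dtype=int)
        if self.de_gene_indices.size and (
            self.de_gene_indices.min() < 0 or self.de_gene_indices.max() >= self.p
        ):
            raise ValueError("de_gene_indices out of range")
        if self.mu2_de <= 0:
            raise ValueError("mu2_de must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs at least 2 samples")


@dataclass
class SimulationScenario:
    """One cell of the benchmark design grid."""

    de_fraction_in_set: float = 0.5  # 0.5 or 0.8
    effect: str = "strong"  # "weak" | "strong"
    n: int = 60  # total sample size, split evenly
    set_size: int = 30
    replicates: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.de_fraction_in_set <= 1:
            raise ValueError("de_fraction_in_set must be in (0, 1]")
        if self.effect not in ("weak", "strong"):
            raise ValueError("effect must be 'weak' or 'strong'")

    @property
    def mu2(self) -> float:
        return WEAK_EFFECT if self.effect == "weak" else STRONG_EFFECT


@dataclass
class SurvivalParams:
    """Group-wise survival and censoring distributions (normal)."""

    mean_group1: float = 6.0
    mean_group2: float = 10.0
    sd_survival: float = 2.0
    mean_censor: float = 10.0
    sd_censor: float = 3.0
    min_time: float = 0.01  # negative draws truncated here


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_additive(
    params: AdditiveModelParams, seed: int | np.random.Generator = 0
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw one expression matrix plus 0/1 group labels.

    Columns are ordered group 1 first.  Group-2 columns at DE rows get
    an independent per-sample effect from N(mu2_de, sigma2_de) in place
    of the shared baseline N(0, 1) sample effect.
    """
    rng = _rng(seed)
    p, n1, n2 = params.p, params.n1, params.n2
    n = n1 + n2
    alpha = rng.standard_normal(p)
    beta = rng.standard_normal(n)
    beta_mat = np.tile(beta, (p, 1))
    if params.de_gene_indices.size:
        beta_de = rng.normal(params.mu2_de, params.sigma2_de, size=n2)
        beta_mat[np.ix_(params.de_gene_indices, np.arange(n1, n))] = beta_de
    eps = rng.standard_normal((p, n))
    values = alpha[:, None] + beta_mat + eps
    expr = ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(p)],
        sample_ids=[f"s{j}" for j in range(n)],
        value_kind="continuous",
    )
    labels = np.r_[np.zeros(n1, dtype=int), np.ones(n2, dtype=int)]
    return expr, labels


def score_with_method(
    method: str, expr: ExpressionMatrix, gsc: GeneSetCollection
) -> np.ndarray:
    """Score matrix (n_sets, n_samples) for one named method.

    GSVA runs with its defaults (Gaussian kernel on continuous data,
    tau = 1, diff-mode score).
    """
    if method == "gsva":
        return gsva(expr, gsc, KcdfConfig(), WalkConfig()).scores
    if method == "plage":
        return plage(expr, gsc).scores
    if method == "zscore":
        return combined_zscore(expr, gsc).scores
    if method == "ssgsea":
        return ssgsea(expr, gsc).scores
    raise ValueError(f"unknown method {method!r}")


def _two_sets(p: int, set_size: int) -> GeneSetCollection:
    ids = [f"g{i}" for i in range(p)]
    return GeneSetCollection(
        sets=[
            GeneSet("de_set", "differential", tuple(ids[:set_size])),
            GeneSet("nonde_set", "null", tuple(ids[set_size : 2 * set_size])),
        ]
    )


def power_type1_study(
    scenario: SimulationScenario,
    methods: tuple[str, ...] = METHODS,
    p: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> dict[str, dict[str, float]]:
    """Estimate statistical power and empirical type-I error per method.

    Each replicate simulates a two-group data set in which the first
    ``set_size`` genes form a DE gene set (a ``de_fraction_in_set``
    share of them actually shifted) and the next ``set_size`` genes a
    non-DE set.  Scores for both sets are compared between groups with
    a two-sample t-test at level ``alpha``.  Power is the rejection
    fraction on the DE set; the type-I error is the rejection fraction
    on the non-DE set.  Binomial standard errors accompany both.
    """
    rng = _rng(seed)
    reps = scenario.replicates
    if reps < 50:
        logger.warning("only %d replicates; power/type-I estimates will be unstable", reps)
    n1 = scenario.n // 2
    n2 = scenario.n - n1
    n_de = int(round(scenario.set_size * scenario.de_fraction_in_set))
    gsc = _two_sets(p, scenario.set_size)
    params = AdditiveModelParams(
        p=p, n1=n1, n2=n2,
        de_gene_indices=np.arange(n_de),
        mu2_de=scenario.mu2,
    )
    rejections = {m: np.zeros((reps, 2), dtype=bool) for m in methods}
    for r in range(reps):
        expr, labels = simulate_additive(params, rng)
        g1 = labels == 0
        for m in methods:
            scores = score_with_method(m, expr, gsc)
            pvals = stats.ttest_ind(
                scores[:, g1], scores[:, ~g1], axis=1, equal_var=False
            ).pvalue
            rejections[m][r] = pvals < alpha
    out: dict[str, dict[str, float]] = {}
    for m in methods:
        power = rejections[m][:, 0].mean()
        type1 = rejections[m][:, 1].mean()
        out[m] = {
            "power": float(power),
            "type1": float(type1),
            "power_se": float(np.sqrt(power * (1 - power) / reps)),
            "type1_se": float(np.sqrt(type1 * (1 - type1) / reps)),
            "replicates": reps,
        }
    return out


def _build_auc_sets(
    rng: np.random.Generator,
    p: int,
    n_de_genes: int,
    n_sets: int,
    n_de_sets: int,
    set_size: int,
    de_fraction: float,
) -> tuple[GeneSetCollection, np.ndarray]:
    """DE sets mix DE/non-DE genes per scenario; null sets sample uniformly."""
    ids = np.array([f"g{i}" for i in range(p)])
    n_in = int(round(set_size * de_fraction))
    sets: list[GeneSet] = []
    labels = np.zeros(n_sets, dtype=int)
    for k in range(n_de_sets):
        de_part = rng.choice(n_de_genes, size=n_in, replace=False)
        bg_part = n_de_genes + rng.choice(p - n_de_genes, size=set_size - n_in, replace=False)
        members = tuple(ids[np.r_[de_part, bg_part]])
        sets.append(GeneSet(f"de_set{k}", "differential", members))
        labels[k] = 1
    for k in range(n_sets - n_de_sets):
        members = tuple(ids[rng.choice(p, size=set_size, replace=False)])
        sets.append(GeneSet(f"null_set{k}", "background", members))
    return GeneSetCollection(sets=sets), labels


def auc_study(
    scenario: SimulationScenario,
    methods: tuple[str, ...] = METHODS,
    p: int = 10000,
    n_de_genes: int = 2000,
    n_sets: int = 1000,
    n_de_sets: int = 500,
    fdr: float = 0.05,
    replicates: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Differential-set calling accuracy as AUC distributions per method.

    Each replicate: simulate with ``n_de_genes`` shifted genes, build
    ``n_sets`` gene sets (``n_de_sets`` of them enriched for DE genes in
    the scenario proportion), score with every method, t-test each set
    between groups, call sets at the Benjamini-Hochberg ``fdr`` level,
    and take the AUC of the binary call vector against the true labels.
    A degenerate replicate (all calls identical) counts as AUC 0.5.
    """
    from sklearn.metrics import roc_auc_score
    from statsmodels.stats.multitest import multipletests

    rng = _rng(seed)
    n1 = scenario.n // 2
    n2 = scenario.n - n1
    aucs = {m: np.empty(replicates) for m in methods}
    for r in range(replicates):
        gsc, labels = _build_auc_sets(
            rng, p, n_de_genes, n_sets, n_de_sets, scenario.set_size,
            scenario.de_fraction_in_set,
        )
        params = AdditiveModelParams(
            p=p, n1=n1, n2=n2,
            de_gene_indices=np.arange(n_de_genes),
            mu2_de=scenario.mu2,
        )
        expr, grp = simulate_additive(params, rng)
        g1 = grp == 0
        for m in methods:
            scores = score_with_method(m, expr, gsc)
            pvals = stats.ttest_ind(
                scores[:, g1], scores[:, ~g1], axis=1, equal_var=False
            ).pvalue
            calls = multipletests(pvals, alpha=fdr, method="fdr_bh")[0].astype(int)
            if calls.min() == calls.max():
                logger.warning("replicate %d, %s: degenerate calls; AUC set to 0.5", r, m)
                aucs[m][r] = 0.5
            else:
                aucs[m][r] = roc_auc_score(labels, calls)
    return aucs


def simulate_survival(
    labels: np.ndarray,
    sp: SurvivalParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed times and event indicators for a two-group cohort.

    Survival times are normal with a group-dependent mean; censoring
    times are drawn independently for every sample.  The observed time
    is the smaller of the two and the event fires when the survival
    time is reached first.  Negative draws are truncated at a small
    positive epsilon so downstream hazard models stay valid.
    """
    sp = sp or SurvivalParams()
    rng = _rng(seed)
    labels = np.asarray(labels)
    n = labels.size
    means = np.where(labels == 0, sp.mean_group1, sp.mean_group2)
    surv = rng.normal(means, sp.sd_survival)
    cens = rng.normal(sp.mean_censor, sp.sd_censor, size=n)
    surv = np.maximum(surv, sp.min_time)
    cens = np.maximum(cens, sp.min_time)
    time = np.minimum(surv, cens)
    event = surv <= cens
    return time, event


def survival_study(
    n: int = 100,
    methods: tuple[str, ...] = METHODS,
    p: int = 1000,
    n_sets: int = 50,
    set_size: int = 10,
    de_fraction: float = 0.5,
    replicates: int = 25,
    include_gene_level: bool = False,
    n_top_genes: int = 10,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Concordance of survival risk predicted from gene-set scores.

    Per replicate: independent training and test cohorts are simulated
    (strong effect, one DE set of ``set_size`` genes among ``n_sets``),
    survival is generated per group, each method's score rows are fitted
    with univariate Cox proportional-hazards models on the training
    cohort, the set with the smallest Wald p-value is carried to the
    test cohort, and the concordance index of its risk prediction is
    recorded.  The optional gene-level baseline picks the
    ``n_top_genes`` lowest-p genes and fits a joint Cox model on them.
    """
    from lifelines import CoxPHFitter
    from lifelines.utils import concordance_index
    import pandas as pd

    rng = _rng(seed)
    n1 = n // 2
    n2 = n - n1
    ids = [f"g{i}" for i in range(p)]
    results: dict[str, list[float]] = {m: [] for m in methods}
    if include_gene_level:
        results["gene"] = []

    def fit_cox_rows(rows: np.ndarray, time, event) -> np.ndarray:
        pv = np.empty(rows.shape[0])
        for i, row in enumerate(rows):
            df = pd.DataFrame({"x": row, "T": time, "E": event.astype(int)})
            try:
                cph = CoxPHFitter()
                cph.fit(df, duration_col="T", event_col="E")
                pv[i] = cph.summary.loc["x", "p"]
            except Exception:  # non-convergence on degenerate rows
                pv[i] = 1.0
            if not np.isfinite(pv[i]):
                pv[i] = 1.0
        return pv

    for _ in range(replicates):
        # one DE set, the rest sampled from the remaining genes
        sets = [GeneSet("de_set", "differential", tuple(ids[:set_size]))]
        for k in range(n_sets - 1):
            pick = set_size + rng.choice(p - set_size, size=set_size, replace=False)
            sets.append(GeneSet(f"null_set{k}", "background", tuple(np.array(ids)[pick])))
        gsc = GeneSetCollection(sets=sets)
        params = AdditiveModelParams(
            p=p, n1=n1, n2=n2,
            de_gene_indices=np.arange(int(round(set_size * de_fraction))),
            mu2_de=STRONG_EFFECT,
        )
        expr_tr, lab_tr = simulate_additive(params, rng)
        expr_te, lab_te = simulate_additive(params, rng)
        t_tr, e_tr = simulate_survival(lab_tr, seed=rng)
        t_te, e_te = simulate_survival(lab_te, seed=rng)
        for m in methods:
            s_tr = score_with_method(m, expr_tr, gsc)
            s_te = score_with_method(m, expr_te, gsc)
            pv = fit_cox_rows(s_tr, t_tr, e_tr)
            best = int(np.argmin(pv))
            df_tr = pd.DataFrame({"x": s_tr[best], "T": t_tr, "E": e_tr.astype(int)})
            cph = CoxPHFitter()
            cph.fit(df_tr, duration_col="T", event_col="E")
            risk = cph.predict_partial_hazard(pd.DataFrame({"x": s_te[best]}))
            results[m].append(concordance_index(t_te, -np.asarray(risk), e_te))
        if include_gene_level:
            pv = fit_cox_rows(expr_tr.values, t_tr, e_tr)
            top = np.argsort(pv)[:n_top_genes]
            cols = {f"x{i}": expr_tr.values[g] for i, g in enumerate(top)}
            df_tr = pd.DataFrame({**cols, "T": t_tr, "E": e_tr.astype(int)})
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df_tr, duration_col="T", event_col="E")
            df_te = pd.DataFrame({f"x{i}": expr_te.values[g] for i, g in enumerate(top)})
            risk = cph.predict_partial_hazard(df_te)
            results["gene"].append(concordance_index(t_te, -np.asarray(risk), e_te))
    return {k: np.asarray(v) for k, v in results.items()}
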