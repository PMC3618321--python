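# Methods

This note documents the models, parameter choices and numerical decisions
behind `pygsva`, and what the simulation-based tests do and do not establish.

## Scoring model

GSVA converts a genes × samples matrix into gene-sets × samples enrichment
scores in four stages (kernel CDF → symmetric ranks → random walk → score
summary); the README gives the formulas. Assumptions worth making explicit:

- The kernel CDF is estimated **across samples within each gene**, so scores
  are population-relative: a sample's score depends on the other samples in
  the matrix. Scoring the same sample inside two different cohorts gives
  different values by design. The estimate needs a reasonable number of
  samples; below roughly n = 10 the package logs a warning.
- The walk is **competitive**: a set is scored against the genes outside it.
  Gene sets covering every gene in the matrix are rejected (the out-of-set
  term is undefined). If differential signal exists outside a set, it can
  displace the set's ranks — the benchmarks below quantify the (small)
  type-I leakage this causes.
- Scores lie in [−1, 1] and carry no significance by themselves; inference
  belongs downstream (the benchmark module uses t-tests on score rows).

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `bandwidth_factor` | 0.25 | Gaussian bandwidth h_i = factor · s_i (sample SD, ddof = 1) |
| `poisson_r` | 0.5 | kernel mean offset; places the Poisson kernel's mode at the observed count |
| `tau` | 1.0 | tail-weight exponent on the symmetric ranks; 0 = unweighted fractions |
| `es_mode` | `diff` | `diff` (unimodal, zero-centred null) or `max` (classical KS summary, bimodal null) |
| size filter | 10–500 | mapped set-size bounds, both inclusive; applied after intersecting members with the matrix |
| ssGSEA `weight_exponent` | 0.25 | rank weight in the running sum, with global range normalization |

`diff` is the default because its null is approximately normal, so ordinary
parametric downstream tests apply; `max` is preferable when a collection
separates pathways into explicit "up" and "down" sets.

## Numerical and tie-breaking decisions

- Gaussian kernel sums use the closed-form normal CDF (`scipy.special.ndtr`),
  chunked so the (genes × n × n) difference tensor stays within a few
  hundred MB at genome scale. The Poisson CDF uses the regularized
  incomplete gamma (`scipy.special.pdtr`), stable for large means.
- Zero-variance genes get the smallest positive bandwidth among the other
  genes (1.0 if none exists): the row becomes constant and carries no
  ranking information, without dividing by zero.
- Ranks must be a permutation of 1..p for the walk, so ties are broken
  deterministically by gene row order (earlier rows rank lower); average
  ranks would break the permutation invariant, randomized tie-breaking would
  break reproducibility. Walk traversal is by decreasing statistic.
- |p/2 − rank| uses real-valued p/2 (p odd gives half-integer weights).
- `es_max` returns the positive extreme on an exact magnitude tie.
- If a set's total tail weight is zero (possible only when every member sits
  exactly at rank p/2), the in-set term falls back to unweighted fractions,
  with a warning.
- IQR filtering drops `floor(p · fraction)` lowest-IQR genes; boundary ties
  keep earlier rows. PLAGE's singular-vector sign is fixed by non-negative
  correlation with the mean standardized member profile.
- Matrix text I/O uses 12 significant digits, which round-trips scores
  beyond test tolerances while staying diff-able.

## Simulation framework

`simulate_additive` draws y_ij = α_i + β_j + ε_ij with α_i ~ N(0,1) (gene
effect, e.g. probe affinity), β_j ~ N(0,1) (per-sample effect) and
ε_ij ~ N(0,1). Differentially expressed (DE) genes replace the sample effect
in group-2 columns by one per-sample draw from N(μ₂, 0.5), with μ₂ = 0.5
("weak") or 1 ("strong"). The shift is applied on DE rows only — the only
reading under which a designated non-DE gene set is actually non-DE while
sharing the sample effect. This generator mimics normalized microarray-scale
data: gene-specific offsets, correlated sample-level noise, Gaussian
residuals. It does **not** model count overdispersion, gene–gene correlation
within pathways, batch structure or heavy tails, so passing benchmarks show
correct relative behaviour of the methods under this model, not performance
guarantees on real data.

Study configurations (defaults follow the benchmark design; scaled sizes
used by the test suite are given in parentheses as the package's standard
quick-run settings):

- **Power / type-I:** p = 1000 genes, a 30-gene DE set (50% or 80% of its
  members shifted) and a 30-gene non-DE set, n = 10–60 samples split evenly,
  1000 replicates (tests use 200–1000). Welch t-tests on score rows at
  α = 0.05; power = rejection rate on the DE set, type-I = rejection rate on
  the non-DE set, with binomial standard errors.
- **Differential-set AUC:** p = 10 000 genes with 2000 DE, 1000 sets of 30
  genes of which 500 are DE in the scenario proportion, non-DE sets sampled
  uniformly from all genes, n = 60, per-set t-tests with Benjamini–Hochberg
  control at 5% (or 1%), AUC of the binary call vector, 100 replicates
  (quick-run: p = 2000, 400 DE genes, 200 sets / 100 DE, 20 replicates).
  Because null sets are sampled from the whole gene pool they carry ~20% DE
  contamination; methods differ sharply in how they respond to it (see the
  type-I note below).
- **Survival:** survival times N(6, 2) vs N(10, 2) per group, censoring
  N(10, 3) for everyone, observed time = min, event = survival ≤ censoring;
  negative draws truncate at 0.01 so hazard models remain valid. The
  predictive study fits univariate Cox models per score row on a training
  cohort, carries the smallest-Wald-p set to an independent test cohort and
  reports the concordance index.
- **Null score shapes:** p = 20 000 i.i.d. standard-normal genes, n = 30,
  100 random sets of 10–100 genes. `max` scores are bimodal, `diff` scores
  unimodal and centred — verified with the dip test below.

One master seed drives everything; replicate streams derive from spawned
child seeds, so results are independent of execution order and bit-for-bit
reproducible.

## Unimodality testing

No dip-statistic implementation is available in the installed stack, so the
package ships its own (`pygsva.unimodality`): the classical greatest-convex-
minorant / least-concave-majorant interval-shrinking algorithm. It is
validated in the test suite against a brute-force oracle that finds the
closest piecewise-linear unimodal CDF by linear programming over all
candidate modes. P-values come from a uniform parametric bootstrap — the
asymptotically least favourable unimodal null — which makes the test
conservative for lighter-tailed data; 200–500 bootstrap draws give ample
resolution at the 5% level.

## Observed calibration properties

The acceptance suite computes (rather than assumes) the following, at the
quick-run sizes above: GSVA's type-I error on the non-DE set is at the
nominal 5% under the weak scenario and in a pure null; at strong effect
sizes a small inflation (~0.07–0.10) appears, the price of the competitive
walk when strong signal exists outside the tested set. In the AUC study,
PLAGE and the combined z-score are bistable across replicates — shared
sample-effect noise can drown their scores entirely (degenerate calls,
AUC ≈ 0.5) — while GSVA's rank-based scores stay in a narrow band, which is
what gives GSVA the best mean AUC despite lower specificity against
contaminated null sets.

## Known limitations

- Bulk expression only; no specific support for sparse single-cell counts.
- PLAGE and the combined z-score assume roughly normal continuous data; when
  handed counts they operate on raw values with a warning.
- ssGSEA follows its originally published form (rank weights, exponent 0.25,
  global range normalization); other published variants differ in
  normalization and are not implemented.
- The scoring pipeline holds the full dense matrix plus one
  (sets × genes) walk buffer per sample in memory; ~10⁵ genes × ~10³ sets is
  comfortable, far larger collections are not the target.
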