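# pygsva

Single-sample gene-set enrichment scoring for bulk transcriptomics, plus a
simulation harness for benchmarking it.

Most gene-set enrichment tools summarize a *two-group comparison* into one
score per pathway. `pygsva` instead condenses an expression matrix into a
**pathways × samples** matrix of enrichment scores, without using any
phenotype labels — a change of coordinates from genes to gene sets that makes
downstream modelling (differential pathway activity, survival regression,
clustering) straightforward. It implements **GSVA** (gene set variation
analysis) together with the three standard unsupervised single-sample
comparators — **PLAGE**, the **combined z-score** and **ssGSEA** — and the
simulation studies used to compare them.

## The method

Given a normalized expression matrix *X* = {x_ij} (p genes × n samples) and
gene sets γ_1, …, γ_m:

1. **Expression-level statistic.** For each gene *i*, a kernel estimate of its
   cumulative density is evaluated at each sample's value:
   - continuous (log2 microarray-scale) data, Gaussian kernel:
     z_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i), with per-gene bandwidth
     h_i = s_i/4 (s_i = sample standard deviation);
   - integer counts (RNA-seq), discrete Poisson kernel:
     z_ij = (1/n) Σ_k P(Y ≤ x_ij), Y ~ Poisson(x_ik + 0.5).

   This places each value within its own gene's distribution across the
   sample population, neutralizing gene-specific effects (probe affinity, GC
   content, length).
2. **Symmetric ranks.** Per sample, z is ranked (largest → rank p) and folded
   around the centre: r_ij = |p/2 − z_(i)j|, so both tails of the ranking get
   large weights.
3. **KS-like random walk.** Traversing genes by decreasing z,
   ν_jk(ℓ) = Σ_{i≤ℓ, in γ_k} |r_ij|^τ / Σ_{in γ_k} |r_ij|^τ −
   #{i≤ℓ, not in γ_k}/(p−|γ_k|), with tail weight τ = 1 by default.
4. **Enrichment score.** Either the walk's maximum deviation from zero
   (`max`; bimodal under the null) or the sum of its largest positive and
   largest negative excursions (`diff`, the default; opposite excursions
   cancel, giving an approximately normal, zero-centred null).

PLAGE scores a set as the first right-singular vector of its row-standardized
submatrix; the combined z-score is the Stouffer sum Σ z_ij /√|γ|; ssGSEA
integrates a weighted in-set/out-of-set rank-ECDF difference and normalizes
by the global score range.

## Worked example

```sh
pygsva make-fixture toy_continuous -d . --seed 7       # 60 genes x 8 samples, 5 sets
pygsva score -i toy_continuous.expr.tsv -g toy_continuous.gmt \
       -o scores.tsv --method gsva --es diff --min-size 5
head -4 scores.tsv
```

```
# method=gsva
# params={"bandwidth_factor": 0.25, "es_mode": "diff", "kernel": "gaussian", "poisson_r": 0.5, "tau": 1.0}
gene_set        s0              s1              s2      ...
set0    -0.526315789474 -0.00269849507006       0.308895155088  ...
```

Each row is a gene set, each column a sample; entries lie in [−1, 1]. A
positive entry means the set's genes sit concentrated toward the top of that
sample's expression ranking relative to the rest of the transcriptome (set0
is relatively suppressed in sample s0, mildly activated in s2). The same
command with `--method plage|zscore|ssgsea` produces the comparator scores,
and `--value-kind counts` switches GSVA to the Poisson kernel. The library
API mirrors the CLI: `pygsva.gsva(expr, sets)` returns the score matrix with
full parameter metadata.

`pygsva simulate` emits synthetic two-group data from the additive model
y_ij = α_i + β_j + ε_ij used by the benchmarks, and `pygsva benchmark
{power-type1,auc,survival,null}` runs the corresponding study and writes a
JSON summary.

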