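"""Independent straight-line reference implementations used as test oracles.

Everything here is deliberately naive — explicit loops, ``sorted`` with
tuple keys, per-element library CDF calls — and shares no code with the
package, so that agreement with the vectorized implementation is
meaningful.
"""

from __future__ import annotations

import statistics

from scipy.stats import norm, poisson


def naive_gaussian_z(x):
    """Per-element evaluation of the Gaussian-kernel CDF statistic."""
    p = len(x)
    n = len(x[0])
    bandwidths = []
    for row in x:
        sd = statistics.stdev(row) if n > 1 else 0.0
        bandwidths.append(sd / 4.0)
    positive = [h for h in bandwidths if h > 0]
    fallback = min(positive) if positive else 1.0
    z = []
    for i in range(p):
        h = bandwidths[i] if bandwidths[i] > 0 else fallback
        row = []
        for j in range(n):
            total = 0.0
            for k in range(n):
                total += norm.cdf((x[i][j] - x[i][k]) / h)
            row.append(total / n)
        z.append(row)
    return z


def naive_poisson_z(x, r=0.5):
    """Per-element evaluation of the Poisson-kernel CDF statistic."""
    p = len(x)
    n = len(x[0])
    z = []
    for i in range(p):
        row = []
        for j in range(n):
            total = 0.0
            for k in range(n):
                total += poisson.cdf(x[i][j], x[i][k] + r)
            row.append(total / n)
        z.append(row)
    return z


def naive_sample_ranks(z_col):
    """Ranks 1..p, largest value gets p, ties to earlier rows first."""
    p = len(z_col)
    order_asc = sorted(range(p), key=lambda i: (z_col[i], i))
    ranks = [0] * p
    for pos, gene in enumerate(order_asc):
        ranks[gene] = pos + 1
    return ranks


def naive_walk(z_col, member_mask, tau):
    """Step-by-step accumulation of the random-walk vector for one sample."""
    p = len(z_col)
    ranks = naive_sample_ranks(z_col)
    sym = [abs(p / 2.0 - r) for r in ranks]
    traversal = sorted(range(p), key=lambda i: (z_col[i], i), reverse=True)
    size = sum(member_mask)
    total_in = sum(sym[g] ** tau for g in traversal if member_mask[g])
    nu = []
    cum_in = 0.0
    cum_out = 0
    for g in traversal:
        if member_mask[g]:
            cum_in += sym[g] ** tau if total_in > 0 else 1.0
        else:
            cum_out += 1
        denom_in = total_in if total_in > 0 else size
        nu.append(cum_in / denom_in - cum_out / (p - size))
    return nu


def naive_es(nu, mode):
    hi = max(nu)
    lo = min(nu)
    if mode == "max":
        return hi if hi >= -lo else lo
    return max(0.0, hi) + min(0.0, lo)


def naive_gsva(x, member_masks, kernel, tau, mode):
    """Full pipeline scores as nested lists [set][sample]."""
    z = naive_gaussian_z(x) if kernel == "gaussian" else naive_poisson_z(x)
    n = len(x[0])
    scores = []
    for mask in member_masks:
        row = []
        for j in range(n):
            z_col = [z[i][j] for i in range(len(x))]
            row.append(naive_es(naive_walk(z_col, mask, tau), mode))
        scores.append(row)
    return scores
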