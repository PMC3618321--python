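"""Hartigan & Hartigan's dip statistic and a bootstrap unimodality test.

The dip of a sample is the largest vertical distance between its
empirical CDF and the closest unimodal CDF, halved.  It is computed by
the classical iterative algorithm: maintain a candidate modal interval,
fit the greatest convex minorant (GCM) below it on the left and the
least concave majorant (LCM) above it on the right, find the largest
discrepancy between the two fits, and shrink the interval until the
discrepancy no longer grows.

P-values are obtained by a parametric bootstrap against the uniform
distribution, the asymptotically least favourable unimodal null, which
makes the test conservative for lighter-tailed unimodal data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def dip_statistic(values: np.ndarray) -> float:
    """The dip statistic of a 1-D sample.

    Always at least ``1 / (2n)``; large values indicate multimodality.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("dip requires a non-empty sample")
    if n == 1:
        return 0.0
    # 1-based arrays to keep the classical index bookkeeping readable
    xv = np.empty(n + 1)
    xv[1:] = x
    if x[0] == x[-1]:
        return 0.0

    low, high = 1, n
    dip = 1.0  # in ECDF-count units; divided by 2n at the end

    # mn[j]: start of the GCM segment ending at j (computed once, global)
    mn = np.empty(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 1:
                break
            mnmnj = mn[mnj]
            if (xv[j] - xv[mnj]) * (mnj - mnmnj) < (xv[mnj] - xv[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    # mj[k]: end of the LCM segment starting at k
    mj = np.empty(n + 1, dtype=np.int64)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n:
                break
            mjmjk = mj[mjk]
            if (xv[k] - xv[mjk]) * (mjk - mjmjk) < (xv[mjk] - xv[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    gcm = np.empty(n + 2, dtype=np.int64)
    lcm = np.empty(n + 2, dtype=np.int64)
    while True:
        # change points of the GCM from high down to low
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i  # gcm[l_gcm] == low
        # change points of the LCM from low up to high
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i  # lcm[l_lcm] == high

        ix = l_gcm - 1
        iv = 2
        ig1 = l_gcm
        ih1 = l_lcm
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            # largest distance between the two fits over [low, high]
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next change point comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xv[lcmiv] - xv[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xv[gcmix] - xv[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig1 = ix + 1
                        ih1 = iv - 1
                else:
                    # next change point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (xv[gcmix] - xv[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xv[lcmiv] - xv[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig1 = ix + 1
                        ih1 = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # dip within the current GCM fit
        dip_l = 0.0
        for j in range(ig1, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and xv[je] != xv[jb]:
                c = (je - jb) / (xv[je] - xv[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xv[jj] - xv[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # dip within the current LCM fit
        dip_u = 0.0
        for j in range(ih1, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and xv[je] != xv[jb]:
                c = (je - jb) / (xv[je] - xv[jb])
                for jj in range(jb, je + 1):
                    t = (xv[jj] - xv[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dip = max(dip, dip_l, dip_u)
        new_low, new_high = gcm[ig1], lcm[ih1]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return dip / (2.0 * n)


def dip_test(
    values: np.ndarray,
    n_boot: int = 500,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value for the unimodality null.

    The p-value is ``(1 + #{uniform bootstrap dips >= observed}) /
    (1 + n_boot)``; small values reject unimodality.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    observed = dip_statistic(values)
    n = values.size
    exceed = 0
    for _ in range(n_boot):
        if dip_statistic(rng.uniform(size=n)) >= observed:
            exceed += 1
    pvalue = (1 + exceed) / (1 + n_boot)
    return observed, pvalue
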