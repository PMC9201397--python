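"""Independent brute-force re-implementations used as oracles.

Everything here is written with plain Python loops and closed-form sums,
deliberately sharing no code path with the package (only scipy's t
distribution function is borrowed for a p-value CDF).
"""

import math

from scipy.stats import t as t_dist


def o_mean(xs):
    return sum(xs) / len(xs)


def o_sd(xs):
    m = o_mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def o_bias_stats(ref, cand):
    d = [c - r for r, c in zip(ref, cand)]
    pct = [100.0 * (c - r) / r for r, c in zip(ref, cand)]
    return o_mean(d), o_sd(d), o_mean(pct), o_sd(pct)


def o_mae(ref, cand):
    return o_mean([abs(c - r) for r, c in zip(ref, cand)])


def o_accuracy_counts(ref, cand):
    under = over = accurate = 0
    for r, c in zip(ref, cand):
        ratio = c / r
        if ratio < 0.95:
            under += 1
        elif ratio > 1.05:
            over += 1
        else:
            accurate += 1
    return accurate, under, over


def o_loa(ref, cand):
    d = [c - r for r, c in zip(ref, cand)]
    return o_mean(d) - 1.96 * o_sd(d), o_mean(d) + 1.96 * o_sd(d)


def o_ols(xs, ys):
    """Closed-form simple OLS: slope, intercept, slope SE, two-sided p, R^2."""
    n = len(xs)
    mx, my = o_mean(xs), o_mean(ys)
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    slope = sxy / sxx
    intercept = my - slope * mx
    sse = sum((y - (intercept + slope * x)) ** 2 for x, y in zip(xs, ys))
    syy = sum((y - my) ** 2 for y in ys)
    se = math.sqrt(sse / (n - 2) / sxx) if n > 2 else float("nan")
    if se > 0:
        tval = slope / se
        p = 2.0 * t_dist.sf(abs(tval), n - 2)
    else:
        p = 0.0 if slope != 0 else 1.0
    r2 = 1.0 - sse / syy if syy > 0 else float("nan")
    return slope, intercept, se, p, r2


def o_quantile_type7(values, q):
    """Linear interpolation between order statistics at h = q*(n-1)."""
    xs = sorted(values)
    h = q * (len(xs) - 1)
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def o_confusion(ref_by_sex, cand_by_sex, q=0.20):
    """Per-sex and pooled confusion counts with per-sex type-7 cut-offs.

    ``ref_by_sex`` / ``cand_by_sex`` map sex label -> list of values.
    Returns {sex: (tp, fn, fp, tn), 'all': summed}.
    """
    out = {}
    total = [0, 0, 0, 0]
    for sex in ref_by_sex:
        cutoff = o_quantile_type7(ref_by_sex[sex], q)
        tp = fn = fp = tn = 0
        for r, c in zip(ref_by_sex[sex], cand_by_sex[sex]):
            ref_low = r < cutoff
            cand_low = c < cutoff
            if ref_low and cand_low:
                tp += 1
            elif ref_low:
                fn += 1
            elif cand_low:
                fp += 1
            else:
                tn += 1
        out[sex] = (tp, fn, fp, tn)
        for i, v in enumerate((tp, fn, fp, tn)):
            total[i] += v
    out["all"] = tuple(total)
    return out
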