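"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: explicit loops and textbook formulas only, no reuse of
the code paths under test and no statsmodels/scipy shortcuts for the
quantities being checked.
"""

import math


def mean(xs):
    return sum(xs) / len(xs)


def sample_variance(xs):
    m = mean(xs)
    return sum((x - m) ** 2 for x in xs) / (len(xs) - 1)


def lloyd_crowding(xs):
    m = mean(xs)
    return m + sample_variance(xs) / m - 1.0


def ols_line(xs, ys):
    """(intercept, slope) from the normal equations."""
    n = len(xs)
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


def pearson_r(xs, ys):
    mx, my = mean(xs), mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(
        sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys)
    )
    return num / den


def paired_t(xs, ys):
    d = [x - y for x, y in zip(xs, ys)]
    n = len(d)
    sd = math.sqrt(sample_variance(d))
    return mean(d) / (sd / math.sqrt(n))


def oneway_anova_f(groups):
    """(F, df_between, df_within) for a one-way layout."""
    all_vals = [v for g in groups for v in g]
    grand = mean(all_vals)
    ss_between = sum(len(g) * (mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((v - mean(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w
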