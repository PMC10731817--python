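"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops and direct textbook formulas, so agreement is a genuine cross-check.
"""

import math


def naive_apen(series, m, r):
    """O(N^2) double-loop approximate entropy: Chebyshev distance,
    self-matches included."""
    u = [float(v) for v in series]
    n = len(u)

    def phi(k):
        templates = [u[i:i + k] for i in range(n - k + 1)]
        total = 0.0
        for ti in templates:
            count = 0
            for tj in templates:
                if max(abs(a - b) for a, b in zip(ti, tj)) <= r:
                    count += 1
            total += math.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sample_std(values):
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def adjusted_skewness(values):
    """Adjusted Fisher-Pearson sample skewness g1 * sqrt(n(n-1))/(n-2)."""
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    g1 = m3 / m2 ** 1.5
    return g1 * math.sqrt(n * (n - 1)) / (n - 2)


def path_length_planar(xs, ys):
    total = 0.0
    for i in range(len(xs) - 1):
        total += math.hypot(xs[i + 1] - xs[i], ys[i + 1] - ys[i])
    return total


def binom_pmf(k, n, p):
    return math.comb(n, k) * p ** k * (1 - p) ** (n - k)


def clopper_pearson_by_inversion(s, n, level=0.95, tol=1e-6):
    """Exact interval endpoints found by bisecting the binomial tail
    probabilities directly — no Beta quantiles involved."""
    alpha = 1 - level

    def upper_tail(p):  # P(X >= s)
        return sum(binom_pmf(k, n, p) for k in range(s, n + 1))

    def lower_tail(p):  # P(X <= s)
        return sum(binom_pmf(k, n, p) for k in range(0, s + 1))

    def solve(f, target, increasing):
        lo, hi = 0.0, 1.0
        while hi - lo > tol / 10:
            mid = (lo + hi) / 2
            below = f(mid) < target
            if below == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    # upper_tail is increasing in p, lower_tail decreasing
    lower = 0.0 if s == 0 else solve(upper_tail, alpha / 2, increasing=True)
    upper = 1.0 if s == n else solve(lower_tail, alpha / 2, increasing=False)
    return lower, upper


def hl_two_groups(obs1, exp1, n1, obs2, exp2, n2):
    """Hosmer-Lemeshow statistic for a fixed 2-group split."""
    stat = 0.0
    for o, e, m in ((obs1, exp1, n1), (obs2, exp2, n2)):
        stat += (o - e) ** 2 / (e * (1 - e / m))
    return stat
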