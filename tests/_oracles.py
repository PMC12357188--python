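"""Independent brute-force oracles used only by the tests.

Each oracle deliberately avoids the code path (and the scipy shortcut) it
checks: confusion by an explicit Python loop, AUC by the O(n^2) all-pairs
count, the exact binomial CI by bisection on hand-rolled binomial tail
probabilities, and percentile scores by direct strict-rank counting.
"""

from __future__ import annotations

import math


def loop_confusion(flags, outcomes):
    tp = fp = tn = fn = 0
    for f, y in zip(flags, outcomes):
        if f == 1 and y == 1:
            tp += 1
        elif f == 1 and y == 0:
            fp += 1
        elif f == 0 and y == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def pairwise_auc(probabilities, outcomes):
    cases = [p for p, y in zip(probabilities, outcomes) if y == 1]
    controls = [p for p, y in zip(probabilities, outcomes) if y == 0]
    if not cases or not controls:
        return math.nan
    score = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                score += 1.0
            elif c == d:
                score += 0.5
    return score / (len(cases) * len(controls))


def _binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def _tail_ge(k: int, n: int, p: float) -> float:
    return sum(_binom_pmf(j, n, p) for j in range(k, n + 1))


def _tail_le(k: int, n: int, p: float) -> float:
    return sum(_binom_pmf(j, n, p) for j in range(0, k + 1))


def clopper_pearson_by_bisection(k: int, n: int, level: float = 0.95,
                                 tol: float = 1e-10):
    """Invert the binomial tails directly: lower solves P(X>=k|p)=alpha/2,
    upper solves P(X<=k|p)=alpha/2."""
    alpha = 1 - level

    def bisect(func, target, increasing):
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if (func(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else bisect(lambda p: _tail_ge(k, n, p), alpha / 2, True)
    upper = 1.0 if k == n else bisect(lambda p: _tail_le(k, n, p), alpha / 2, False)
    return lower, upper


def strict_rank_percentiles(probabilities):
    n = len(probabilities)
    return [
        (100 * sum(1 for q in probabilities if q < p)) // n for p in probabilities
    ]
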