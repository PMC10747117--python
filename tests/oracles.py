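"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (explicit loops, textbook
formulas, exhaustive enumeration) and deliberately avoids the package's
vectorised code paths.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial, sqrt

import numpy as np


# ---------------------------------------------------------------------------
# time-domain feature formulas


def oracle_mode(x) -> float:
    """Most frequent value (smallest on ties) if ties exist; otherwise a
    plain recursive half-sample mode, averaging the leftmost-tie and
    rightmost-tie scans."""
    xs = sorted(float(v) for v in x)
    counts: dict[float, int] = {}
    for v in xs:
        counts[v] = counts.get(v, 0) + 1
    if max(counts.values()) > 1:
        best = max(counts.values())
        return min(v for v, c in counts.items() if c == best)

    def rec(s, from_right):
        n = len(s)
        if n == 1:
            return s[0]
        if n == 2:
            return (s[0] + s[1]) / 2
        if n == 3:
            if s[2] - s[1] < s[1] - s[0]:
                return (s[1] + s[2]) / 2
            if s[2] - s[1] > s[1] - s[0]:
                return (s[0] + s[1]) / 2
            return s[1]
        m = n // 2 + 1
        widths = [s[i + m - 1] - s[i] for i in range(n - m + 1)]
        best = min(widths)
        if from_right:
            i = max(i for i, w in enumerate(widths) if w == best)
        else:
            i = widths.index(best)
        return rec(s[i : i + m], from_right)

    return (rec(xs, False) + rec(xs, True)) / 2


def oracle_feature(x, name: str, zc_mode: str = "conventional") -> float:
    """Evaluate one named feature on one window, straight from its formula."""
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    sd = sqrt(var)
    if name == "mean":
        return mean
    if name == "Maximum":
        return max(x)
    if name == "Minimum":
        return min(x)
    if name == "amplitude":
        return max(x) - min(x)
    if name == "Median":
        s = sorted(x)
        return s[(n - 1) // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
    if name == "Activity":
        return var
    if name == "Energy":
        return sum(v * v for v in x) / n
    if name == "RMS":
        return sqrt(sum(v * v for v in x) / n)
    if name == "Mobility":
        d = [x[i + 1] - x[i] for i in range(n - 1)]
        dm = sum(d) / len(d)
        dv = sum((v - dm) ** 2 for v in d) / (len(d) - 1)
        return sqrt(dv / var)
    if name == "Complexity":
        d = [x[i + 1] - x[i] for i in range(n - 1)]
        return oracle_feature(d, "Mobility") / oracle_feature(x, "Mobility")
    if name == "kurtosis":
        q1, q3, p10, p90 = (float(np.percentile(x, q)) for q in (25, 75, 10, 90))
        return (q3 - q1) / (2 * (p90 - p10))
    if name == "skewness":
        return (mean - oracle_mode(x)) / sd
    if name == "Zero crossing":
        changes = 0
        pairs = 0
        for a, b in zip(x[:-1], x[1:]):
            if a == 0 or b == 0:
                continue
            pairs += 1
            if (a > 0) != (b > 0):
                changes += 1
        return (n - 1) - changes if zc_mode == "as_printed" else changes
    raise KeyError(name)


# ---------------------------------------------------------------------------
# exhaustive path-dependent Shapley values for a single tree


def tree_conditional_expectation(arrays, x, S, j=0, strict=False):
    """E[f(x) | x_S] under cover-weighted tree traversal."""
    left, right, feat, thr, val, cov = arrays
    if left[j] < 0:
        return val[j]
    f = int(feat[j])
    if f in S:
        if strict:
            nxt = left[j] if x[f] < thr[j] else right[j]
        else:
            nxt = left[j] if x[f] <= thr[j] else right[j]
        return tree_conditional_expectation(arrays, x, S, int(nxt), strict)
    l, r = int(left[j]), int(right[j])
    return (
        cov[l] * tree_conditional_expectation(arrays, x, S, l, strict)
        + cov[r] * tree_conditional_expectation(arrays, x, S, r, strict)
    ) / cov[j]


def brute_force_tree_shap(arrays, x, p, strict=False) -> np.ndarray:
    """Shapley values by enumerating all feature subsets (small p only)."""
    phi = np.zeros(p)
    for i in range(p):
        rest = [f for f in range(p) if f != i]
        for r in range(len(rest) + 1):
            for S in combinations(rest, r):
                w = factorial(len(S)) * factorial(p - len(S) - 1) / factorial(p)
                with_i = tree_conditional_expectation(
                    arrays, x, set(S) | {i}, strict=strict
                )
                without = tree_conditional_expectation(arrays, x, set(S), strict=strict)
                phi[i] += w * (with_i - without)
    return phi
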