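"""Independent brute-force reference implementations used only by tests.

These are deliberately naive (two-pass sums, explicit pair enumeration,
exact rational arithmetic) and share no code with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


def pearson_two_pass(x, y):
    """Textbook two-pass Pearson."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)


def average_ranks(x):
    """Fractional ranks with ties averaged, by explicit sorting."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_brute(x, y):
    return pearson_two_pass(average_ranks(list(x)), average_ranks(list(y)))


def kendall_tau_b_brute(x, y):
    """Tau-b by exhaustive pair enumeration with tie corrections."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i, j in combinations(range(n), 2):
        dx = x[i] - x[j]
        dy = y[i] - y[j]
        if dx == 0 and dy == 0:
            ties_x += 1
            ties_y += 1
        elif dx == 0:
            ties_x += 1
        elif dy == 0:
            ties_y += 1
        elif (dx > 0) == (dy > 0):
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        return float("nan")
    return (concordant - discordant) / denom


def hypergeom_upper_tail(N, K, n, k):
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n) via rational arithmetic."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


def hypergeom_pmf_table(N, K, n):
    """Exact pmf over the full support, as Fractions."""
    denom = math.comb(N, n)
    lo = max(0, n - (N - K))
    hi = min(K, n)
    return {
        k: Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
        for k in range(lo, hi + 1)
    }


def duplicate_groups_brute(values, tol):
    """Union-find closure of pairwise near-equality by exhaustive comparison."""
    n = values.shape[1]
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for i, j in combinations(range(n), 2):
        vi, vj = values[:, i], values[:, j]
        scale = np.maximum(np.abs(vi), np.abs(vj))
        if np.all(np.abs(vi - vj) <= tol * scale):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    groups = {}
    for c in range(n):
        groups.setdefault(find(c), []).append(c)
    return sorted([g for g in groups.values() if len(g) >= 2], key=lambda g: g[0])


def replicate_rule_oracle(members, pair_r, r_min):
    """Literal four-case decision rule for 2 and 3 replicates."""
    members = list(members)

    def r_of(a, b):
        v = pair_r[(min(a, b), max(a, b))]
        return -2.0 if (v != v) else v  # NaN counts as below threshold

    if len(members) == 2:
        a, b = members
        if r_of(a, b) >= r_min:
            return members, []
        return [], members
    if len(members) == 3:
        pairs = list(combinations(members, 2))
        passing = [p for p in pairs if r_of(*p) >= r_min]
        if len(passing) == 3:
            return members, []
        if len(passing) == 0:
            return [], members
        best = passing[0]
        for p in passing[1:]:
            if r_of(*p) > r_of(*best):
                best = p
        kept = [m for m in members if m in best]
        return kept, [m for m in members if m not in best]
    raise ValueError("oracle covers 2 and 3 replicates only")
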