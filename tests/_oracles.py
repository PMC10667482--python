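"""Independent brute-force oracles used to verify the fast implementations.

Everything here is written as a direct transcription of the defining formula
(loops, enumeration, closed forms) and deliberately shares no code with the
package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def average_ranks(x):
    x = list(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def rank_normalize_brute(x):
    r = average_ranks(x)
    lo, hi = min(r), max(r)
    if hi == lo:
        return [0.0] * len(r)
    return [(v - lo) / (hi - lo) for v in r]


def bray_curtis_brute(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def kendall_tau_b_brute(x, y):
    conc = disc = tx = ty = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0x = conc + disc + tx
    n0y = conc + disc + ty
    return (conc - disc) / math.sqrt(n0x * n0y)


def pearson_brute(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def spearman_brute(x, y):
    return pearson_brute(average_ranks(x), average_ranks(y))


def shannon_brute(p):
    return -sum(v * math.log(v) for v in p if v > 0)


def simpson_brute(p):
    return 1.0 - sum(v * v for v in p)


def kruskal_h_brute(groups):
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = average_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rs = sum(ranks[start : start + len(g)])
        h += rs * rs / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    corr = 1.0 - tie / (n**3 - n)
    return h / corr if corr > 0 else 0.0


def dunn_z_brute(groups):
    """Pairwise Dunn z statistics, in (i, j) order with i < j."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = average_ranks(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(sum(ranks[start : start + len(g)]) / len(g))
        start += len(g)
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    var_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    zs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(var_base * (1 / len(groups[i]) + 1 / len(groups[j])))
            zs.append((mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0)
    return zs


def mann_whitney_u_brute(a, b):
    """U statistic of sample a (count of (a_i > b_j) pairs + half-ties)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def wilcoxon_exact_p_brute(a, b):
    """Two-sided exact p by enumerating all assignments (tie-free data)."""
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = mann_whitney_u_brute(a, b)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(mann_whitney_u_brute(ga, gb))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def fisher_p_brute(table):
    """Two-sided Fisher exact p: sum of hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyper(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    p_obs = hyper(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hyper(k)
        if pk <= p_obs * (1 + 1e-12):
            total += pk
    return min(total, 1.0)


def bh_brute(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        q[i] = running
    return q


def cohens_d_brute(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    return (ma - mb) / sp
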