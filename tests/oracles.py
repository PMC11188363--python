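"""Naive reference implementations used as independent oracles.

Deliberately plain, loop-based O(N^2) code kept separate from the package:
these implement the textbook definitions as directly as possible and are
the ground truth the fast implementations are compared against.
"""

import math
from itertools import permutations

import numpy as np


def apen_naive(x, m, r_frac):
    x = np.asarray(x, float)
    n = len(x)
    r = r_frac * x.std()
    if x.std() == 0:
        return 0.0

    def phi(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for ti in templates:
            count = 0
            for tj in templates:
                if max(abs(a - b) for a, b in zip(ti, tj)) <= r:
                    count += 1
            total += math.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def saen_naive(x, m, r_frac):
    x = np.asarray(x, float)
    n = len(x)
    r = r_frac * x.std()
    if x.std() == 0:
        return 0.0
    nt = n - m
    tm = [x[i:i + m] for i in range(nt)]
    tm1 = [x[i:i + m + 1] for i in range(nt)]
    B = A = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if max(abs(a - b) for a, b in zip(tm[i], tm[j])) <= r:
                B += 1
            if max(abs(a - b) for a, b in zip(tm1[i], tm1[j])) <= r:
                A += 1
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def peen_naive(x, order, delay, log_base=math.e):
    x = np.asarray(x, float)
    n = len(x) - (order - 1) * delay
    counts = {}
    for i in range(n):
        vec = [x[i + k * delay] for k in range(order)]
        # rank with ties broken by first occurrence
        order_idx = sorted(range(order), key=lambda k: (vec[k], k))
        ranks = tuple(sorted(range(order), key=lambda k: order_idx[k]))
        counts[ranks] = counts.get(ranks, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log(p)
    return h / math.log(log_base)


def bh_stepup_naive(p_values, alpha=None):
    """Step-up adjusted q-values via explicit sort-and-scan."""
    p = list(map(float, p_values))
    n = len(p)
    idx = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = idx[rank - 1]
        val = min(prev, p[i] * n / rank)
        q[i] = val
        prev = val
    return q


def bh_reject_naive(p_values, alpha):
    """The raw BH step-up rejection rule: largest k with p_(k) <= k*alpha/n."""
    p = sorted(map(float, p_values))
    n = len(p)
    k_max = 0
    for k in range(1, n + 1):
        if p[k - 1] <= k * alpha / n:
            k_max = k
    return [pi <= p[k_max - 1] if k_max else False for pi in p_values]


def all_ordinal_patterns(order):
    return list(permutations(range(order)))
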