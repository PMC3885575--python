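"""Independent brute-force oracles used to check the package's numerics.

These deliberately re-derive each quantity from first principles (exhaustive
enumeration, direct counting) and share no code with the implementation.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


def entropy_oracle(column: str) -> float:
    """-sum p ln p over the symbols of one alignment column (X counts as gap)."""
    counts = Counter("-" if c in {"X", "."} else c for c in column)
    n = sum(counts.values())
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def pssm_score_oracle(column: str, residue: str, matrix) -> float:
    """Direct evaluation of sum_k ln(c_k+1)/ln(N+1) * sim(k, residue)."""
    n = len(column)
    counts = Counter(c for c in column if c not in {"-", "X"})
    total = 0.0
    for k, c_k in counts.items():
        w = math.log(c_k + 1) / math.log(n + 1)
        total += w * matrix.score(k, residue)
    return total


def sfunc_oracle(ecs) -> float:
    counts = Counter(".".join(e.split(".")[:3]) for e in ecs)
    n = len(ecs)
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def enum_global_score(a: str, b: str, matrix, gap_open: float = 10, gap_ext: float = 1) -> float:
    """Best global affine-gap score by exhaustive enumeration of alignments.

    A gap of length g costs gap_open + g*gap_ext; end gaps are penalized.
    Exponential -- for sequences of length <= ~7 only.
    """
    best = [float("-inf")]

    def rec(i, j, score, prev):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix.score(a[i], b[j]), "M")
        if i < len(a):
            rec(i + 1, j, score - (gap_ext if prev == "X" else gap_open + gap_ext), "X")
        if j < len(b):
            rec(i, j + 1, score - (gap_ext if prev == "Y" else gap_open + gap_ext), "Y")

    rec(0, 0, 0.0, "")
    return best[0]


def enum_local_score(a: str, b: str, matrix, gap_open: float = 11, gap_ext: float = 1) -> float:
    """Best local affine-gap score: max over all substring pairs, floored at 0."""
    best = 0.0
    for i1 in range(len(a) + 1):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b) + 1):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = enum_global_score(a[i1:i2], b[j1:j2], matrix, gap_open, gap_ext)
                    best = max(best, s)
    return best


def rank_sum_exact_p(group_1, group_2) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments.

    Uses midranks, so it is valid with ties; p = 2*min(P(U<=u), P(U>=u)),
    capped at 1.
    """
    pooled = list(group_1) + list(group_2)
    n1 = len(group_1)
    ranks = _midranks(pooled)
    u_obs = sum(ranks[i] for i in range(n1)) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        us.append(sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2)
    n = len(us)
    p_le = sum(1 for u in us if u <= u_obs + 1e-12) / n
    p_ge = sum(1 for u in us if u >= u_obs - 1e-12) / n
    return min(1.0, 2 * min(p_le, p_ge))


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def paired_t_oracle(a, b):
    """Textbook paired t statistic and two-sided p via the t distribution."""
    from scipy.stats import t as t_dist

    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2 * t_dist.sf(abs(t), df=n - 1)
    return t, p


def best_1d_split_oracle(xs, ys):
    """Information-gain-optimal threshold for a 1-D binary split (midpoints)."""

    def ent(labels):
        n = len(labels)
        out = 0.0
        for c in Counter(labels).values():
            out -= (c / n) * math.log2(c / n)
        return out

    xs_sorted = sorted(set(xs))
    best_gain, best_thr = -1.0, None
    base = ent(ys)
    for lo, hi in zip(xs_sorted, xs_sorted[1:]):
        thr = (lo + hi) / 2
        left = [y for x, y in zip(xs, ys) if x <= thr]
        right = [y for x, y in zip(xs, ys) if x > thr]
        gain = base - (len(left) * ent(left) + len(right) * ent(right)) / len(ys)
        if gain > best_gain:
            best_gain, best_thr = gain, thr
    return best_thr, best_gain
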