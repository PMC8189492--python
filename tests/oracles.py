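"""Independent brute-force oracles for the sequential procedures.

These follow the procedure definitions literally with explicit Python
loops (sort, per-rank multipliers, stop rules, minima over enumerated
thresholds) and are deliberately kept free of the vectorised code paths
in the package, so that agreement is a genuine two-route check.
"""

from __future__ import annotations

import math


def _order(p):
    return sorted(range(len(p)), key=lambda i: p[i])


def holm_oracle(p: list[float]) -> list[float]:
    """Holm step-down adjusted values: rank-k multiplier n-k+1, running max."""
    n = len(p)
    order = _order(p)
    adjusted = [0.0] * n
    running = 0.0
    for k, idx in enumerate(order, start=1):
        value = (n - k + 1) * p[idx]
        running = max(running, value)
        adjusted[idx] = min(1.0, running)
    return adjusted


def hochberg_oracle(p: list[float]) -> list[float]:
    """Hochberg step-up adjusted values: min over tail of (n-j+1) p_(j)."""
    n = len(p)
    order = _order(p)
    adjusted = [0.0] * n
    for k, idx in enumerate(order, start=1):
        tail = [(n - j + 1) * p[order[j - 1]] for j in range(k, n + 1)]
        adjusted[idx] = min(1.0, min(tail))
    return adjusted


def hochberg_variant_oracle(p: list[float]) -> list[float]:
    """Step-up variant: ascending rank k multiplied by k, min over tail."""
    n = len(p)
    order = _order(p)
    adjusted = [0.0] * n
    for k, idx in enumerate(order, start=1):
        tail = [j * p[order[j - 1]] for j in range(k, n + 1)]
        adjusted[idx] = min(1.0, min(tail))
    return adjusted


def bh_adjust_oracle(p: list[float]) -> list[float]:
    """BH adjusted values: min over tail of min(1, (n/j) p_(j))."""
    n = len(p)
    order = _order(p)
    adjusted = [0.0] * n
    for k, idx in enumerate(order, start=1):
        tail = [min(1.0, (n / j) * p[order[j - 1]]) for j in range(k, n + 1)]
        adjusted[idx] = min(tail)
    return adjusted


def bh_reject_oracle(p: list[float], level: float) -> list[bool]:
    """Step-up rejection: highest rank k with p_(k) < (k/n) level; reject 1..k."""
    n = len(p)
    order = _order(p)
    k_star = 0
    for k in range(1, n + 1):
        if p[order[k - 1]] < (k / n) * level:
            k_star = k
    rejected = [False] * n
    for k in range(1, k_star + 1):
        rejected[order[k - 1]] = True
    return rejected


def holm_reject_oracle(p: list[float], alpha: float) -> list[bool]:
    """Sequential Holm stop rule: reject while (n-k+1) p_(k) <= alpha."""
    n = len(p)
    order = _order(p)
    rejected = [False] * n
    for k, idx in enumerate(order, start=1):
        if (n - k + 1) * p[idx] <= alpha:
            rejected[idx] = True
        else:
            break
    return rejected


def hochberg_reject_oracle(p: list[float], alpha: float) -> list[bool]:
    """Step-up stop rule: scan from the largest p down; first rank with
    (n-k+1) p_(k) <= alpha rejects it and everything smaller."""
    n = len(p)
    order = _order(p)
    rejected = [False] * n
    for k in range(n, 0, -1):
        if (n - k + 1) * p[order[k - 1]] <= alpha:
            for j in range(1, k + 1):
                rejected[order[j - 1]] = True
            break
    return rejected


def storey_fdr_oracle(p: list[float], t: float, pi0: float) -> float:
    """pi0 * m * t / S(t), S(t) counted by loop; capped at 1."""
    m = len(p)
    s_t = sum(1 for x in p if x <= t)
    if s_t == 0:
        raise ValueError("S(t) = 0")
    return min(1.0, pi0 * m * t / s_t)


def qvalue_oracle(p: list[float], pi0: float) -> list[float]:
    """q(p_i) = min over observed thresholds t >= p_i of FDR(t)."""
    m = len(p)
    q = []
    for pi in p:
        candidates = []
        for t in p:
            if t >= pi:
                s_t = sum(1 for x in p if x <= t)
                candidates.append(min(1.0, pi0 * m * t / s_t))
        q.append(min(candidates))
    return q


def fwer_oracle(alpha_pc: float, c: int) -> float:
    """1 - (1 - alpha)^c via repeated multiplication."""
    keep = 1.0
    for _ in range(c):
        keep *= 1.0 - alpha_pc
    return 1.0 - keep
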