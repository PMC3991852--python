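"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (scalar loops, explicit
formulas, exhaustive enumeration) and deliberately shares no code path with
the package.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, List, Sequence, Tuple

from scipy import stats


def pearson_oracle(
    x: Sequence[float], y: Sequence[float], ci_level: float = 0.90
) -> Tuple[float, float, float, float]:
    """Direct-formula Pearson r, two-sided t p-value, Fisher-z CI."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        p = 5e-324
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), n - 2)
    z = math.atanh(max(-1 + 1e-15, min(1 - 1e-15, r)))
    half = stats.norm.ppf(0.5 + ci_level / 2) / math.sqrt(n - 3)
    lo, hi = math.tanh(z - half), math.tanh(z + half)
    if abs(r) >= 1.0:
        lo = hi = r
    return r, p, lo, hi


def bh_adjust_oracle(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values by the book."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = pvals[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = min(1.0, running_min)
    return adjusted


def bh_reject_oracle(pvals: Sequence[float], alpha: float) -> List[bool]:
    """BH rejection set: the k* smallest p-values where k* is the largest k
    with p_(k) <= k/m * alpha."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k / m * alpha:
            k_star = k
    rejected = [False] * m
    for k in range(k_star):
        rejected[order[k]] = True
    return rejected


def ks_d_oracle(a: Sequence[float], b: Sequence[float]) -> float:
    """sup |ECDF_a - ECDF_b| by exhaustive evaluation at all sample points."""
    best = 0.0
    for point in list(a) + list(b):
        fa = sum(1 for v in a if v <= point) / len(a)
        fb = sum(1 for v in b if v <= point) / len(b)
        best = max(best, abs(fa - fb))
    return best


def induced_edges_oracle(
    edges: Iterable[Tuple[str, str]], genes: Iterable[str]
) -> int:
    """Number of edges with both endpoints in the gene set, by enumeration."""
    gene_set = set(genes)
    seen = set()
    for u, v in edges:
        if u == v:
            continue
        key = (u, v) if u <= v else (v, u)
        if key in seen:
            continue
        seen.add(key)
    return sum(1 for u, v in seen if u in gene_set and v in gene_set)


def exhaustive_null_oracle(
    edges: Iterable[Tuple[str, str]], universe: Sequence[str], set_size: int
) -> List[float]:
    """Edges-per-gene for every subset of the universe of the given size."""
    edge_list = list(edges)
    out = []
    for combo in itertools.combinations(sorted(universe), set_size):
        out.append(induced_edges_oracle(edge_list, combo) / set_size)
    return out
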