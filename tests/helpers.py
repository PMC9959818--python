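"""Independent oracles used across the test suite.

These deliberately avoid the implementation's code paths: exact integer
combinatorics instead of log-space tails, literal step-up definition
instead of vectorized cumulative minima, full subset enumeration instead
of membership-signature grouping, and Fraction-counted permutation
enumeration for the rank-sum test.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def hypergeom_tail_oracle(k: int, n: int, K: int, N: int) -> float:
    """Brute-force upper tail by exact integer pmf summation."""
    denom = math.comb(N, n)
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return num / denom


def bh_oracle(p) -> list[float]:
    """Literal BH step-up: q_(i) = min_{j >= i} min(1, p_(j) * m / j)."""
    p = [float(v) for v in p]
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos in range(m):
        q[order[pos]] = min(
            min(1.0, p[order[j]] * m / (j + 1)) for j in range(pos, m)
        )
    return q


def ranksum_exact_oracle(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Doubled mid-ranks are integers, so tail counting is exact; the final
    probability is formed in Fractions.
    """
    x, y = list(x), list(y)
    n1, N = len(x), len(x) + len(y)
    ranks2 = np.rint(2 * rankdata(np.asarray(x + y, dtype=float))).astype(np.int64)
    w_obs2 = int(ranks2[:n1].sum())
    combos = np.array(list(combinations(range(N), n1)), dtype=np.intp)
    sums2 = ranks2[combos].sum(axis=1)
    total = math.comb(N, n1)
    le = int(np.count_nonzero(sums2 <= w_obs2))
    ge = int(np.count_nonzero(sums2 >= w_obs2))
    p = 2 * min(Fraction(le, total), Fraction(ge, total))
    return float(min(Fraction(1), p))


def upset_oracle(named_sets: dict) -> dict[frozenset, set]:
    """Exclusive-region membership by brute-force subset enumeration."""
    names = list(named_sets)
    out: dict[frozenset, set] = {}
    for r in range(1, len(names) + 1):
        for sub in combinations(names, r):
            inside = set.intersection(*(set(named_sets[n]) for n in sub))
            rest = [set(named_sets[n]) for n in names if n not in sub]
            outside = set().union(*rest) if rest else set()
            items = inside - outside
            if items:
                out[frozenset(sub)] = items
    return out


def random_network(rng: np.random.Generator, max_edges: int = 50):
    """A random CommunicationNetwork over a small ligand/receptor vocabulary."""
    from exocomm.crossmatch import CommunicationNetwork, Edge

    n_edges = int(rng.integers(0, max_edges + 1))
    pairs = {
        (f"L{int(rng.integers(1, 12))}", f"R{int(rng.integers(1, 12))}")
        for _ in range(n_edges)
    }
    edges = tuple(
        Edge(ligand=l, receptor=r, cell_types=frozenset({"EC"})) for l, r in sorted(pairs)
    )
    return CommunicationNetwork(edges=edges)
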