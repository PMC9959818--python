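"""Gene-set over-representation analysis (ORA) with BH-FDR control.

The model: a universe of N genes contains a term of K genes; a query of n
genes overlaps the term in k genes. Under the null that the query is an
exchangeable draw from the universe, k follows a hypergeometric
distribution and the enrichment p-value is the upper tail P(X >= k).

The tail is evaluated in log space (log-gamma binomial coefficients plus a
running log-sum-exp) so that deeply significant terms do not underflow.
Multiple testing across terms is corrected with the Benjamini–Hochberg
step-up procedure; only terms actually tested (overlap >= 1, size within
bounds) enter the correction, and the output table is filtered at an
adjusted-p cutoff (default 0.05) — the convention used for both the
ligand-side and receptor-side enrichments of the communication pipeline.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = ["hypergeom_upper_tail", "bh_adjust", "enrich", "ENRICHMENT_COLUMNS"]

ENRICHMENT_COLUMNS = [
    "term_id",
    "description",
    "term_size",
    "query_size",
    "overlap_size",
    "overlap_genes",
    "p_raw",
    "p_adj",
]


def _log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper_tail(k, n: int, K: int, N: int):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    Parameters
    ----------
    k : int or array of int
        Observed overlap(s); must satisfy 0 <= k <= min(n, K).
    n : int
        Query size (number of draws).
    K : int
        Term size (successes in the universe).
    N : int
        Universe size.

    Returns a float (or array matching ``k``), always in (0, 1].
    """
    n, K, N = int(n), int(K), int(N)
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts: n={n}, K={K}, N={N}")
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    lo = max(0, n + K - N)
    hi = min(n, K)
    if np.any(k_arr < 0) or np.any(k_arr > hi):
        raise ValueError(f"k out of range [0, {hi}]: {k}")

    i = np.arange(lo, hi + 1, dtype=np.float64)
    log_pmf = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    # tail[j] = logsumexp(log_pmf[j:]) via a reversed running log-add
    tail = np.logaddexp.accumulate(log_pmf[::-1])[::-1]
    p = np.ones(k_arr.shape, dtype=np.float64)
    above = k_arr > lo
    p[above] = np.minimum(1.0, np.exp(tail[k_arr[above] - lo]))
    if np.isscalar(k) or np.asarray(k).ndim == 0:
        return float(p[0])
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving, capped at 1.

    For sorted p-values p_(1) <= ... <= p_(m):
    q_(i) = min_{j >= i} min(1, p_(j) * m / j).
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    np.clip(q, 0.0, 1.0, out=q)
    out = np.empty_like(q)
    out[order] = q
    # q >= p holds mathematically; guard against 1-ulp rounding below p
    return np.maximum(out, p)


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    min_term_size: int = 3,
    max_term_size: int = 2000,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every term of ``collection``.

    The universe defaults to the union of all annotated genes; term genes
    outside the universe are dropped (warned), the query is restricted to
    the universe, and only terms with overlap >= 1 and restricted size in
    ``[min_term_size, max_term_size]`` are tested. BH correction runs over
    the tested terms, the table is filtered to ``p_adj < alpha`` and sorted
    by (p_adj, term_id). Metadata (universe size, number of terms tested)
    lands in ``DataFrame.attrs``.
    """
    universe_set = frozenset(universe) if universe is not None else collection.universe
    if not universe_set:
        raise ValueError("empty universe")
    query_set = frozenset(s.strip() for s in query if s and s.strip())
    outside = len(query_set - universe_set)
    query_set &= universe_set
    if not query_set:
        raise ValueError("query is empty after restriction to the universe")
    if outside:
        log.warning("%d query genes outside the universe dropped", outside)

    n = len(query_set)
    N = len(universe_set)
    rows = []
    dropped_genes = 0
    n_skipped_size = 0
    for term_id, (desc, genes) in collection.terms.items():
        gset = frozenset(genes)
        inside = gset & universe_set
        dropped_genes += len(gset) - len(inside)
        K = len(inside)
        if K < min_term_size or K > max_term_size:
            n_skipped_size += 1
            continue
        overlap = inside & query_set
        if not overlap:
            continue
        rows.append((term_id, desc, K, len(overlap), overlap))
    if dropped_genes:
        log.warning("%d annotated genes outside the universe ignored", dropped_genes)

    if not rows:
        df = pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    else:
        p_raw = np.array(
            [hypergeom_upper_tail(len(ov), n, K, N) for _, _, K, _, ov in rows]
        )
        p_adj = bh_adjust(p_raw)
        df = pd.DataFrame(
            {
                "term_id": [r[0] for r in rows],
                "description": [r[1] for r in rows],
                "term_size": [r[2] for r in rows],
                "query_size": n,
                "overlap_size": [r[3] for r in rows],
                "overlap_genes": [";".join(sorted(r[4])) for r in rows],
                "p_raw": p_raw,
                "p_adj": p_adj,
            }
        )
        df = df[df["p_adj"] < alpha]
        df = df.sort_values(["p_adj", "term_id"], kind="mergesort").reset_index(drop=True)
    df.attrs.update(
        universe_size=N,
        query_size=n,
        n_terms_tested=len(rows),
        n_terms_skipped_size=n_skipped_size,
        alpha=alpha,
    )
    return df
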