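"""Single-cell preprocessing and cluster-marker statistics.

The stages mirror the standard Seurat-style workflow for droplet scRNA-seq:
cell QC on detected-gene counts and mitochondrial UMI fraction, library-size
normalization with log transform, dispersion-based highly-variable-gene
selection, PCA + shared-nearest-neighbor (SNN) graph clustering, marker-based
cluster annotation, and a cluster-versus-rest Wilcoxon rank-sum marker test
with the conventional min.pct / log-fold-change prefilters.

Boundary semantics (fixed here, asserted in tests): a cell is retained iff
min_genes <= detected <= max_genes and mito fraction <= max_mito_fraction
("over X%" removes strictly above X). Cell metrics are computed on the raw
matrix before gene filtering and are not recomputed afterwards.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm as _norm
from scipy.stats import rankdata

from .enrichment import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "MarkerParams",
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "embed_and_cluster",
    "annotate_clusters",
    "find_markers",
    "rank_sum_test",
    "MARKER_COLUMNS",
]

MARKER_COLUMNS = ["cell_type", "gene", "p_raw", "p_adj", "log_fc", "pct_in", "pct_out"]


@dataclass(frozen=True)
class QCThresholds:
    """Cell and gene quality-control thresholds.

    ``max_mito_fraction`` defaults to 0.25 (the neonatal-heart setting);
    adult-heart runs use 0.15.
    """

    min_genes: int = 200
    max_genes: int = 4000
    max_mito_fraction: float = 0.25
    min_cells_per_gene: int = 3
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise ValueError("require 0 < min_genes < max_genes")
        if not (0 < self.max_mito_fraction <= 1):
            raise ValueError("require 0 < max_mito_fraction <= 1")


@dataclass(frozen=True)
class MarkerParams:
    """Parameters of the cluster-versus-rest marker test (Seurat conventions)."""

    min_pct: float = 0.25
    logfc_threshold: float = 0.25
    only_positive: bool = True
    return_thresh: float = 0.05
    pseudocount: float = 1.0
    scale: float = 10_000.0

    def __post_init__(self) -> None:
        if not (0 <= self.min_pct <= 1):
            raise ValueError("min_pct must be in [0, 1]")
        if not (0 < self.return_thresh <= 1):
            raise ValueError("return_thresh must be in (0, 1]")
        if self.logfc_threshold < 0:
            raise ValueError("logfc_threshold must be >= 0")


# ---------------------------------------------------------------------------
# QC


def qc_filter(raw: ad.AnnData, thresholds: QCThresholds = QCThresholds()):
    """Filter cells on detected genes and mito fraction, then rare genes.

    Cell metrics (detected genes; mito fraction = mito UMIs / total UMIs)
    are computed on the raw matrix. Cells failing any rule are removed;
    genes detected in fewer than ``min_cells_per_gene`` of the *remaining*
    cells are then removed. Returns ``(filtered AnnData, QC report dict)``;
    the report lists removed barcodes/genes per rule.
    """
    if raw.n_obs == 0 or raw.n_vars == 0:
        raise ValueError("matrix has zero cells or zero genes")
    X = raw.X if sp.issparse(raw.X) else sp.csr_matrix(raw.X)
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = raw.var_names.str.startswith(thresholds.mito_prefix)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros(raw.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)

    low = detected < thresholds.min_genes
    high = detected > thresholds.max_genes
    mito_bad = mito_frac > thresholds.max_mito_fraction
    keep_cells = ~(low | high | mito_bad)

    kept = raw[keep_cells]
    gene_cells = np.asarray((kept.X > 0).sum(axis=0)).ravel()
    keep_genes = gene_cells >= thresholds.min_cells_per_gene

    obs_names = np.asarray(raw.obs_names)
    report = {
        "n_cells_in": int(raw.n_obs),
        "n_genes_in": int(raw.n_vars),
        "removed_low_genes": [str(b) for b in obs_names[low]],
        "removed_high_genes": [str(b) for b in obs_names[high]],
        "removed_high_mito": [str(b) for b in obs_names[mito_bad]],
        "removed_genes": [str(g) for g in np.asarray(raw.var_names)[~keep_genes]],
        "n_cells_out": int(keep_cells.sum()),
        "n_genes_out": int(keep_genes.sum()),
        "thresholds": {
            "min_genes": thresholds.min_genes,
            "max_genes": thresholds.max_genes,
            "max_mito_fraction": thresholds.max_mito_fraction,
            "min_cells_per_gene": thresholds.min_cells_per_gene,
            "mito_prefix": thresholds.mito_prefix,
        },
    }
    filtered = kept[:, keep_genes].copy()
    return filtered, report


# ---------------------------------------------------------------------------
# normalization / HVG


def normalize_log(counts: ad.AnnData, scale: float = 10_000.0) -> ad.AnnData:
    """Scale each cell to ``scale`` total counts, then natural log1p."""
    if counts.n_obs == 0 or counts.n_vars == 0:
        raise ValueError("matrix has zero cells or zero genes")
    X = counts.X if sp.issparse(counts.X) else sp.csr_matrix(counts.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("cell with zero total counts cannot be normalized")
    X = sp.csr_matrix(X, dtype=np.float64)
    scaling = sp.diags(scale / totals)
    Xn = scaling @ X
    Xn.data = np.log1p(Xn.data)
    out = ad.AnnData(X=Xn, obs=counts.obs.copy(), var=counts.var.copy())
    out.uns["normalization"] = {"scale": scale, "log": "natural log1p"}
    return out


def select_hvg(norm: ad.AnnData, n: int = 2500) -> list[str]:
    """Top-``n`` genes by dispersion (variance / mean of normalized values).

    Zero-mean genes get dispersion 0; ties break lexicographically by symbol.
    """
    if n > norm.n_vars:
        raise ValueError(f"n={n} exceeds gene count {norm.n_vars}")
    X = norm.X if sp.issparse(norm.X) else sp.csr_matrix(norm.X)
    n_obs = norm.n_obs
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n_obs / max(n_obs - 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    order = sorted(range(norm.n_vars), key=lambda i: (-dispersion[i], norm.var_names[i]))
    return [norm.var_names[i] for i in order[:n]]


# ---------------------------------------------------------------------------
# embedding + clustering


def embed_and_cluster(
    norm: ad.AnnData,
    hvg: Sequence[str],
    n_pcs: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
    k: int = 30,
    snn_prune: float = 1.0 / 15.0,
) -> np.ndarray:
    """PCA on the standardized HVG submatrix, SNN graph, Leiden communities.

    The HVG submatrix is z-scored per gene (clipped at ±10), projected onto
    ``n_pcs`` principal components (deterministic full SVD), a k-nearest-
    neighbor graph (k = 30 by default, self included) is re-weighted by
    Jaccard shared-neighbor overlap, edges below ``snn_prune`` are dropped,
    and modularity-based (RB configuration) community detection runs at the
    given resolution with an explicit seed. Returned labels are consecutive
    integers ordered by descending cluster size.
    """
    import igraph as ig
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    missing = [g for g in hvg if g not in norm.var_names]
    if missing:
        raise ValueError(f"HVG not in matrix: {missing[:5]}...")
    if norm.n_obs <= n_pcs:
        raise ValueError(f"need more than n_pcs={n_pcs} cells, got {norm.n_obs}")

    Xh = norm[:, list(hvg)].X
    Xh = Xh.toarray() if sp.issparse(Xh) else np.asarray(Xh)
    mu = Xh.mean(axis=0)
    sd = Xh.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = np.clip((Xh - mu) / sd, -10, 10)

    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(Z)

    k_eff = min(k, norm.n_obs)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    n_cells = norm.n_obs
    rows = np.repeat(np.arange(n_cells), k_eff)
    A = sp.csr_matrix(
        (np.ones(n_cells * k_eff), (rows, idx.ravel())), shape=(n_cells, n_cells)
    )
    shared = (A @ A.T).tocoo()
    with np.errstate(divide="ignore"):
        jac = shared.data / (2 * k_eff - shared.data)
    keep = (jac >= snn_prune) & (shared.row < shared.col)
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    weights = jac[keep].tolist()

    g = ig.Graph(n=n_cells, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # relabel: 0 = largest cluster; ties broken by original label
    uniq, counts = np.unique(labels, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    remap = {uniq[i]: new for new, i in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=np.int64)


def annotate_clusters(
    labels: np.ndarray,
    norm: ad.AnnData,
    canonical_markers: Mapping[str, Sequence[str]],
) -> dict[int, str]:
    """Assign each cluster the cell type whose markers score highest.

    The score of a type in a cluster is the mean normalized expression of
    its canonical marker genes over the cluster's cells. Markers absent
    from the matrix are skipped with a warning; ties go to the
    first-declared type (warned). Raises if no marker of any type is
    present.
    """
    var_index = {g: i for i, g in enumerate(norm.var_names)}
    marker_idx: dict[str, list[int]] = {}
    for ctype, genes in canonical_markers.items():
        present = [var_index[g] for g in genes if g in var_index]
        absent = [g for g in genes if g not in var_index]
        if absent:
            log.warning("markers of %s absent from matrix, skipped: %s", ctype, absent)
        if present:
            marker_idx[ctype] = present
    if not marker_idx:
        raise ValueError("no canonical marker of any cell type is present in the matrix")

    X = norm.X if sp.issparse(norm.X) else sp.csr_matrix(norm.X)
    assignment: dict[int, str] = {}
    declared = list(canonical_markers)
    for cluster in np.unique(labels):
        cells = np.where(labels == cluster)[0]
        scores = {
            ctype: float(X[cells][:, idx].mean()) for ctype, idx in marker_idx.items()
        }
        best = max(scores.values())
        winners = [t for t in declared if t in scores and scores[t] == best]
        if len(winners) > 1:
            log.warning(
                "cluster %d: tie between %s; first-declared %s wins",
                cluster,
                winners,
                winners[0],
            )
        assignment[int(cluster)] = winners[0]
    return assignment


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _ranksum_asymptotic(U: np.ndarray, n1: int, n2: int, tie_term: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation p for Mann-Whitney U with tie and
    continuity corrections."""
    N = n1 + n2
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    d = U - mu
    cc = 0.5 * np.sign(d)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sigma > 0, (d - cc) / np.where(sigma > 0, sigma, 1.0), 0.0)
    p = np.minimum(1.0, 2.0 * _norm.sf(np.abs(z)))
    p[sigma == 0] = 1.0
    return p


def rank_sum_test(x, y, method: str = "asymptotic") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of two samples.

    ``method='asymptotic'`` uses the normal approximation with tie and
    continuity corrections (the production path of ``find_markers``).
    ``method='exact'`` enumerates all C(n1+n2, n1) assignments of the
    pooled values to the first group and reports
    ``min(1, 2 * min(P(W <= w), P(W >= w)))`` — feasible for small groups
    (n1 + n2 <= ~16) and exact under ties.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    if method == "asymptotic":
        W = ranks[:n1].sum()
        U = W - n1 * (n1 + 1) / 2.0
        _, cnt = np.unique(pooled, return_counts=True)
        tie_term = float((cnt.astype(np.float64) ** 3 - cnt).sum())
        return float(_ranksum_asymptotic(np.array([U]), n1, n2, np.array([tie_term]))[0])
    if method == "exact":
        N = n1 + n2
        if math.comb(N, n1) > 500_000:
            raise ValueError("exact enumeration infeasible for these group sizes")
        w_obs = ranks[:n1].sum()
        sums = np.array(
            [ranks[list(c)].sum() for c in itertools.combinations(range(N), n1)]
        )
        eps = 1e-9
        total = len(sums)
        p_le = np.count_nonzero(sums <= w_obs + eps) / total
        p_ge = np.count_nonzero(sums >= w_obs - eps) / total
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    raise ValueError(f"unknown method {method!r}")


def find_markers(
    norm: ad.AnnData,
    cell_types: Sequence[str],
    params: MarkerParams = MarkerParams(),
) -> pd.DataFrame:
    """Cluster-versus-rest Wilcoxon marker detection for every cell type.

    For each type T, genes pass the prefilter when expressed (> 0) in at
    least ``min_pct`` of T's cells or of the rest, and (when
    ``only_positive``) when
    ``log_fc = ln((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1))``
    reaches ``logfc_threshold``. Passing genes get a two-sided rank-sum
    test of T versus all other cells (normal approximation, tie and
    continuity corrections); BH adjustment runs per cell type over the
    tests performed; records are kept when ``p_raw < return_thresh``.

    Cell types with fewer than 3 cells are skipped with a warning; at
    least two usable types are required.
    """
    cell_types = np.asarray(cell_types)
    if len(cell_types) != norm.n_obs:
        raise ValueError("cell_types length must equal number of cells")
    usable = [t for t in pd.unique(cell_types) if (cell_types == t).sum() >= 3]
    skipped = [t for t in pd.unique(cell_types) if t not in usable]
    for t in skipped:
        log.warning("cell type %s has < 3 cells; skipped", t)
    if len(usable) < 2:
        raise ValueError("need at least 2 cell types with >= 3 cells each")

    X = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X, dtype=np.float64)
    expm1 = np.expm1(X)
    genes = np.asarray(norm.var_names)

    frames = []
    for ctype in usable:
        in_mask = cell_types == ctype
        n1 = int(in_mask.sum())
        n2 = int((~in_mask).sum())
        pct_in = (X[in_mask] > 0).mean(axis=0)
        pct_out = (X[~in_mask] > 0).mean(axis=0)
        mean_in = expm1[in_mask].mean(axis=0)
        mean_out = expm1[~in_mask].mean(axis=0)
        log_fc = np.log((mean_in + params.pseudocount) / (mean_out + params.pseudocount))

        passing = (pct_in >= params.min_pct) | (pct_out >= params.min_pct)
        if params.only_positive:
            passing &= log_fc >= params.logfc_threshold
        else:
            passing &= np.abs(log_fc) >= params.logfc_threshold
        cols = np.where(passing)[0]
        if cols.size == 0:
            continue

        ranks = rankdata(X[:, cols], axis=0)
        W = ranks[in_mask].sum(axis=0)
        U = W - n1 * (n1 + 1) / 2.0
        tie_term = np.empty(cols.size)
        for j in range(cols.size):
            _, cnt = np.unique(X[:, cols[j]], return_counts=True)
            tie_term[j] = float((cnt.astype(np.float64) ** 3 - cnt).sum())
        p_raw = _ranksum_asymptotic(U, n1, n2, tie_term)
        p_adj = bh_adjust(p_raw)

        keep = p_raw < params.return_thresh
        frames.append(
            pd.DataFrame(
                {
                    "cell_type": ctype,
                    "gene": genes[cols][keep],
                    "p_raw": p_raw[keep],
                    "p_adj": p_adj[keep],
                    "log_fc": log_fc[cols][keep],
                    "pct_in": pct_in[cols][keep],
                    "pct_out": pct_out[cols][keep],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["cell_type", "p_adj", "gene"], kind="mergesort"
    ).reset_index(drop=True)
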