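"""QC, normalization, HVG, clustering, annotation, and marker statistics."""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import helpers
from exocomm.sc import (
    MarkerParams,
    QCThresholds,
    annotate_clusters,
    embed_and_cluster,
    find_markers,
    normalize_log,
    qc_filter,
    rank_sum_test,
    select_hvg,
)


def make_adata(X, genes=None, barcodes=None):
    X = np.asarray(X, dtype=np.float64)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    barcodes = barcodes or [f"c{i}" for i in range(X.shape[0])]
    return ad.AnnData(
        X=sp.csr_matrix(X),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


class TestQCFilter:
    def _detected_matrix(self):
        # 3 cells over 300 genes: 150 / 250 / 260 detected genes
        X = np.zeros((3, 300))
        X[0, :150] = 1
        X[1, :250] = 1
        X[2, 20:280] = 1
        return make_adata(X)

    def test_low_gene_cell_removed_at_default_floor(self):
        filtered, report = qc_filter(self._detected_matrix(), QCThresholds(min_cells_per_gene=1))
        assert report["removed_low_genes"] == ["c0"]
        assert list(filtered.obs_names) == ["c1", "c2"]

    def test_mito_fraction_boundary_is_strictly_greater(self):
        genes = [f"g{i}" for i in range(210)] + ["mt-1"]
        X = np.zeros((2, 211))
        X[:, :210] = 1  # 210 detected non-mito UMIs
        X[:, 210] = 90  # mito fraction exactly 90/300 = 0.30
        adata = make_adata(X, genes=genes)
        for limit in (0.25, 0.15):  # neonatal / adult limits: 0.30 > limit -> removed
            _, report = qc_filter(
                adata, QCThresholds(min_genes=100, max_mito_fraction=limit, min_cells_per_gene=1)
            )
            assert report["removed_high_mito"] == ["c0", "c1"]
        _, report = qc_filter(  # at the boundary exactly: retained
            adata, QCThresholds(min_genes=100, max_mito_fraction=0.30, min_cells_per_gene=1)
        )
        assert report["removed_high_mito"] == []

    def test_rare_gene_removed_after_cell_filtering(self):
        X = np.ones((5, 250))
        X[0, 0] = 0
        X[1, 0] = 0
        X[2, 0] = 0  # gene g0 detected in only 2 cells
        _, report = qc_filter(make_adata(X), QCThresholds(min_genes=100))
        assert report["removed_genes"] == ["g0"]

    def test_zero_size_matrix_rejected(self):
        with pytest.raises(ValueError):
            qc_filter(make_adata(np.ones((1, 0))), QCThresholds())

    def test_planted_violations_recovered_exactly(self, tiny_bundle):
        cfg = tiny_bundle.config
        for spec in cfg.tissues:
            raw = tiny_bundle.tissues[spec.name]
            thr = QCThresholds(
                min_genes=cfg.qc_min_genes,
                max_genes=cfg.qc_max_genes,
                max_mito_fraction=spec.max_mito_fraction,
                min_cells_per_gene=cfg.min_cells_per_gene,
            )
            _, report = qc_filter(raw, thr)
            truth = tiny_bundle.truth.qc_fail[spec.name]
            assert report["removed_low_genes"] == truth["low_genes"]
            assert report["removed_high_genes"] == truth["high_genes"]
            assert report["removed_high_mito"] == truth["high_mito"]
            assert sorted(report["removed_genes"]) == sorted(tiny_bundle.truth.rare_genes)

    def test_idempotent_on_own_output(self, tiny_bundle):
        thr = QCThresholds(max_mito_fraction=0.25)
        once, _ = qc_filter(tiny_bundle.tissues["neonatal"], thr)
        twice, report = qc_filter(once, thr)
        assert twice.shape == once.shape
        assert report["removed_low_genes"] == []
        assert report["removed_genes"] == []


class TestNormalizeLog:
    def test_hand_computation(self):
        out = normalize_log(make_adata([[5.0, 5.0]]), scale=10)
        np.testing.assert_allclose(out.X.toarray(), np.log(6.0) * np.ones((1, 2)))

    def test_all_zero_gene_stays_zero(self):
        out = normalize_log(make_adata([[5.0, 0.0], [3.0, 0.0]]), scale=10)
        assert np.all(out.X.toarray()[:, 1] == 0)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_log(make_adata([[0.0, 0.0], [1.0, 1.0]]))

    def test_expm1_inversion_recovers_scale(self, tiny_bundle):
        filtered, _ = qc_filter(tiny_bundle.tissues["adult"], QCThresholds(max_mito_fraction=0.15))
        norm = normalize_log(filtered, scale=10_000)
        sums = np.expm1(norm.X.toarray()).sum(axis=1)
        np.testing.assert_allclose(sums, 10_000, rtol=1e-9)


class TestSelectHVG:
    def test_zero_variance_gene_excluded(self, rng):
        X = rng.poisson(5, size=(30, 5)).astype(float)
        X[:, 2] = 3.0  # constant
        hvg = select_hvg(make_adata(X), n=4)
        assert "g2" not in hvg

    def test_full_n_is_identity_set(self, rng):
        adata = make_adata(rng.poisson(3, size=(20, 6)).astype(float))
        assert set(select_hvg(adata, n=6)) == set(adata.var_names)

    def test_n_beyond_gene_count_rejected(self, rng):
        with pytest.raises(ValueError):
            select_hvg(make_adata(rng.poisson(3, size=(10, 4)).astype(float)), n=5)

    def test_planted_markers_selected_at_pipeline_default(self, tiny_bundle):
        # the workflow clamps n_hvg to the gene count on small universes,
        # so every planted marker must end up in the HVG set
        filtered, _ = qc_filter(tiny_bundle.tissues["neonatal"], QCThresholds(max_mito_fraction=0.25))
        norm = normalize_log(filtered)
        hvg = set(select_hvg(norm, n=min(2500, norm.n_vars)))
        planted = {g for gs in tiny_bundle.truth.markers.values() for g in gs}
        assert planted <= hvg


def _blob_adata(rng, sizes=(60, 60)):
    """Two groups with disjoint high-expression gene blocks."""
    n_genes = 40
    rows = []
    for gi, size in enumerate(sizes):
        lam = np.ones(n_genes)
        lam[gi * 10 : gi * 10 + 10] = 25.0
        rows.append(rng.poisson(lam, size=(size, n_genes)))
    X = np.log1p(np.vstack(rows).astype(float))
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return make_adata(X), labels


class TestEmbedAndCluster:
    def test_two_blobs_recovered_exactly(self, rng):
        from sklearn.metrics import adjusted_rand_score

        adata, truth = _blob_adata(rng)
        labels = embed_and_cluster(adata, list(adata.var_names), n_pcs=10, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_same_seed_is_deterministic(self, rng):
        adata, _ = _blob_adata(rng)
        a = embed_and_cluster(adata, list(adata.var_names), n_pcs=10, seed=3)
        b = embed_and_cluster(adata, list(adata.var_names), n_pcs=10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_zero_resolution_limit_is_single_cluster(self, rng):
        X = np.log1p(rng.poisson(5.0, size=(80, 30)).astype(float))
        adata = make_adata(X)
        labels = embed_and_cluster(
            adata, list(adata.var_names), n_pcs=10, resolution=0.0, seed=0
        )
        assert len(set(labels)) == 1

    def test_too_few_cells_rejected(self, rng):
        X = np.log1p(rng.poisson(5.0, size=(15, 30)).astype(float))
        with pytest.raises(ValueError, match="n_pcs"):
            embed_and_cluster(make_adata(X), [f"g{i}" for i in range(30)], n_pcs=20)


class TestAnnotateClusters:
    def _adata(self):
        X = np.zeros((6, 2))
        X[:3, 0] = 3.0  # marker A high in cluster 0
        X[3:, 1] = 0.1  # marker B barely expressed in cluster 1
        return make_adata(X, genes=["A", "B"])

    def test_highest_marker_score_wins(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        result = annotate_clusters(labels, self._adata(), {"FB": ["A"], "EC": ["B"]})
        assert result[0] == "FB"

    def test_tie_goes_to_first_declared_with_warning(self, caplog):
        labels = np.zeros(6, dtype=int)
        with caplog.at_level("WARNING"):
            result = annotate_clusters(labels, self._adata(), {"FB": ["A"], "EC": ["A"]})
        assert result[0] == "FB"
        assert any("tie" in r.message for r in caplog.records)

    def test_absent_markers_skipped_and_all_absent_rejected(self, caplog):
        labels = np.zeros(6, dtype=int)
        with caplog.at_level("WARNING"):
            annotate_clusters(labels, self._adata(), {"FB": ["A", "missing"]})
        assert any("absent" in r.message for r in caplog.records)
        with pytest.raises(ValueError):
            annotate_clusters(labels, self._adata(), {"FB": ["missing"]})

    def test_synthetic_clusters_annotate_to_true_types(self, tiny_bundle, tiny_result):
        for name, tr in tiny_result.tissues.items():
            truth_labels = tiny_bundle.truth.cell_labels[name]
            observed = dict(zip(tr.barcodes, tr.cell_types))
            agree = np.mean([observed[b] == truth_labels[b] for b in observed])
            assert agree == 1.0


class TestRankSum:
    def test_separated_quadruples_match_enumeration(self):
        x, y = [3.0, 3.0, 3.0, 3.0], [0.0, 0.0, 0.0, 0.0]
        p = rank_sum_test(x, y, method="exact")
        assert p == pytest.approx(helpers.ranksum_exact_oracle(x, y), abs=1e-12)
        assert p == pytest.approx(2 / 70, abs=1e-12)

    def test_exact_matches_oracle_on_random_tied_inputs(self, rng):
        for _ in range(40):
            n1, n2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            x = rng.integers(0, 4, size=n1).astype(float)
            y = rng.integers(0, 4, size=n2).astype(float)
            got = rank_sum_test(x, y, method="exact")
            want = helpers.ranksum_exact_oracle(x, y)
            assert got == pytest.approx(want, abs=1e-10)

    def test_asymptotic_matches_scipy_with_ties(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(30):
            x = rng.integers(0, 6, size=25).astype(float)
            y = rng.integers(0, 6, size=30).astype(float)
            got = rank_sum_test(x, y, method="asymptotic")
            want = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert got == pytest.approx(want, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestFindMarkers:
    def _adata(self):
        # 8 cells; gene "up" elevated in group A, "same" identical everywhere
        X = np.zeros((8, 2))
        X[:, 0] = [2.0, 2.1, 2.2, 2.3, 0.0, 0.0, 0.1, 0.0]
        X[:, 1] = 1.0
        return make_adata(X, genes=["up", "same"])

    def test_identical_distribution_gene_not_returned(self):
        types = ["A"] * 4 + ["B"] * 4
        table = find_markers(self._adata(), types, MarkerParams())
        assert "same" not in set(table["gene"])
        assert ("A", "up") in set(zip(table["cell_type"], table["gene"]))

    def test_small_group_skipped_with_warning(self, caplog):
        types = ["A"] * 3 + ["B"] * 3 + ["C"] * 2
        with caplog.at_level("WARNING"):
            table = find_markers(self._adata(), types, MarkerParams())
        assert any("< 3 cells" in r.message for r in caplog.records)
        assert "C" not in set(table["cell_type"])

    def test_fewer_than_two_usable_types_rejected(self):
        with pytest.raises(ValueError):
            find_markers(self._adata(), ["A"] * 6 + ["B"] * 2, MarkerParams())

    def test_marker_table_invariants(self, tiny_result):
        params = MarkerParams()
        for tr in tiny_result.tissues.values():
            t = tr.markers
            assert np.all(t["p_adj"] >= t["p_raw"])
            assert np.all(t["log_fc"] >= params.logfc_threshold)
            assert np.all(np.maximum(t["pct_in"], t["pct_out"]) >= params.min_pct)
            assert np.all(t["p_raw"] < params.return_thresh)

    def test_planted_receptors_are_markers_of_host_type_only(self, tiny_bundle, tiny_result):
        host = tiny_bundle.truth.receptor_host
        for tr in tiny_result.tissues.values():
            recorded = set(zip(tr.markers["cell_type"], tr.markers["gene"]))
            strong = tr.markers[tr.markers["p_adj"] <= 0.01]
            strong_pairs = set(zip(strong["cell_type"], strong["gene"]))
            for receptor, ctype in host.items():
                assert (ctype, receptor) in strong_pairs
                for other in tiny_bundle.truth.cell_types:
                    if other != ctype:
                        assert (other, receptor) not in recorded
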