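"""Ortholog mapping, molecule identification, cross-match, and networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import helpers
from exocomm.crossmatch import (
    CommunicationNetwork,
    Edge,
    LRReference,
    build_network,
    compare_networks,
    crossmatch_terms,
    identify_celltype_receptors,
    identify_exosome_ligands,
    map_orthologs,
    receptor_celltype_contribution,
    receptor_pathway_correlation,
    restrict_to_celltype,
)
from exocomm.io import GeneSetCollection


def _ref(**kw):
    defaults = dict(
        ligands=frozenset({"L1", "L2", "L3"}),
        receptors=frozenset({"R1", "R2"}),
        pairs=frozenset({("L1", "R1"), ("L2", "R2")}),
    )
    defaults.update(kw)
    return LRReference(**defaults)


class TestMapOrthologs:
    def test_simple_case_variant_mapping(self):
        mapped, _ = map_orthologs(["CLU"], {"CLU": ("Clu",)})
        assert mapped == ["Clu"]

    def test_one_to_many_expands_with_report(self):
        mapped, report = map_orthologs(["A"], {"A": ("a1", "a2")})
        assert mapped == ["a1", "a2"]
        assert report["expanded"] == ["A"]

    def test_case_fallback_and_dropping(self):
        mapped, report = map_orthologs(
            ["KDR", "GHOST"], {}, fallback_vocab=["Kdr"], fallback_case_match=True
        )
        assert mapped == ["Kdr"]
        assert report["case_fallback"] == ["KDR"]
        assert report["dropped"] == ["GHOST"]
        mapped, report = map_orthologs(["KDR"], {}, fallback_vocab=["Kdr"], fallback_case_match=False)
        assert mapped == []
        assert report["dropped"] == ["KDR"]

    def test_synthetic_proteome_maps_onto_planted_namespace(self, tiny_bundle):
        truth = tiny_bundle.truth
        vocab = (
            set(tiny_bundle.ref.ligands)
            | set(tiny_bundle.ref.receptors)
            | set(tiny_bundle.collection.universe)
        )
        mapped, report = map_orthologs(
            tiny_bundle.proteome.symbols, tiny_bundle.ref.ortholog_map, fallback_vocab=vocab
        )
        assert set(truth.ligands) <= set(mapped)
        # aliased symbols are recovered through case fallback, not lost
        assert set(report["case_fallback"]) <= set(truth.unmapped_aliases)


class TestIdentify:
    def test_ligand_intersection(self):
        assert identify_exosome_ligands(["L1", "L2", "X"], _ref()) == ["L1", "L2"]

    def test_disjoint_proteome_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert identify_exosome_ligands(["X", "Y"], _ref()) == []
        assert any("no exosome protein" in r.message for r in caplog.records)

    def test_receptor_padj_cutoff(self):
        markers = pd.DataFrame(
            {
                "cell_type": ["EC", "EC", "FB"],
                "gene": ["R1", "R2", "R2"],
                "p_adj": [0.005, 0.02, 0.001],
            }
        )
        result = identify_celltype_receptors(markers, _ref(), padj_max=0.01)
        assert result == {"EC": ["R1"], "FB": ["R2"]}

    def test_receptor_map_matches_ground_truth(self, tiny_bundle, tiny_result):
        expected = {
            t: sorted(rs) for t, rs in tiny_bundle.truth.receptors_by_type.items()
        }
        for tr in tiny_result.tissues.values():
            assert tr.receptors == expected


def _enrich_table(rows):
    return pd.DataFrame(rows, columns=["term_id", "overlap_genes"]).assign(
        description="", term_size=5, query_size=5, overlap_size=2, p_raw=0.001, p_adj=0.01
    )


class TestCrossmatchTerms:
    def test_definition_on_overlapping_tables(self):
        lig = _enrich_table([("T1", "L1;L2"), ("T2", "L2;L3")])
        rec = _enrich_table([("T2", "R1;R2"), ("T3", "R3")])
        result = crossmatch_terms(lig, rec)
        assert result.shared_terms == ("T2",)
        assert result.ligands == ("L2", "L3")
        assert result.receptors == ("R1", "R2")
        assert result.ligand_terms["L2"] == frozenset({"T2"})

    def test_no_shared_terms_is_all_empty(self):
        result = crossmatch_terms(
            _enrich_table([("T1", "L1")]), _enrich_table([("T9", "R1")])
        )
        assert result.shared_terms == ()
        assert result.ligands == () and result.receptors == ()

    def test_empty_table_logs_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            result = crossmatch_terms(_enrich_table([]), _enrich_table([("T1", "R1")]))
        assert result.shared_terms == ()

    def test_recovers_planted_shared_terms_end_to_end(self, tiny_bundle, tiny_result):
        planted = set(tiny_bundle.truth.shared_terms)
        for tr in tiny_result.tissues.values():
            assert set(tr.crossmatch.shared_terms) == planted


class TestBuildNetwork:
    def test_single_pair(self):
        net = build_network(["L1"], {"EC": ["R1"]}, _ref(), source="neo")
        assert len(net) == 1
        edge = net.edges[0]
        assert edge.pair == ("L1", "R1")
        assert edge.cell_types == frozenset({"EC"})
        assert net.sources == frozenset({"neo"})

    def test_participants_without_reference_pair_give_empty_network(self):
        net = build_network(["L3"], {"EC": ["R1"]}, _ref())
        assert len(net) == 0

    def test_every_edge_is_a_reference_pair(self, tiny_bundle, tiny_result):
        for tr in tiny_result.tissues.values():
            assert tr.network.pair_set <= tiny_bundle.ref.pairs

    def test_deterministic_lexicographic_order(self):
        ref = _ref(pairs=frozenset({("L2", "R2"), ("L1", "R1"), ("L1", "R2")}))
        net = build_network(["L2", "L1"], {"EC": ["R2", "R1"]}, ref)
        assert [e.pair for e in net.edges] == [("L1", "R1"), ("L1", "R2"), ("L2", "R2")]


class TestContributionAndRestriction:
    def _network(self):
        return CommunicationNetwork(
            edges=(
                Edge("L1", "R1", frozenset({"EC"})),
                Edge("L1", "R2", frozenset({"EC"})),
                Edge("L2", "R3", frozenset({"FB"})),
            )
        )

    def test_counts_per_cell_type(self):
        assert receptor_celltype_contribution(self._network()) == {"EC": 2, "FB": 1}

    def test_empty_network_is_all_zero(self):
        assert receptor_celltype_contribution(CommunicationNetwork()) == {}

    def test_multihost_receptor_counts_everywhere(self):
        net = CommunicationNetwork(edges=(Edge("L1", "R1", frozenset({"EC", "FB"})),))
        assert receptor_celltype_contribution(net) == {"EC": 1, "FB": 1}

    def test_ec_dominates_default_bundle_contribution(self, default_result):
        contribution = default_result.contribution
        assert max(contribution, key=contribution.get) == "EC"

    def test_restriction_keeps_only_matching_edges(self):
        restricted = restrict_to_celltype(self._network(), "EC")
        assert len(restricted) == 2
        assert restricted.receptors == {"R1", "R2"}
        assert len(restricted) <= len(self._network())

    def test_restriction_to_absent_type_rejected(self):
        with pytest.raises(ValueError, match="MC"):
            restrict_to_celltype(self._network(), "MC")


def _net_from_pairs(pairs):
    return CommunicationNetwork(
        edges=tuple(Edge(l, r, frozenset({"EC"})) for l, r in sorted(pairs))
    )


class TestCompareNetworks:
    def test_two_network_example(self):
        e1, e2, e3 = ("L1", "R1"), ("L2", "R2"), ("L3", "R3")
        report = compare_networks(
            [("A", _net_from_pairs({e1, e2})), ("B", _net_from_pairs({e2, e3}))]
        )
        assert report.regions[frozenset({"A"})] == (e1,)
        assert report.regions[frozenset({"B"})] == (e3,)
        assert report.regions[frozenset({"A", "B"})] == (e2,)
        assert report.consensus.pair_set == {e2}

    def test_identical_networks_intersect_fully(self):
        pairs = {("L1", "R1"), ("L2", "R2")}
        report = compare_networks(
            [("A", _net_from_pairs(pairs)), ("B", _net_from_pairs(pairs))]
        )
        assert dict(report.counts()) == {frozenset({"A", "B"}): 2}
        assert report.consensus.pair_set == pairs

    def test_duplicate_names_rejected(self):
        net = _net_from_pairs({("L1", "R1")})
        with pytest.raises(ValueError, match="duplicate"):
            compare_networks([("A", net), ("A", net)])

    def test_matches_bruteforce_subset_enumeration(self, rng):
        for _ in range(30):
            k = int(rng.integers(2, 5))
            nets = {f"N{i}": helpers.random_network(rng) for i in range(k)}
            report = compare_networks(list(nets.items()))
            oracle = helpers.upset_oracle({n: net.pair_set for n, net in nets.items()})
            got = {k_: set(v) for k_, v in report.regions.items()}
            assert got == oracle
            union = set().union(*(net.pair_set for net in nets.values()))
            assert sum(len(v) for v in report.regions.values()) == len(union)


class TestReceptorPathwayCorrelation:
    def _adata(self, X, genes):
        import anndata as ad
        import scipy.sparse as sp

        return ad.AnnData(
            X=sp.csr_matrix(np.asarray(X, dtype=float)),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(len(X))]),
            var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        )

    def test_receptor_equal_to_term_score_gives_r_one(self, rng):
        v = rng.normal(size=30)
        X = np.column_stack([v, v, v])  # receptor == every member
        adata = self._adata(X, ["rec", "m1", "m2"])
        coll = GeneSetCollection({"T1": ("d", ("m1", "m2", "rec"))})
        table = receptor_pathway_correlation(
            adata, np.arange(30), ["rec"], ["T1"], coll
        )
        assert table.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert not table.loc[0, "undefined"]

    def test_constant_receptor_flagged_undefined(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20), rng.normal(size=20)])
        adata = self._adata(X, ["rec", "m1", "m2"])
        coll = GeneSetCollection({"T1": ("d", ("m1", "m2"))})
        table = receptor_pathway_correlation(adata, np.arange(20), ["rec"], ["T1"], coll)
        assert bool(table.loc[0, "undefined"])
        assert np.isnan(table.loc[0, "pearson_r"])

    def test_planted_coexpression_program_stands_out(self, rng):
        n_cells, n_noise_terms = 80, 20
        z = rng.normal(size=n_cells)
        program = [f"p{i}" for i in range(6)]
        noise_genes = [f"n{i}" for i in range(60)]
        X = np.column_stack(
            [z + 0.3 * rng.normal(size=n_cells)]
            + [z + 0.5 * rng.normal(size=n_cells) for _ in program]
            + [rng.normal(size=n_cells) for _ in noise_genes]
        )
        adata = self._adata(X, ["rec"] + program + noise_genes)
        terms = {"PROG": ("d", tuple(program))}
        for i in range(n_noise_terms):
            picks = rng.choice(60, size=6, replace=False)
            terms[f"RAND{i}"] = ("d", tuple(noise_genes[j] for j in picks))
        coll = GeneSetCollection(terms)
        table = receptor_pathway_correlation(
            adata, np.arange(n_cells), ["rec"], list(terms), coll
        ).set_index("term_id")
        r_prog = table.loc["PROG", "pearson_r"]
        r_noise = table.drop(index="PROG")["pearson_r"].to_numpy(dtype=float)
        assert r_prog > np.quantile(r_noise, 0.95)


class TestLRReferenceValidation:
    def test_pair_with_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="not in ligand set"):
            LRReference(
                ligands=frozenset({"L1"}),
                receptors=frozenset({"R1"}),
                pairs=frozenset({("LX", "R1")}),
            )
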