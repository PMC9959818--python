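"""Exosome→tissue communication-network inference by GO-term cross-matching.

The core procedure: exosomal proteins are mapped into the tissue species'
gene namespace and intersected with a curated ligand set; per-cell-type
marker genes (adjusted p <= 0.01) are intersected with the receptor set;
both gene lists are tested for GO biological-process over-representation;
the *shared* enriched terms define which ligands and receptors participate
in the communication network; and participating molecules are paired via
the curated directed ligand→receptor interaction table. Networks built for
several conditions are compared by UpSet-style exclusive intersections,
with the full k-way intersection serving as the consensus network.

Edge identity for intersection is the (ligand, receptor) pair — cell types
are merged metadata. An edge's supporting terms are the shared terms whose
ligand-side overlap contains its ligand.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import GeneSetCollection, ProteinList

log = logging.getLogger(__name__)

__all__ = [
    "LRReference",
    "Edge",
    "CommunicationNetwork",
    "CrossMatchResult",
    "ComparisonReport",
    "map_orthologs",
    "identify_exosome_ligands",
    "identify_celltype_receptors",
    "crossmatch_terms",
    "build_network",
    "receptor_celltype_contribution",
    "restrict_to_celltype",
    "compare_networks",
    "receptor_pathway_correlation",
]


@dataclass(frozen=True)
class LRReference:
    """Curated ligand/receptor sets, directed L→R pairs, and an ortholog map."""

    ligands: frozenset[str]
    receptors: frozenset[str]
    pairs: frozenset[tuple[str, str]]
    ortholog_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lig, rec in self.pairs:
            if lig not in self.ligands:
                raise ValueError(f"pair ligand {lig!r} not in ligand set")
            if rec not in self.receptors:
                raise ValueError(f"pair receptor {rec!r} not in receptor set")

    @classmethod
    def from_tables(
        cls,
        ligands: pd.DataFrame,
        receptors: pd.DataFrame,
        pairs: pd.DataFrame,
        orthologs: pd.DataFrame | None = None,
    ) -> "LRReference":
        """Build from the TSV tables (columns: ligand / receptor / source,target)."""
        omap: dict[str, tuple[str, ...]] = {}
        if orthologs is not None:
            for src, grp in orthologs.groupby("source", sort=False):
                omap[str(src)] = tuple(dict.fromkeys(grp["target"].astype(str)))
        return cls(
            ligands=frozenset(ligands["ligand"].astype(str)),
            receptors=frozenset(receptors["receptor"].astype(str)),
            pairs=frozenset(
                (str(l), str(r)) for l, r in zip(pairs["ligand"], pairs["receptor"])
            ),
            ortholog_map=omap,
        )


@dataclass(frozen=True, order=True)
class Edge:
    """A directed ligand → receptor edge with its provenance."""

    ligand: str
    receptor: str
    cell_types: frozenset[str] = frozenset()
    shared_terms: frozenset[str] = frozenset()
    sources: frozenset[str] = frozenset()

    @property
    def pair(self) -> tuple[str, str]:
        return (self.ligand, self.receptor)


@dataclass(frozen=True)
class CommunicationNetwork:
    """A set of ligand → receptor edges; participants derive from the edges."""

    edges: tuple[Edge, ...] = ()

    @property
    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(e.pair for e in self.edges)

    @property
    def ligands(self) -> frozenset[str]:
        return frozenset(e.ligand for e in self.edges)

    @property
    def receptors(self) -> frozenset[str]:
        return frozenset(e.receptor for e in self.edges)

    @property
    def cell_types(self) -> frozenset[str]:
        return frozenset(t for e in self.edges for t in e.cell_types)

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(s for e in self.edges for s in e.sources)

    def receptor_cell_types(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for e in self.edges:
            out.setdefault(e.receptor, set()).update(e.cell_types)
        return {r: frozenset(ts) for r, ts in out.items()}

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# ortholog mapping and molecule identification


def map_orthologs(
    symbols: Iterable[str],
    ortholog_map: Mapping[str, Sequence[str]],
    fallback_vocab: Iterable[str] | None = None,
    fallback_case_match: bool = True,
) -> tuple[list[str], dict]:
    """Map symbols across species via an ortholog table.

    One-to-many entries expand to all targets. Symbols missing from the
    table are, when ``fallback_case_match`` is on, matched case-
    insensitively against ``fallback_vocab`` (e.g. the reference +
    annotation namespace); otherwise they are dropped. Returns the mapped
    symbols (order of first appearance, deduplicated) and a report listing
    expanded, fallback-matched and dropped symbols.
    """
    symbols = list(symbols)
    vocab_by_case: dict[str, str] = {}
    if fallback_case_match and fallback_vocab is not None:
        for v in fallback_vocab:
            vocab_by_case.setdefault(v.casefold(), v)

    mapped: dict[str, None] = {}
    expanded, fell_back, dropped = [], [], []
    for s in symbols:
        if s in ortholog_map:
            targets = tuple(ortholog_map[s])
            if len(targets) > 1:
                expanded.append(s)
            for t in targets:
                mapped.setdefault(t)
        elif fallback_case_match and s.casefold() in vocab_by_case:
            fell_back.append(s)
            mapped.setdefault(vocab_by_case[s.casefold()])
        else:
            dropped.append(s)
    if dropped:
        log.warning("%d symbols could not be mapped and were dropped", len(dropped))
    report = {
        "n_input": len(symbols),
        "n_mapped": len(mapped),
        "expanded": expanded,
        "case_fallback": fell_back,
        "dropped": dropped,
    }
    return list(mapped), report


def identify_exosome_ligands(
    proteome: ProteinList | Iterable[str], ref: LRReference
) -> list[str]:
    """Intersect the (namespace-mapped) exosome proteome with the ligand set."""
    symbols = proteome.symbols if isinstance(proteome, ProteinList) else tuple(proteome)
    result = sorted(set(symbols) & ref.ligands)
    if not result:
        log.warning("no exosome protein matched the ligand reference")
    return result


def identify_celltype_receptors(
    markers: pd.DataFrame, ref: LRReference, padj_max: float = 0.01
) -> dict[str, list[str]]:
    """Per cell type: marker genes with p_adj <= ``padj_max`` that are receptors.

    A receptor may appear for multiple cell types. Cell types with no
    receptor are omitted from the result.
    """
    out: dict[str, list[str]] = {}
    if len(markers) == 0:
        return out
    sig = markers[markers["p_adj"].astype(float) <= padj_max]
    for ctype, grp in sig.groupby("cell_type", sort=True):
        recs = sorted(set(grp["gene"].astype(str)) & ref.receptors)
        if recs:
            out[str(ctype)] = recs
    return out


# ---------------------------------------------------------------------------
# term cross-match and network construction


@dataclass(frozen=True)
class CrossMatchResult:
    shared_terms: tuple[str, ...]
    ligands: tuple[str, ...]
    receptors: tuple[str, ...]
    ligand_terms: Mapping[str, frozenset[str]]  # ligand -> shared terms containing it
    receptor_terms: Mapping[str, frozenset[str]]


def _overlap_map(table: pd.DataFrame, terms: Iterable[str]) -> dict[str, frozenset[str]]:
    gene_terms: dict[str, set[str]] = {}
    wanted = set(terms)
    for _, row in table.iterrows():
        if row["term_id"] not in wanted:
            continue
        for g in str(row["overlap_genes"]).split(";"):
            if g:
                gene_terms.setdefault(g, set()).add(row["term_id"])
    return {g: frozenset(ts) for g, ts in gene_terms.items()}


def crossmatch_terms(
    ligand_enrich: pd.DataFrame, receptor_enrich: pd.DataFrame
) -> CrossMatchResult:
    """Intersect ligand-side and receptor-side enriched terms.

    Shared terms are the term-id intersection of the two (already
    alpha-filtered) tables; participating ligands/receptors are the unions
    of the respective overlap genes across the shared terms.
    """
    if len(ligand_enrich) == 0 or len(receptor_enrich) == 0:
        log.warning("one enrichment table is empty; cross-match result is empty")
        return CrossMatchResult((), (), (), {}, {})
    shared = sorted(
        set(ligand_enrich["term_id"]) & set(receptor_enrich["term_id"])
    )
    lig_terms = _overlap_map(ligand_enrich, shared)
    rec_terms = _overlap_map(receptor_enrich, shared)
    return CrossMatchResult(
        shared_terms=tuple(shared),
        ligands=tuple(sorted(lig_terms)),
        receptors=tuple(sorted(rec_terms)),
        ligand_terms=lig_terms,
        receptor_terms=rec_terms,
    )


def build_network(
    participating_ligands: Iterable[str],
    celltype_receptors: Mapping[str, Sequence[str]],
    ref: LRReference,
    source: str = "",
    ligand_terms: Mapping[str, frozenset[str]] | None = None,
) -> CommunicationNetwork:
    """Pair participating ligands with participating receptors via the reference.

    Edges are the reference pairs whose ligand is a participant and whose
    receptor appears in ``celltype_receptors`` (restricted beforehand to
    participating receptors). Each edge carries the receptor's host cell
    types and, when ``ligand_terms`` is given, the shared terms that
    admitted its ligand. Edge order is (ligand, receptor) lexicographic.
    """
    lig_set = frozenset(participating_ligands)
    rec_hosts: dict[str, set[str]] = {}
    for ctype, recs in celltype_receptors.items():
        for r in recs:
            rec_hosts.setdefault(r, set()).add(ctype)
    sources = frozenset([source]) if source else frozenset()
    edges = []
    for lig, rec in sorted(ref.pairs):
        if lig in lig_set and rec in rec_hosts:
            edges.append(
                Edge(
                    ligand=lig,
                    receptor=rec,
                    cell_types=frozenset(rec_hosts[rec]),
                    shared_terms=(ligand_terms or {}).get(lig, frozenset()),
                    sources=sources,
                )
            )
    return CommunicationNetwork(edges=tuple(edges))


def receptor_celltype_contribution(network: CommunicationNetwork) -> dict[str, int]:
    """Count the network's receptor genes attributed to each cell type.

    A receptor hosted by k cell types contributes to each of the k.
    """
    counts: dict[str, int] = {t: 0 for t in sorted(network.cell_types)}
    for receptor, types in network.receptor_cell_types().items():
        for t in types:
            counts[t] += 1
    return counts


def restrict_to_celltype(network: CommunicationNetwork, cell_type: str) -> CommunicationNetwork:
    """Keep only edges whose receptor is hosted by ``cell_type``."""
    if cell_type not in network.cell_types:
        raise ValueError(
            f"cell type {cell_type!r} not present in network "
            f"(has {sorted(network.cell_types)})"
        )
    edges = tuple(e for e in network.edges if cell_type in e.cell_types)
    return CommunicationNetwork(edges=edges)


# ---------------------------------------------------------------------------
# multi-network comparison (UpSet semantics)


@dataclass(frozen=True)
class ComparisonReport:
    """Exclusive-intersection regions over named networks plus the consensus.

    ``regions`` maps each nonempty subset of names to the (ligand,
    receptor) pairs found in exactly those networks and no other.
    ``consensus`` is the full k-way intersection as a derived network with
    merged cell types and the union of source labels.
    """

    names: tuple[str, ...]
    regions: Mapping[frozenset[str], tuple[tuple[str, str], ...]]
    consensus: CommunicationNetwork

    def counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.regions.items()}


def compare_networks(
    networks: Mapping[str, CommunicationNetwork] | Sequence[tuple[str, CommunicationNetwork]],
) -> ComparisonReport:
    """UpSet-style comparison of >= 2 named networks.

    Edge identity is the (ligand, receptor) pair; cell types and
    supporting terms are merged metadata on the consensus edges.
    """
    items = list(networks.items()) if isinstance(networks, Mapping) else list(networks)
    names = [n for n, _ in items]
    if len(names) != len(set(names)):
        raise ValueError("duplicate network names")
    if len(items) < 2:
        raise ValueError("need at least 2 networks to compare")

    membership: dict[tuple[str, str], set[str]] = {}
    edge_lookup: dict[tuple[str, str], list[Edge]] = {}
    for name, net in items:
        for e in net.edges:
            membership.setdefault(e.pair, set()).add(name)
            edge_lookup.setdefault(e.pair, []).append(e)

    regions: dict[frozenset[str], list[tuple[str, str]]] = {}
    for pair, present in membership.items():
        regions.setdefault(frozenset(present), []).append(pair)

    all_names = frozenset(names)
    consensus_pairs = sorted(regions.get(all_names, []))
    consensus_edges = tuple(
        Edge(
            ligand=lig,
            receptor=rec,
            cell_types=frozenset(
                t for e in edge_lookup[(lig, rec)] for t in e.cell_types
            ),
            shared_terms=frozenset(
                t for e in edge_lookup[(lig, rec)] for t in e.shared_terms
            ),
            sources=all_names,
        )
        for lig, rec in consensus_pairs
    )
    return ComparisonReport(
        names=tuple(names),
        regions={k: tuple(sorted(v)) for k, v in regions.items()},
        consensus=CommunicationNetwork(edges=consensus_edges),
    )


# ---------------------------------------------------------------------------
# exploratory receptor-pathway correlation


def receptor_pathway_correlation(
    norm: ad.AnnData,
    cells: np.ndarray,
    receptors: Sequence[str],
    terms: Sequence[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Pearson correlation of receptor expression with pathway scores.

    For each (receptor, term): across the given cells (boolean mask or
    index array), correlate the receptor's normalized expression with the
    term's score (mean normalized expression of its member genes present in
    the matrix, excluding the receptor itself). Constant vectors yield an
    undefined correlation (NaN, flagged). Exploratory output — the exact
    construction is a documented package choice.
    """
    X = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X, dtype=np.float64)
    X = X[np.asarray(cells)]
    var_index = {g: i for i, g in enumerate(norm.var_names)}
    rows = []
    for rec in receptors:
        if rec not in var_index:
            log.warning("receptor %s not in matrix; skipped", rec)
            continue
        rec_expr = X[:, var_index[rec]]
        for term in terms:
            members = [
                var_index[g]
                for g in collection.gene_set(term)
                if g in var_index and g != rec
            ]
            if not members:
                rows.append((rec, term, np.nan, True))
                continue
            score = X[:, members].mean(axis=1)
            if np.std(rec_expr) == 0 or np.std(score) == 0:
                rows.append((rec, term, np.nan, True))
                continue
            r = float(np.corrcoef(rec_expr, score)[0, 1])
            rows.append((rec, term, r, False))
    return pd.DataFrame(rows, columns=["receptor", "term_id", "pearson_r", "undefined"])
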