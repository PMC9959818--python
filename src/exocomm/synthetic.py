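"""Synthetic fixture bundles with planted, fully recorded ground truth.

The generator emulates the statistical shape of the study inputs — an
exosome proteome (a flat symbol list in the "human" namespace), two tissue
scRNA-seq count matrices with distinct cell-type compositions, a curated
ligand/receptor/pair reference with an ortholog map, and a GO-BP-style
annotation — while planting every signal the downstream pipeline is meant
to recover:

* negative-binomial counts (mean/dispersion parameterization), with
  cell-type marker genes (including all planted receptors) up-regulated by
  ``marker_fold`` in their host type;
* mitochondrial genes (``mt-`` prefix, elevated baseline mean) and cells
  explicitly constructed to violate each QC rule;
* planted exosomal ligands carried by the proteome, decoy ligands/receptors
  carried only by the reference, and planted directed L→R pairs;
* shared GO terms that contain enough planted ligands *and* planted
  receptors of a single cell type that both sides enrich, so the
  term cross-match recovers exactly the planted communication network.

Species namespaces are simulated by case convention: "human" symbols are
upper-case, "mouse" symbols capitalized, linked by an explicit ortholog
table (minus a configurable alias fraction that exercises case-fallback
matching).

Every generated structure is recorded in :class:`GroundTruth`, and a fixed
seed regenerates a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .crossmatch import LRReference
from .io import (
    GeneSetCollection,
    ProteinList,
    write_counts_mtx,
    write_gmt,
    write_protein_list,
    write_table,
)

log = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "TissueSpec",
    "SyntheticConfig",
    "GroundTruth",
    "Bundle",
    "generate_lr_reference",
    "generate_go_annotation",
    "generate_tissue_counts",
    "generate_exosome_proteome",
    "generate_bundle",
]


class ConfigurationError(ValueError):
    """Inconsistent synthetic-data configuration."""


@dataclass(frozen=True)
class TissueSpec:
    """One tissue: its name, cells per cell type, and its mito QC threshold."""

    name: str
    cells_per_type: Mapping[str, int]
    max_mito_fraction: float = 0.25


def _default_tissues() -> tuple[TissueSpec, ...]:
    return (
        TissueSpec("neonatal", {"EC": 480, "FB": 400, "MAC": 320}, max_mito_fraction=0.25),
        TissueSpec("adult", {"EC": 320, "FB": 480, "MAC": 400}, max_mito_fraction=0.15),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic bundle (defaults are the test bed).

    ``nb_mean``/``nb_dispersion`` parameterize baseline negative-binomial
    counts (variance = mu + mu^2/dispersion); ``marker_fold`` multiplies the
    mean of a planted marker in its host cell type (fold units, >= 1;
    default 4). ``qc_*_fraction`` are the fractions of cells synthesized to
    violate each QC rule; planted high-gene violators require
    ``n_genes > qc_max_genes``.
    """

    seed: int = 7
    n_genes: int = 2000
    n_mito_genes: int = 13
    tissues: tuple[TissueSpec, ...] = field(default_factory=_default_tissues)
    markers_per_type: int = 30
    planted_ligands: int = 30
    planted_receptors: int = 24
    planted_pairs: int = 40
    decoy_ligands: int = 20
    decoy_receptors: int = 20
    decoy_pairs: int = 30
    background_proteins: int = 70
    proteome_decoy_ligands: int = 0
    n_go_terms: int = 40
    genes_per_term: tuple[int, int] = (20, 60)
    shared_terms: int = 6
    ligands_per_shared_term: int = 10
    receptors_per_shared_term: int = 8
    nb_mean: float = 0.5
    nb_dispersion: float = 2.0
    mito_mean_factor: float = 8.0
    marker_fold: float = 4.0
    qc_low_gene_fraction: float = 0.01
    qc_high_gene_fraction: float = 0.0
    qc_high_mito_fraction: float = 0.01
    qc_min_genes: int = 200
    qc_max_genes: int = 4000
    n_rare_genes: int = 2
    min_cells_per_gene: int = 3
    ortholog_alias_fraction: float = 0.1

    @property
    def cell_types(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.tissues:
            for c in t.cells_per_type:
                seen.setdefault(c)
        return tuple(seen)

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_mito_genes": self.n_mito_genes,
            "markers_per_type": self.markers_per_type,
            "planted_ligands": self.planted_ligands,
            "planted_receptors": self.planted_receptors,
            "planted_pairs": self.planted_pairs,
            "decoy_ligands": self.decoy_ligands,
            "decoy_receptors": self.decoy_receptors,
            "decoy_pairs": self.decoy_pairs,
            "background_proteins": self.background_proteins,
            "n_go_terms": self.n_go_terms,
            "shared_terms": self.shared_terms,
            "n_rare_genes": self.n_rare_genes,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        if not self.tissues:
            raise ConfigurationError("at least one tissue required")
        for t in self.tissues:
            if not t.cells_per_type:
                raise ConfigurationError(f"tissue {t.name!r} has zero cell types")
        if self.planted_pairs > self.planted_ligands * self.planted_receptors:
            raise ConfigurationError("planted_pairs exceeds ligand x receptor product")
        if self.decoy_pairs > self.decoy_ligands * self.decoy_receptors:
            raise ConfigurationError("decoy_pairs exceeds decoy product")
        if self.shared_terms > self.n_go_terms:
            raise ConfigurationError("shared_terms exceeds n_go_terms")
        if self.marker_fold < 1:
            raise ConfigurationError("marker_fold must be >= 1")
        if self.genes_per_term[0] < 1 or self.genes_per_term[0] > self.genes_per_term[1]:
            raise ConfigurationError("invalid genes_per_term range")
        n_types = len(self.cell_types)
        needed = n_types * self.markers_per_type + self.decoy_receptors + self.n_rare_genes
        if needed > self.n_genes:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small for {needed} special genes"
            )
        if self.planted_receptors > n_types * self.markers_per_type:
            raise ConfigurationError("planted_receptors exceed total marker slots")
        if self.shared_terms and self.planted_receptors < 3 * n_types:
            raise ConfigurationError(
                "shared terms need >= 3 planted receptors per cell type"
            )
        if self.shared_terms and self.planted_ligands < 3:
            raise ConfigurationError("need >= 3 planted ligands for shared terms")
        if self.shared_terms and self.receptors_per_shared_term < 3:
            raise ConfigurationError("receptors_per_shared_term must be >= 3")
        if self.qc_high_gene_fraction > 0 and self.n_genes - self.n_rare_genes <= self.qc_max_genes:
            raise ConfigurationError(
                "planting high-gene QC violators requires n_genes > qc_max_genes"
            )


@dataclass
class GroundTruth:
    """Everything planted, directly checkable against the emitted files."""

    matrix_genes: list[str] = field(default_factory=list)
    mito_genes: list[str] = field(default_factory=list)
    cell_types: list[str] = field(default_factory=list)
    markers: dict[str, list[str]] = field(default_factory=dict)
    receptors_by_type: dict[str, list[str]] = field(default_factory=dict)
    ligands: list[str] = field(default_factory=list)
    ligands_human: list[str] = field(default_factory=list)
    decoy_ligands: list[str] = field(default_factory=list)
    decoy_receptors: list[str] = field(default_factory=list)
    background_proteins: list[str] = field(default_factory=list)
    pairs: list[tuple[str, str]] = field(default_factory=list)
    decoy_pairs: list[tuple[str, str]] = field(default_factory=list)
    shared_terms: dict[str, dict] = field(default_factory=dict)
    unmapped_aliases: list[str] = field(default_factory=list)
    rare_genes: list[str] = field(default_factory=list)
    cell_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    qc_fail: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    rare_gene_cells: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    @property
    def all_receptors(self) -> list[str]:
        return sorted(r for rs in self.receptors_by_type.values() for r in rs)

    @property
    def receptor_host(self) -> dict[str, str]:
        return {r: t for t, rs in self.receptors_by_type.items() for r in rs}

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["pairs"] = [list(p) for p in self.pairs]
        payload["decoy_pairs"] = [list(p) for p in self.decoy_pairs]
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        payload["pairs"] = [tuple(p) for p in payload["pairs"]]
        payload["decoy_pairs"] = [tuple(p) for p in payload["decoy_pairs"]]
        return cls(**payload)


def _mouse(symbol: str) -> str:
    return symbol.capitalize()


def _human(symbol: str) -> str:
    return symbol.upper()


# ---------------------------------------------------------------------------
# L-R reference


def _allocate(total: int, n_bins: int, minimum: int = 0) -> list[int]:
    """Largest-remainder allocation with descending weights n_bins..1,
    after granting each bin ``minimum``."""
    if total < minimum * n_bins:
        raise ConfigurationError(
            f"cannot allocate {total} items with minimum {minimum} over {n_bins} bins"
        )
    rest = total - minimum * n_bins
    weights = np.arange(n_bins, 0, -1, dtype=float)
    weights /= weights.sum()
    base = np.floor(weights * rest).astype(int)
    rem = rest - base.sum()
    frac_order = np.argsort(-(weights * rest - base), kind="stable")
    for i in range(rem):
        base[frac_order[i % n_bins]] += 1
    return (base + minimum).tolist()


def generate_lr_reference(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[LRReference, GroundTruth]:
    """Generate the ligand/receptor/pair reference and start the ground truth.

    Also fixes the matrix gene universe and gene roles (markers, planted
    receptors hosted by exactly one cell type, decoy receptors, rare
    genes), because planted receptors *are* matrix genes. The ortholog map
    covers every proteome-namespace symbol except a random
    ``ortholog_alias_fraction`` left to case-fallback matching.
    """
    config.validate()
    truth = GroundTruth()
    cell_types = list(config.cell_types)
    truth.cell_types = cell_types

    genes = [f"Gene{i + 1:04d}" for i in range(config.n_genes)]
    mito = [f"mt-Gene{i + 1:02d}" for i in range(config.n_mito_genes)]
    truth.matrix_genes = genes + mito
    truth.mito_genes = mito

    perm = rng.permutation(config.n_genes)
    cursor = 0

    receptor_counts = _allocate(
        config.planted_receptors,
        len(cell_types),
        minimum=3 if config.shared_terms else 0,
    )
    for ctype, n_rec in zip(cell_types, receptor_counts):
        block = [genes[i] for i in perm[cursor : cursor + config.markers_per_type]]
        cursor += config.markers_per_type
        truth.markers[ctype] = block
        truth.receptors_by_type[ctype] = block[:n_rec]

    truth.decoy_receptors = [
        genes[i] for i in perm[cursor : cursor + config.decoy_receptors]
    ]
    cursor += config.decoy_receptors
    truth.rare_genes = [genes[i] for i in perm[cursor : cursor + config.n_rare_genes]]
    cursor += config.n_rare_genes

    truth.ligands = [f"Lig{i + 1:04d}" for i in range(config.planted_ligands)]
    truth.ligands_human = [_human(s) for s in truth.ligands]
    truth.decoy_ligands = [f"Dlg{i + 1:04d}" for i in range(config.decoy_ligands)]
    truth.background_proteins = [
        f"Bkg{i + 1:04d}" for i in range(config.background_proteins)
    ]

    receptors_all = [r for t in cell_types for r in truth.receptors_by_type[t]]
    pair_idx = rng.choice(
        config.planted_ligands * len(receptors_all) or 1,
        size=config.planted_pairs,
        replace=False,
    ) if config.planted_pairs else np.array([], dtype=int)
    truth.pairs = sorted(
        (truth.ligands[i // len(receptors_all)], receptors_all[i % len(receptors_all)])
        for i in pair_idx
    )
    if config.decoy_pairs:
        didx = rng.choice(
            config.decoy_ligands * config.decoy_receptors,
            size=config.decoy_pairs,
            replace=False,
        )
        truth.decoy_pairs = sorted(
            (
                truth.decoy_ligands[i // config.decoy_receptors],
                truth.decoy_receptors[i % config.decoy_receptors],
            )
            for i in didx
        )

    # ortholog map over the proteome ("human") namespace, minus alias dropouts
    mapped_symbols = truth.ligands + truth.decoy_ligands + truth.background_proteins
    n_alias = int(round(config.ortholog_alias_fraction * len(mapped_symbols)))
    alias_idx = set(
        rng.choice(len(mapped_symbols), size=n_alias, replace=False).tolist()
    ) if n_alias else set()
    ortholog_map = {
        _human(s): (s,) for i, s in enumerate(mapped_symbols) if i not in alias_idx
    }
    truth.unmapped_aliases = sorted(
        _human(mapped_symbols[i]) for i in alias_idx
    )

    ref = LRReference(
        ligands=frozenset(truth.ligands) | frozenset(truth.decoy_ligands),
        receptors=frozenset(receptors_all) | frozenset(truth.decoy_receptors),
        pairs=frozenset(truth.pairs) | frozenset(truth.decoy_pairs),
        ortholog_map=ortholog_map,
    )
    return ref, truth


# ---------------------------------------------------------------------------
# GO annotation


def generate_go_annotation(
    config: SyntheticConfig,
    rng: np.random.Generator,
    ref: LRReference,
    truth: GroundTruth,
) -> GeneSetCollection:
    """Generate a GMT-writable collection with planted shared terms.

    Exactly ``config.shared_terms`` terms contain >= 3 planted ligands and
    >= 3 planted receptors of a single cell type; together those terms
    cover *every* planted ligand and receptor, so full network recovery is
    attainable. Remaining terms draw uniformly from the annotation
    universe excluding planted ligands/receptors (keeps the planted terms
    the only cross-matchable ones, making recovery exact).
    """
    planted_set = set(truth.ligands) | {r for r in truth.all_receptors}
    fill_universe = sorted(
        (set(truth.matrix_genes) - planted_set - set(truth.rare_genes))
        | set(truth.background_proteins)
        | set(truth.decoy_ligands)
    )
    lo, hi = config.genes_per_term
    if hi > len(fill_universe):
        raise ConfigurationError(
            f"genes_per_term upper bound {hi} exceeds fill universe "
            f"({len(fill_universe)} genes)"
        )

    term_ids = [f"GO:SYN{i + 1:04d}" for i in range(config.n_go_terms)]
    shared_ids = sorted(
        term_ids[i]
        for i in rng.choice(config.n_go_terms, size=config.shared_terms, replace=False)
    ) if config.shared_terms else []

    # distribute receptors: shared terms round-robin over cell types; each
    # type's receptors chunked over its terms, padded to >= 3 members
    type_terms: dict[str, list[str]] = {t: [] for t in truth.cell_types}
    for i, tid in enumerate(shared_ids):
        type_terms[truth.cell_types[i % len(truth.cell_types)]].append(tid)

    term_receptors: dict[str, list[str]] = {}
    for ctype, tids in type_terms.items():
        if not tids:
            continue
        recs = truth.receptors_by_type[ctype]
        chunks = [list(c) for c in np.array_split(np.array(recs, dtype=object), len(tids))]
        for tid, chunk in zip(tids, chunks):
            members = list(chunk)
            if len(members) < 3:  # >= 3 receptors of the host type per term
                others = [r for r in recs if r not in members]
                pad = rng.choice(len(others), size=3 - len(members), replace=False)
                members += [others[i] for i in pad]
            term_receptors[tid] = members

    # strengthen each shared term with receptors borrowed across types, so
    # the receptor-side enrichment is decisive regardless of term size
    all_receptors = truth.all_receptors
    for tid, members in term_receptors.items():
        target = min(config.receptors_per_shared_term, len(all_receptors))
        if len(members) < target:
            others = [r for r in all_receptors if r not in members]
            pad = rng.choice(len(others), size=target - len(members), replace=False)
            members += [others[i] for i in pad]
        term_receptors[tid] = members

    # distribute ligands: chunked for coverage, padded to ligands_per_shared_term
    term_ligands: dict[str, list[str]] = {}
    if shared_ids:
        lig_arr = np.array(truth.ligands, dtype=object)
        chunks = [list(c) for c in np.array_split(lig_arr, len(shared_ids))]
        target = min(config.ligands_per_shared_term, config.planted_ligands)
        for tid, chunk in zip(shared_ids, chunks):
            members = list(chunk)
            if len(members) < target:
                others = [l for l in truth.ligands if l not in members]
                pad = rng.choice(len(others), size=target - len(members), replace=False)
                members += [others[i] for i in pad]
            term_ligands[tid] = members

    terms: dict[str, tuple[str, tuple[str, ...]]] = {}
    host_of = {tid: t for t, tids in type_terms.items() for tid in tids}
    for tid in term_ids:
        size = int(rng.integers(lo, hi + 1))
        if tid in term_ligands:
            members = list(term_ligands[tid]) + list(term_receptors[tid])
            truth.shared_terms[tid] = {
                "cell_type": host_of[tid],
                "ligands": sorted(term_ligands[tid]),
                "receptors": sorted(term_receptors[tid]),
            }
        else:
            members = []
        n_fill = max(0, size - len(members))
        fill = rng.choice(len(fill_universe), size=n_fill, replace=False)
        members = members + [fill_universe[i] for i in fill]
        terms[tid] = (f"synthetic biological process {tid[-4:]}", tuple(members))
    return GeneSetCollection(terms)


# ---------------------------------------------------------------------------
# counts


def generate_tissue_counts(
    config: SyntheticConfig,
    tissue: TissueSpec,
    rng: np.random.Generator,
    truth: GroundTruth,
) -> ad.AnnData:
    """Negative-binomial counts for one tissue, with planted markers and
    explicitly constructed QC-violating cells."""
    if not tissue.cells_per_type:
        raise ConfigurationError(f"tissue {tissue.name!r} has zero cell types")
    genes = truth.matrix_genes
    gene_index = {g: i for i, g in enumerate(genes)}
    G = len(genes)
    mito_idx = np.array([gene_index[g] for g in truth.mito_genes], dtype=int)
    rare_idx = np.array([gene_index[g] for g in truth.rare_genes], dtype=int)

    mu_base = np.full(G, config.nb_mean)
    if len(mito_idx):
        mu_base[mito_idx] = config.nb_mean * config.mito_mean_factor
    if len(rare_idx):
        mu_base[rare_idx] = 0.0

    blocks, labels = [], []
    r = config.nb_dispersion
    for ctype, n_cells in tissue.cells_per_type.items():
        mu = mu_base.copy()
        midx = [gene_index[g] for g in truth.markers.get(ctype, [])]
        mu[midx] *= config.marker_fold
        p = r / (r + mu)
        blocks.append(rng.negative_binomial(r, p, size=(n_cells, G)))
        labels += [ctype] * n_cells
    counts = np.vstack(blocks)
    n_total = counts.shape[0]
    barcodes = [f"{tissue.name}-{i + 1:05d}" for i in range(n_total)]

    eligible = np.array(
        [i for i in range(G) if i not in set(mito_idx) and i not in set(rare_idx)]
    )
    n_low = int(round(config.qc_low_gene_fraction * n_total))
    n_high = int(round(config.qc_high_gene_fraction * n_total))
    n_mito = int(round(config.qc_high_mito_fraction * n_total))
    picked = rng.choice(n_total, size=n_low + n_high + n_mito, replace=False) if (
        n_low + n_high + n_mito
    ) else np.array([], dtype=int)
    low_cells = picked[:n_low]
    high_cells = picked[n_low : n_low + n_high]
    mito_cells = picked[n_low + n_high :]

    low_detected = max(1, config.qc_min_genes // 2)
    for c in low_cells:
        counts[c] = 0
        on = rng.choice(len(eligible), size=low_detected, replace=False)
        counts[c, eligible[on]] = 1
    high_detected = config.qc_max_genes + 50
    for c in high_cells:
        counts[c] = 0
        on = rng.choice(len(eligible), size=high_detected, replace=False)
        counts[c, eligible[on]] = 1
    target = min(0.95, 2.0 * tissue.max_mito_fraction)
    for c in mito_cells:
        nonmito_total = counts[c].sum() - counts[c, mito_idx].sum()
        need = int(np.ceil(target / (1 - target) * max(nonmito_total, 1)))
        per_gene = int(np.ceil(need / max(len(mito_idx), 1)))
        counts[c, mito_idx] = per_gene

    # rare genes: detected in exactly (min_cells_per_gene - 1) clean cells
    outlier_set = set(picked.tolist())
    clean = np.array([i for i in range(n_total) if i not in outlier_set])
    rare_cells: dict[str, list[str]] = {}
    for gi, gene in zip(rare_idx, truth.rare_genes):
        n_carrier = max(1, config.min_cells_per_gene - 1)
        carriers = clean[rng.choice(len(clean), size=n_carrier, replace=False)]
        counts[carriers, gi] = 1
        rare_cells[gene] = sorted(barcodes[c] for c in carriers)

    truth.cell_labels[tissue.name] = {b: l for b, l in zip(barcodes, labels)}
    truth.qc_fail[tissue.name] = {
        "low_genes": sorted(barcodes[c] for c in low_cells),
        "high_genes": sorted(barcodes[c] for c in high_cells),
        "high_mito": sorted(barcodes[c] for c in mito_cells),
    }
    truth.rare_gene_cells[tissue.name] = rare_cells

    adata = ad.AnnData(
        X=sp.csr_matrix(counts, dtype=np.float64),
        obs=pd.DataFrame(
            {"true_cell_type": labels}, index=pd.Index(barcodes, name="barcode")
        ),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    return adata


# ---------------------------------------------------------------------------
# proteome


def generate_exosome_proteome(
    config: SyntheticConfig, rng: np.random.Generator, truth: GroundTruth
) -> ProteinList:
    """Proteome in the "human" namespace: planted ligands + background
    proteins (+ optionally some reference decoy ligands)."""
    symbols = [_human(s) for s in truth.ligands]
    symbols += [_human(s) for s in truth.background_proteins]
    if config.proteome_decoy_ligands:
        symbols += [
            _human(s) for s in truth.decoy_ligands[: config.proteome_decoy_ligands]
        ]
    order = rng.permutation(len(symbols))
    return ProteinList(tuple(symbols[i] for i in order), source="npEXO-synthetic")


# ---------------------------------------------------------------------------
# whole bundle


@dataclass
class Bundle:
    """All in-memory artifacts of one synthetic dataset."""

    config: SyntheticConfig
    truth: GroundTruth
    ref: LRReference
    collection: GeneSetCollection
    proteome: ProteinList
    tissues: dict[str, ad.AnnData]
    canonical_markers: dict[str, list[str]]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, adata in self.tissues.items():
            tdir = out / name
            tdir.mkdir(exist_ok=True)
            write_counts_mtx(
                adata, tdir / "matrix.mtx", tdir / "genes.tsv", tdir / "barcodes.tsv"
            )
        write_protein_list(self.proteome, out / "proteome.txt")
        write_table(
            pd.DataFrame({"ligand": sorted(self.ref.ligands)}), out / "ligands.tsv"
        )
        write_table(
            pd.DataFrame({"receptor": sorted(self.ref.receptors)}), out / "receptors.tsv"
        )
        pairs = sorted(self.ref.pairs)
        write_table(
            pd.DataFrame(
                {"ligand": [p[0] for p in pairs], "receptor": [p[1] for p in pairs]}
            ),
            out / "pairs.tsv",
        )
        rows = [
            {"source": src, "target": t}
            for src, targets in sorted(self.ref.ortholog_map.items())
            for t in targets
        ]
        write_table(pd.DataFrame(rows, columns=["source", "target"]), out / "orthologs.tsv")
        write_gmt(self.collection, out / "go_bp.gmt")
        cm_rows = [
            {"cell_type": t, "gene": g}
            for t, gs in self.canonical_markers.items()
            for g in gs
        ]
        write_table(
            pd.DataFrame(cm_rows, columns=["cell_type", "gene"]),
            out / "canonical_markers.tsv",
        )
        (out / "ground_truth.json").write_text(self.truth.to_json() + "\n")


def generate_bundle(
    config: SyntheticConfig | None = None, out_dir: str | Path | None = None
) -> Bundle:
    """Generate the full fixture bundle; optionally write it to ``out_dir``.

    All randomness flows from ``config.seed``; regeneration under the same
    config is byte-identical on disk.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    ref, truth = generate_lr_reference(config, rng)
    collection = generate_go_annotation(config, rng, ref, truth)
    tissues = {
        t.name: generate_tissue_counts(config, t, rng, truth) for t in config.tissues
    }
    proteome = generate_exosome_proteome(config, rng, truth)
    canonical = {t: gs[: min(5, len(gs))] for t, gs in truth.markers.items()}
    bundle = Bundle(
        config=config,
        truth=truth,
        ref=ref,
        collection=collection,
        proteome=proteome,
        tissues=tissues,
        canonical_markers=canonical,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
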