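"""End-to-end orchestration: bundle inputs → consensus communication network.

One run executes, per tissue: QC → normalization → HVG → SNN clustering →
marker-based annotation → Wilcoxon markers → receptor identification →
receptor-side GO-BP enrichment; plus, once: ortholog mapping of the exosome
proteome → ligand identification → ligand-side enrichment. Each tissue's
enriched terms are cross-matched against the ligand side, participants are
paired through the L-R reference into a per-tissue network, and the named
networks are intersected (UpSet semantics) into the consensus network.

All stage parameters live in :class:`PipelineParams`; all randomness flows
from its single ``seed``. Re-running with identical inputs and parameters
reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd

from . import __version__
from .crossmatch import (
    CommunicationNetwork,
    ComparisonReport,
    CrossMatchResult,
    LRReference,
    build_network,
    compare_networks,
    crossmatch_terms,
    identify_celltype_receptors,
    identify_exosome_ligands,
    map_orthologs,
    receptor_celltype_contribution,
    restrict_to_celltype,
)
from .enrichment import ENRICHMENT_COLUMNS, enrich
from .io import (
    GeneSetCollection,
    ProteinList,
    read_counts_mtx,
    read_gmt,
    read_protein_list,
    read_table,
    write_network,
    write_table,
)
from .sc import (
    MARKER_COLUMNS,
    MarkerParams,
    QCThresholds,
    annotate_clusters,
    embed_and_cluster,
    find_markers,
    normalize_log,
    qc_filter,
    select_hvg,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineParams", "BundleInputs", "TissueResult", "PipelineResult", "run_pipeline"]

DEFAULT_MITO_BY_TISSUE = {"neonatal": 0.25, "adult": 0.15}


@dataclass(frozen=True)
class PipelineParams:
    """Every tunable of a pipeline run.

    ``qc_overrides`` maps tissue names to their QC thresholds; tissues not
    listed fall back to ``qc_default`` with the tissue-specific mito limit
    from ``DEFAULT_MITO_BY_TISSUE`` when the name is known.
    """

    seed: int = 0
    n_hvg: int = 2500
    n_pcs: int = 20
    resolution: float = 0.5
    knn: int = 30
    qc_default: QCThresholds = field(default_factory=QCThresholds)
    qc_overrides: Mapping[str, QCThresholds] = field(default_factory=dict)
    marker_params: MarkerParams = field(default_factory=MarkerParams)
    alpha: float = 0.05
    min_term_size: int = 3
    max_term_size: int = 2000
    receptor_padj: float = 0.01
    restrict_cell_type: str | None = None

    def qc_for(self, tissue: str) -> QCThresholds:
        if tissue in self.qc_overrides:
            return self.qc_overrides[tissue]
        if tissue in DEFAULT_MITO_BY_TISSUE:
            return dataclasses.replace(
                self.qc_default, max_mito_fraction=DEFAULT_MITO_BY_TISSUE[tissue]
            )
        return self.qc_default


@dataclass
class BundleInputs:
    """The raw inputs of one run, already loaded into memory."""

    tissues: dict[str, ad.AnnData]
    proteome: ProteinList
    ref: LRReference
    collection: GeneSetCollection
    canonical_markers: dict[str, list[str]]

    @classmethod
    def from_dir(cls, bundle_dir: str | Path) -> "BundleInputs":
        """Load a bundle directory (the layout ``exocomm simulate`` writes)."""
        bundle_dir = Path(bundle_dir)
        for fname in ("proteome.txt", "ligands.tsv", "receptors.tsv", "pairs.tsv", "go_bp.gmt"):
            if not (bundle_dir / fname).exists():
                raise FileNotFoundError(f"missing required input {bundle_dir / fname}")
        tissues = {}
        for tdir in sorted(p for p in bundle_dir.iterdir() if p.is_dir()):
            if (tdir / "matrix.mtx").exists():
                tissues[tdir.name] = read_counts_mtx(
                    tdir / "matrix.mtx", tdir / "genes.tsv", tdir / "barcodes.tsv"
                )
        if not tissues:
            raise FileNotFoundError(f"no tissue count matrices under {bundle_dir}")
        orthologs = None
        if (bundle_dir / "orthologs.tsv").exists():
            orthologs = read_table(bundle_dir / "orthologs.tsv", ["source", "target"])
        ref = LRReference.from_tables(
            read_table(bundle_dir / "ligands.tsv", ["ligand"]),
            read_table(bundle_dir / "receptors.tsv", ["receptor"]),
            read_table(bundle_dir / "pairs.tsv", ["ligand", "receptor"]),
            orthologs,
        )
        canonical: dict[str, list[str]] = {}
        if (bundle_dir / "canonical_markers.tsv").exists():
            cm = read_table(bundle_dir / "canonical_markers.tsv", ["cell_type", "gene"])
            for ctype, grp in cm.groupby("cell_type", sort=False):
                canonical[str(ctype)] = list(grp["gene"].astype(str))
        return cls(
            tissues=tissues,
            proteome=read_protein_list(bundle_dir / "proteome.txt", source="proteome"),
            ref=ref,
            collection=read_gmt(bundle_dir / "go_bp.gmt"),
            canonical_markers=canonical,
        )

    @classmethod
    def from_bundle(cls, bundle) -> "BundleInputs":
        """Adopt an in-memory synthetic Bundle without touching disk."""
        return cls(
            tissues={k: v.copy() for k, v in bundle.tissues.items()},
            proteome=bundle.proteome,
            ref=bundle.ref,
            collection=bundle.collection,
            canonical_markers=bundle.canonical_markers,
        )


@dataclass
class TissueResult:
    name: str
    qc_report: dict
    cluster_labels: np.ndarray
    cluster_annotation: dict[int, str]
    cell_types: np.ndarray
    barcodes: list[str]
    markers: pd.DataFrame
    receptors: dict[str, list[str]]
    receptor_enrichment: pd.DataFrame
    crossmatch: CrossMatchResult | None = None
    network: CommunicationNetwork = CommunicationNetwork()


@dataclass
class PipelineResult:
    params: PipelineParams
    mapping_report: dict
    ligands: list[str]
    ligand_enrichment: pd.DataFrame
    tissues: dict[str, TissueResult]
    comparison: ComparisonReport | None
    consensus: CommunicationNetwork
    contribution: dict[str, int]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(pd.DataFrame({"ligand": self.ligands}), out / "ligands.tsv")
        (out / "mapping_report.json").write_text(
            json.dumps(self.mapping_report, indent=1, sort_keys=True) + "\n"
        )
        write_table(
            _ensure_columns(self.ligand_enrichment, ENRICHMENT_COLUMNS),
            out / "ligand_enrichment.tsv",
        )
        for name, tr in self.tissues.items():
            tdir = out / name
            tdir.mkdir(exist_ok=True)
            (tdir / "qc_report.json").write_text(
                json.dumps(tr.qc_report, indent=1, sort_keys=True) + "\n"
            )
            write_table(
                pd.DataFrame(
                    {
                        "barcode": tr.barcodes,
                        "cluster": tr.cluster_labels,
                        "cell_type": tr.cell_types,
                    }
                ),
                tdir / "cell_types.tsv",
            )
            write_table(_ensure_columns(tr.markers, MARKER_COLUMNS), tdir / "markers.tsv")
            rec_rows = [
                {"cell_type": t, "receptor": r}
                for t in sorted(tr.receptors)
                for r in tr.receptors[t]
            ]
            write_table(
                pd.DataFrame(rec_rows, columns=["cell_type", "receptor"]),
                tdir / "receptors.tsv",
            )
            write_table(
                _ensure_columns(tr.receptor_enrichment, ENRICHMENT_COLUMNS),
                tdir / "receptor_enrichment.tsv",
            )
            write_network(tr.network, tdir / "network.tsv", fmt="tsv")
            write_network(tr.network, tdir / "network.json", fmt="json")
        if self.comparison is not None:
            regions = [
                {
                    "networks": sorted(k),
                    "count": len(v),
                    "edges": [list(p) for p in v],
                }
                for k, v in sorted(
                    self.comparison.regions.items(), key=lambda kv: sorted(kv[0])
                )
            ]
            (out / "upset.json").write_text(
                json.dumps(
                    {"names": list(self.comparison.names), "regions": regions},
                    indent=1,
                    sort_keys=True,
                )
                + "\n"
            )
        write_network(self.consensus, out / "consensus_network.tsv", fmt="tsv")
        write_network(self.consensus, out / "consensus_network.json", fmt="json")
        write_table(
            pd.DataFrame(
                [{"cell_type": t, "receptor_count": c} for t, c in sorted(self.contribution.items())],
                columns=["cell_type", "receptor_count"],
            ),
            out / "contribution.tsv",
        )
        manifest = {
            "exocomm_version": __version__,
            "params": _params_dict(self.params),
            "tissues": sorted(self.tissues),
            "outputs": sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )


def _ensure_columns(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    if len(df) == 0:
        return pd.DataFrame(columns=columns)
    return df[columns]


def _params_dict(params: PipelineParams) -> dict:
    d = dataclasses.asdict(params)
    d["qc_default"] = dataclasses.asdict(params.qc_default)
    d["qc_overrides"] = {k: dataclasses.asdict(v) for k, v in params.qc_overrides.items()}
    d["marker_params"] = dataclasses.asdict(params.marker_params)
    return d


def _empty_enrichment() -> pd.DataFrame:
    return pd.DataFrame(columns=ENRICHMENT_COLUMNS)


def _process_tissue(
    name: str,
    raw: ad.AnnData,
    inputs: BundleInputs,
    params: PipelineParams,
) -> TissueResult:
    filtered, qc_report = qc_filter(raw, params.qc_for(name))
    norm = normalize_log(filtered, params.marker_params.scale)
    n_hvg = min(params.n_hvg, norm.n_vars)
    if n_hvg < params.n_hvg:
        log.info("%s: n_hvg clamped to gene count %d", name, n_hvg)
    hvg = select_hvg(norm, n_hvg)
    labels = embed_and_cluster(
        norm,
        hvg,
        n_pcs=params.n_pcs,
        resolution=params.resolution,
        seed=params.seed,
        k=params.knn,
    )
    annotation = annotate_clusters(labels, norm, inputs.canonical_markers)
    cell_types = np.array([annotation[int(l)] for l in labels])
    try:
        markers = find_markers(norm, cell_types, params.marker_params)
    except ValueError as exc:
        log.warning("%s: marker detection skipped (%s)", name, exc)
        markers = pd.DataFrame(columns=MARKER_COLUMNS)
    receptors = identify_celltype_receptors(markers, inputs.ref, params.receptor_padj)
    rec_query = sorted({r for rs in receptors.values() for r in rs})
    universe = inputs.collection.universe & set(map(str, norm.var_names))
    if rec_query and universe:
        try:
            rec_enrich = enrich(
                rec_query,
                inputs.collection,
                universe,
                alpha=params.alpha,
                min_term_size=params.min_term_size,
                max_term_size=params.max_term_size,
            )
        except ValueError as exc:
            log.warning("%s: receptor enrichment skipped (%s)", name, exc)
            rec_enrich = _empty_enrichment()
    else:
        rec_enrich = _empty_enrichment()
    return TissueResult(
        name=name,
        qc_report=qc_report,
        cluster_labels=labels,
        cluster_annotation=annotation,
        cell_types=cell_types,
        barcodes=[str(b) for b in norm.obs_names],
        markers=markers,
        receptors=receptors,
        receptor_enrichment=rec_enrich,
    )


def run_pipeline(inputs: BundleInputs, params: PipelineParams | None = None) -> PipelineResult:
    """Execute the full workflow on loaded inputs and return all artifacts."""
    params = params or PipelineParams()

    # ligand side (shared across tissues)
    vocab = (
        set(inputs.ref.ligands) | set(inputs.ref.receptors) | set(inputs.collection.universe)
    )
    mapped, mapping_report = map_orthologs(
        inputs.proteome.symbols, inputs.ref.ortholog_map, fallback_vocab=vocab
    )
    ligands = identify_exosome_ligands(mapped, inputs.ref)
    lig_universe = inputs.collection.universe & set(mapped)
    if ligands and lig_universe:
        try:
            lig_enrich = enrich(
                ligands,
                inputs.collection,
                lig_universe,
                alpha=params.alpha,
                min_term_size=params.min_term_size,
                max_term_size=params.max_term_size,
            )
        except ValueError as exc:
            log.warning("ligand enrichment skipped (%s)", exc)
            lig_enrich = _empty_enrichment()
    else:
        lig_enrich = _empty_enrichment()

    tissue_results: dict[str, TissueResult] = {}
    for name in sorted(inputs.tissues):
        tr = _process_tissue(name, inputs.tissues[name], inputs, params)
        cross = crossmatch_terms(lig_enrich, tr.receptor_enrichment)
        participating_receptors = set(cross.receptors)
        restricted = {
            t: [r for r in rs if r in participating_receptors]
            for t, rs in tr.receptors.items()
        }
        restricted = {t: rs for t, rs in restricted.items() if rs}
        net = build_network(
            cross.ligands,
            restricted,
            inputs.ref,
            source=name,
            ligand_terms=cross.ligand_terms,
        )
        if params.restrict_cell_type is not None and len(net):
            net = restrict_to_celltype(net, params.restrict_cell_type)
        tr.crossmatch = cross
        tr.network = net
        tissue_results[name] = tr

    if len(tissue_results) >= 2:
        comparison = compare_networks(
            [(name, tr.network) for name, tr in tissue_results.items()]
        )
        consensus = comparison.consensus
    else:
        comparison = None
        consensus = next(iter(tissue_results.values())).network
    contribution = receptor_celltype_contribution(consensus)

    return PipelineResult(
        params=params,
        mapping_report=mapping_report,
        ligands=ligands,
        ligand_enrichment=lig_enrich,
        tissues=tissue_results,
        comparison=comparison,
        consensus=consensus,
        contribution=contribution,
    )
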