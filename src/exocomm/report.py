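"""Human-readable markdown summary of a finished pipeline run.

Everything in the report is recounted from the stored result tables — the
report never caches numbers of its own, so it is stable across reruns and
always consistent with the TSV/JSON artifacts it cites.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .io import read_table

__all__ = ["generate_report"]


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing result table: {path}")
    return path


def generate_report(results_dir: str | Path) -> str:
    """Summarize a results directory written by ``run_pipeline(...).write``."""
    out = Path(results_dir)
    lines: list[str] = ["# exocomm run summary", ""]

    ligands = read_table(_require(out / "ligands.tsv"), ["ligand"])
    lig_enrich = read_table(_require(out / "ligand_enrichment.tsv"))
    lines += [
        "## Exosome ligand side",
        "",
        f"- identified exosome ligands: {len(ligands)}",
        f"- enriched ligand-side terms (adj. p < alpha): {len(lig_enrich)}",
        "",
    ]
    if len(lig_enrich):
        top = lig_enrich.nsmallest(5, "p_adj")[["term_id", "overlap_size", "p_adj"]]
        lines += ["Top ligand-side terms:", ""]
        lines += [
            f"- {r.term_id}: overlap {r.overlap_size}, adj. p = {float(r.p_adj):.3g}"
            for r in top.itertuples()
        ]
        lines.append("")

    tissue_dirs = sorted(
        p for p in out.iterdir() if p.is_dir() and (p / "markers.tsv").exists()
    )
    lines += ["## Tissues", ""]
    for tdir in tissue_dirs:
        qc = json.loads(_require(tdir / "qc_report.json").read_text())
        cell_types = read_table(_require(tdir / "cell_types.tsv"), ["barcode", "cell_type"])
        markers = read_table(_require(tdir / "markers.tsv"))
        receptors = read_table(_require(tdir / "receptors.tsv"))
        rec_enrich = read_table(_require(tdir / "receptor_enrichment.tsv"))
        network = read_table(_require(tdir / "network.tsv"))
        type_counts = cell_types["cell_type"].value_counts().sort_index()
        shared = (
            set(network["shared_terms"].str.split(";").explode().dropna())
            if len(network)
            else set()
        )
        shared.discard("")
        lines += [
            f"### {tdir.name}",
            "",
            f"- cells retained after QC: {qc['n_cells_out']} / {qc['n_cells_in']}"
            f" (genes {qc['n_genes_out']} / {qc['n_genes_in']})",
            "- cell-type composition: "
            + ", ".join(f"{t}: {c}" for t, c in type_counts.items()),
            f"- marker records: {len(markers)}",
            "- receptors per cell type: "
            + (
                ", ".join(
                    f"{t}: {c}"
                    for t, c in receptors["cell_type"].value_counts().sort_index().items()
                )
                if len(receptors)
                else "none"
            ),
            f"- enriched receptor-side terms: {len(rec_enrich)}",
            f"- shared (cross-matched) terms supporting the network: {len(shared)}",
            f"- network edges: {len(network)} "
            f"({network['ligand'].nunique() if len(network) else 0} ligands, "
            f"{network['receptor'].nunique() if len(network) else 0} receptors)",
            "",
        ]

    consensus = read_table(_require(out / "consensus_network.tsv"))
    contribution = read_table(_require(out / "contribution.tsv"), ["cell_type", "receptor_count"])
    lines += ["## Consensus network", ""]
    if len(consensus):
        lines += [
            f"- edges: {len(consensus)} ({consensus['ligand'].nunique()} ligands, "
            f"{consensus['receptor'].nunique()} receptors)",
        ]
    else:
        lines += ["- edges: 0 (no ligand-receptor pair survived the intersection)"]
    lines += ["", "Receptor contribution per cell type:", ""]
    if len(contribution):
        lines += [
            f"- {r.cell_type}: {r.receptor_count}" for r in contribution.itertuples()
        ]
    else:
        lines += ["- (empty network: all zero)"]
    lines.append("")

    upset_path = out / "upset.json"
    if upset_path.exists():
        upset = json.loads(upset_path.read_text())
        lines += ["## Network comparison (exclusive intersections)", ""]
        for region in upset["regions"]:
            label = " & ".join(region["networks"])
            lines.append(f"- exactly in {{{label}}}: {region['count']} pairs")
        lines.append("")
    return "\n".join(lines)
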