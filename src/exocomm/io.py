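"""Readers and writers for every on-disk format the pipeline touches.

Formats: Matrix Market count triplets with gene/barcode TSV sidecars, GMT
gene-set collections, plain TSV record tables, one-symbol-per-line protein
lists, and the communication-network edge list (TSV and JSON).

Conventions fixed here and nowhere else: Matrix Market files are 1-based
(per the standard) and genes × cells on disk; everything in memory is
0-based and cells × genes (an :class:`anndata.AnnData`). Tables are TSV,
UTF-8, unquoted. Files ending in ``.gz`` are read/written transparently.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SchemaError",
    "GeneSetCollection",
    "ProteinList",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
    "read_protein_list",
    "write_protein_list",
    "write_network",
    "read_network_json",
]


class FormatError(ValueError):
    """Malformed input file; the message names the file (and line, if known)."""


class SchemaError(ValueError):
    """A table is missing required columns."""


def _open(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode, encoding="utf-8" if "b" not in mode else None)


def _read_lines(path: str | Path) -> list[str]:
    with _open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


# ---------------------------------------------------------------------------
# expression matrices


def read_counts_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ad.AnnData:
    """Read a genes × cells Matrix Market triplet into an AnnData (cells × genes).

    Duplicate gene symbols are disambiguated by suffixing ``-1``, ``-2`` ...;
    the original symbol is kept in ``var["original_symbol"]``.

    Raises
    ------
    FormatError
        On dimension mismatches with the sidecars, non-integer or negative
        counts, or duplicate barcodes.
    """
    matrix_path = Path(matrix_path)
    try:
        with _open(matrix_path, "rb" if matrix_path.suffix == ".gz" else "r") as fh:
            mat = scipy.io.mmread(fh)
    except (ValueError, OSError) as exc:  # scipy raises ValueError on bad headers
        raise FormatError(f"{matrix_path}: not a valid Matrix Market file ({exc})") from exc
    mat = sp.coo_matrix(mat)

    genes = [line.split("\t")[0].strip() for line in _read_lines(genes_path)]
    barcodes = [line.split("\t")[0].strip() for line in _read_lines(barcodes_path)]

    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{genes_path}: {len(genes)} gene rows but {matrix_path} declares "
            f"{mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcode rows but {matrix_path} "
            f"declares {mat.shape[1]} columns"
        )
    if mat.nnz and not np.all(mat.data == np.floor(mat.data)):
        raise FormatError(f"{matrix_path}: matrix contains non-integer counts")
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{matrix_path}: matrix contains negative counts")

    dup = pd.Index(barcodes)[pd.Index(barcodes).duplicated()]
    if len(dup):
        first = barcodes.index(dup[0]) + 1
        raise FormatError(
            f"{barcodes_path}: duplicate barcode {dup[0]!r} (first duplicate at "
            f"line {first})"
        )

    unique_genes = _deduplicate(genes)
    var = pd.DataFrame({"original_symbol": genes}, index=unique_genes)
    var.index.name = "gene"
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    X = sp.csr_matrix(mat.T, dtype=np.float64)
    return ad.AnnData(X=X, obs=obs, var=var)


def _deduplicate(symbols: Sequence[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}-{seen[s]}")
            log.warning("duplicate gene symbol %r renamed to %r", s, out[-1])
        else:
            seen[s] = 0
            out.append(s)
    return out


def write_counts_mtx(
    adata: ad.AnnData,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write an AnnData of raw counts as a genes × cells Matrix Market triplet."""
    X = sp.coo_matrix(adata.X.T)
    X.data = np.asarray(X.data)
    scipy.io.mmwrite(str(matrix_path), X, field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in adata.var_names))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in adata.obs_names))


# ---------------------------------------------------------------------------
# gene-set collections (GMT)


@dataclass
class GeneSetCollection:
    """Ordered term-id → (description, genes) map, e.g. a GO-BP annotation.

    ``terms`` maps a unique term id to a description and an ordered,
    deduplicated gene tuple. No term may be empty.
    """

    terms: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not term_id:
                raise ValueError("empty term id")
            if len(genes) == 0:
                raise ValueError(f"term {term_id!r} has no genes")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(g for _, genes in self.terms.values() for g in genes)

    def gene_set(self, term_id: str) -> frozenset[str]:
        return frozenset(self.terms[term_id][1])

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (term, description, genes...; tab-separated).

    Duplicate genes within a term are dropped with a warning; a line with
    fewer than three fields is a :class:`FormatError` carrying line number.
    An empty file yields an empty (valid) collection.
    """
    terms: dict[str, tuple[str, tuple[str, ...]]] = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
            )
        term_id, desc, *genes = fields
        genes = [g.strip() for g in genes if g.strip()]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            log.warning("%s:%d: duplicate genes in term %r deduplicated", path, lineno, term_id)
        if term_id in terms:
            raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
        if not deduped:
            raise FormatError(f"{path}:{lineno}: term {term_id!r} has no genes")
        terms[term_id] = (desc, tuple(deduped))
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for term_id, (desc, genes) in collection.terms.items():
            fh.write("\t".join([term_id, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# record tables


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV with a header row; validate the required columns exist."""
    with _open(path) as fh:
        df = pd.read_csv(
            fh, sep="\t", dtype={c: str for c in required}, float_precision="round_trip"
        )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; expected "
            f"{list(required)}, found {list(df.columns)}"
        )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV preserving floats to 17 significant digits (lossless round trip)."""
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# protein lists


@dataclass(frozen=True)
class ProteinList:
    """Ordered unique gene symbols with a source label (e.g. ``npEXO``)."""

    symbols: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("protein list contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.symbols)


def read_protein_list(path: str | Path, source: str = "") -> ProteinList:
    symbols = []
    seen = set()
    for line in _read_lines(path):
        s = line.strip()
        if not s:
            continue
        if s in seen:
            log.warning("%s: duplicate protein %r dropped", path, s)
            continue
        seen.add(s)
        symbols.append(s)
    return ProteinList(tuple(symbols), source=source or Path(path).stem)


def write_protein_list(proteins: ProteinList, path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for s in proteins.symbols:
            fh.write(s + "\n")


# ---------------------------------------------------------------------------
# communication networks

NETWORK_COLUMNS = ["ligand", "receptor", "receptor_cell_types", "shared_terms", "source_networks"]


def write_network(network, path: str | Path, fmt: str = "tsv") -> None:
    """Write a CommunicationNetwork as an edge-list TSV or as JSON.

    The TSV is the Cytoscape-ingestible surface: one row per directed
    ligand → receptor edge, multi-valued fields semicolon-joined.
    """
    if fmt == "tsv":
        rows = [
            {
                "ligand": e.ligand,
                "receptor": e.receptor,
                "receptor_cell_types": ";".join(sorted(e.cell_types)),
                "shared_terms": ";".join(sorted(e.shared_terms)),
                "source_networks": ";".join(sorted(e.sources)),
            }
            for e in network.edges
        ]
        df = pd.DataFrame(rows, columns=NETWORK_COLUMNS)
        write_table(df, path)
    elif fmt == "json":
        payload = {
            "edges": [
                {
                    "ligand": e.ligand,
                    "receptor": e.receptor,
                    "receptor_cell_types": sorted(e.cell_types),
                    "shared_terms": sorted(e.shared_terms),
                    "source_networks": sorted(e.sources),
                }
                for e in network.edges
            ],
        }
        with _open(path, "wt") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network_json(path: str | Path):
    """Load a CommunicationNetwork previously written with ``fmt='json'``."""
    from .crossmatch import CommunicationNetwork, Edge  # deferred to avoid a cycle

    with _open(path) as fh:
        payload = json.load(fh)
    edges = tuple(
        Edge(
            ligand=e["ligand"],
            receptor=e["receptor"],
            cell_types=frozenset(e["receptor_cell_types"]),
            shared_terms=frozenset(e["shared_terms"]),
            sources=frozenset(e["source_networks"]),
        )
        for e in payload["edges"]
    )
    return CommunicationNetwork(edges=edges)
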