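"""Readers and writers for every external file the pipeline touches.

All tabular files use the TSV dialect (tab separator, ``.`` decimal, no
quoting), matching GEO supplementary conventions.  Gene identifiers are opaque
strings: Ensembl-id vs symbol mapping is the caller's job.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import (
    BiotypeMap,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    TargetTable,
    validate_sample_sheet,
)

log = logging.getLogger(__name__)

DE_TABLE_COLUMNS = [
    "gene_id",
    "mean_cond1",
    "mean_cond2",
    "log2FC",
    "pvalue",
    "padj",
    "significant",
]


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_sheet(sheet)


def read_count_matrix(path, sample_sheet) -> ExpressionMatrix:
    """Read a genes × samples integer count TSV aligned to a sample sheet.

    ``sample_sheet`` may be a path or an already-validated DataFrame.  The
    returned matrix columns follow the sample-sheet order; a sheet sample
    missing from the file is an error.
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = read_sample_sheet(sample_sheet)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate feature id in count matrix: {dup[0]!r}")
    missing = [s for s in sample_sheet.index if s not in raw.columns]
    if missing:
        raise FormatError(f"sample(s) in sheet but not in count matrix: {missing}")
    raw = raw[list(sample_sheet.index)]
    for col in raw.columns:
        series = raw[col]
        bad = series[(series < 0) | (series != series.round()) | series.isna()]
        if len(bad):
            raise FormatError(
                f"count matrix cell for gene {bad.index[0]!r}, sample {col!r} "
                f"is not a non-negative integer: {bad.iloc[0]!r}"
            )
    return ExpressionMatrix(raw.astype("int64"), sample_sheet, "counts")


def read_expression_tsv(path, sample_sheet, unit: str) -> ExpressionMatrix:
    """Read a real-valued features × samples TSV (e.g. log2 array intensities)."""
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = read_sample_sheet(sample_sheet)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    missing = [s for s in sample_sheet.index if s not in raw.columns]
    if missing:
        raise FormatError(f"sample(s) in sheet but not in matrix: {missing}")
    return ExpressionMatrix(raw[list(sample_sheet.index)].astype(float), sample_sheet, unit)


def read_biotype_map(path) -> BiotypeMap:
    """TSV with columns gene_id, biotype; a gene listed twice with two biotypes errors."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "biotype"}.issubset(table.columns):
        raise FormatError("biotype map needs columns gene_id, biotype")
    mapping: dict[str, str] = {}
    for gene, biotype in zip(table["gene_id"], table["biotype"]):
        if gene in mapping and mapping[gene] != biotype:
            raise FormatError(f"gene {gene!r} mapped to two biotypes")
        mapping[gene] = biotype
    return BiotypeMap(mapping)


def read_gene_lengths(path) -> dict[str, int]:
    """TSV with columns gene_id, length (bases, >= 1)."""
    table = pd.read_csv(path, sep="\t")
    if not {"gene_id", "length"}.issubset(table.columns):
        raise FormatError("gene length table needs columns gene_id, length")
    lengths = dict(zip(table["gene_id"].astype(str), table["length"].astype(int)))
    bad = [g for g, n in lengths.items() if n < 1]
    if bad:
        raise FormatError(f"non-positive gene length for {bad[0]!r}")
    return lengths


def read_target_table(
    path, mirna_column: str = "miRNA", target_column: str = "target_gene"
) -> TargetTable:
    """Read a StarBase-style miRNA → target export into a deduplicated pair set.

    Any table containing the two named columns is accepted; column names are
    configurable because exports vary between database versions.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in (mirna_column, target_column):
        if col not in table.columns:
            raise FormatError(f"target table missing required column {col!r}")
    pairs = frozenset(zip(table[mirna_column], table[target_column]))
    if not pairs:
        log.warning("target table %s is empty", path)
    log.info(
        "target table: %d pairs, %d miRNAs, %d targets",
        len(pairs), len({m for m, _ in pairs}), len({t for _, t in pairs}),
    )
    return TargetTable(pairs)


def write_target_table(
    table: TargetTable, path, mirna_column: str = "miRNA", target_column: str = "target_gene"
) -> None:
    frame = pd.DataFrame(sorted(table.pairs), columns=[mirna_column, target_column])
    frame.to_csv(path, sep="\t", index=False)


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Standard GMT: one set per line — name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, description, *genes = fields
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = {g for g in genes if g}
            if members:
                sets[name] = members
                descriptions[name] = description
    return GeneSetCollection(sets, descriptions, set(universe) if universe is not None else None)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            handle.write(f"{name}\t{collection.descriptions.get(name, '')}\t{genes}\n")


def write_de_table(records, path) -> None:
    """CSV of DE results, one row per feature, sorted by gene id."""
    rows = [
        {
            "gene_id": r.feature_id,
            "mean_cond1": r.mean_cond1,
            "mean_cond2": r.mean_cond2,
            "log2FC": r.log2fc,
            "pvalue": r.pvalue,
            "padj": r.padj,
            "significant": r.significant,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=DE_TABLE_COLUMNS)
    frame = frame.sort_values("gene_id").reset_index(drop=True)
    frame.to_csv(path, index=False, float_format="%.6g")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _check_network(nodes: pd.DataFrame, edges: pd.DataFrame) -> None:
    known = set(nodes["id"])
    for col in ("source", "target"):
        unknown = set(edges[col]) - known
        if unknown:
            raise FormatError(f"edge references unknown node {sorted(unknown)[0]!r}")


def write_network(nodes: pd.DataFrame, edges: pd.DataFrame, path, fmt: str = "GraphML") -> None:
    """Export a ceRNA network for Cytoscape.

    ``nodes`` columns: id, node_class (lncRNA/miRNA/mRNA), direction (up/down).
    ``edges`` columns: source, target, kind ("lncRNA-miRNA" or "miRNA-mRNA").
    SIF rows are ``source<TAB>kind<TAB>target``; GraphML carries node_class and
    direction as node attributes.
    """
    _check_network(nodes, edges)
    path = Path(path)
    if fmt.upper() == "SIF":
        with open(path, "w") as handle:
            for row in edges.sort_values(["source", "target"]).itertuples():
                handle.write(f"{row.source}\t{row.kind}\t{row.target}\n")
            connected = set(edges["source"]) | set(edges["target"])
            for node in sorted(set(nodes["id"]) - connected):
                handle.write(f"{node}\n")
    elif fmt.upper() == "GRAPHML":
        graph = nx.Graph()
        for row in nodes.itertuples():
            graph.add_node(row.id, node_class=row.node_class, direction=row.direction)
        for row in edges.itertuples():
            graph.add_edge(row.source, row.target, kind=row.kind)
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}; use SIF or GraphML")


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
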