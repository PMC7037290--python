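"""Readers and writers for every on-disk format the pipeline touches.

Formats: expression TSV (first column gene symbol, header row of sample ids),
two-column group specs, GMT gene-set libraries, interaction edge TSVs
(STRING-dialect PPI with a combined_score column; two-column regulator
dialects), and Cytoscape-loadable SIF / GraphML network exports.

All readers reject malformed input with coordinates rather than silently
coercing; all writer/reader pairs round-trip to equality.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    ExpressionStudy,
    GeneSetLibrary,
    InteractionTable,
    clean_symbol,
)

log = logging.getLogger(__name__)

SIF_RELATIONS = {
    "gene-disease", "pp", "tf-target", "mirna-target",
}


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_tsv(
    path: str | Path,
    group_spec: dict[str, str],
    disease_id: str | None = None,
    collapse_rule: str = "max_mean",
) -> ExpressionStudy:
    """Read a gene x sample expression TSV.

    Rows whose symbol cleans to missing ("", "NA", "null", "---") are
    dropped and counted in the log; duplicate symbols are collapsed with
    the preprocess rule (largest mean by default).  Every sample column must
    appear in ``group_spec`` mapping sample id -> "case"/"control".
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene column plus sample columns")
    sample_ids = list(df.columns[1:])
    missing = [s for s in sample_ids if s not in group_spec]
    if missing:
        raise ValueError(
            f"{path}: samples absent from group spec: {missing[:5]}"
        )

    raw_symbols = df.iloc[:, 0].tolist()
    numeric = np.empty((len(df), len(sample_ids)), dtype=float)
    for j, col in enumerate(sample_ids):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            i = int(bad[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} at row "
                f"{i + 2}, column '{col}'"
            )
        numeric[:, j] = converted.to_numpy()

    keep_rows: list[int] = []
    symbols: list[str] = []
    n_dropped = 0
    for i, raw in enumerate(raw_symbols):
        sym = clean_symbol(raw)
        if sym is None:
            n_dropped += 1
            continue
        keep_rows.append(i)
        symbols.append(sym)
    if n_dropped:
        log.info("%s: dropped %d rows with null/missing gene symbols",
                 path.name, n_dropped)

    study = ExpressionStudy(
        disease_id=disease_id or path.stem,
        gene_ids=symbols,
        sample_ids=sample_ids,
        values=numeric[keep_rows],
        group_labels=[group_spec[s] for s in sample_ids],
    )
    if len(set(symbols)) != len(symbols):
        from .preprocess import collapse_duplicate_symbols

        study = collapse_duplicate_symbols(study, rule=collapse_rule)
    study.validate()
    return study


def write_expression_tsv(
    study: ExpressionStudy,
    path: str | Path,
    junk_rows: tuple[list[str], np.ndarray] | None = None,
) -> Path:
    """Write a study as TSV; ``junk_rows`` (symbols, values) are interleaved
    verbatim for readers to exercise the missing-symbol discard rule."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\t" + "\t".join(study.sample_ids) + "\n")
        rows = [
            (g, study.values[i]) for i, g in enumerate(study.gene_ids)
        ]
        if junk_rows is not None:
            junk_syms, junk_vals = junk_rows
            for s, v in zip(junk_syms, junk_vals):
                rows.append((s, v))
        for sym, vals in rows:
            fh.write(sym + "\t" + "\t".join(repr(float(v)) for v in vals) + "\n")
    return path


def write_group_spec(study: ExpressionStudy, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in zip(study.sample_ids, study.group_labels):
            fh.write(f"{s}\t{g}\n")
    return path


def read_group_spec(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ValueError(f"{path}: expected columns 'sample' and 'group'")
    return dict(zip(df["sample"], df["group"]))


# ---------------------------------------------------------------------------
# GMT gene-set libraries

def read_gmt(path: str | Path, library_name: str | None = None) -> GeneSetLibrary:
    """Read a GMT library: term, description, then member symbols, tab-separated.

    Symbols are upper-cased and de-duplicated within a term.  Lines with
    fewer than three fields are an error naming the line number.
    """
    path = Path(path)
    terms: list[tuple[str, str, frozenset[str]]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; GMT "
                    "requires term, description and at least one member"
                )
            members = frozenset(
                s for s in (clean_symbol(f) for f in fields[2:]) if s is not None
            )
            if not members:
                raise ValueError(
                    f"{path}: line {lineno} has no valid member symbols"
                )
            terms.append((fields[0], fields[1], members))
    if not terms:
        log.warning("%s: empty GMT library", path.name)
    return GeneSetLibrary(library_name or path.stem, terms)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for term_id, desc, members in library.terms:
            fh.write("\t".join([term_id, desc, *sorted(members)]) + "\n")
    return path


# ---------------------------------------------------------------------------
# interaction edge tables

def read_edges_tsv(path: str | Path, kind: str) -> InteractionTable:
    """Read an edge TSV.  PPI dialect: node_a, node_b, combined_score
    (integer 0-1000, required).  Regulator dialects: regulator, target."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    edges: list[tuple[str, str, int | None]] = []
    if kind == "ppi":
        needed = {"node_a", "node_b", "combined_score"}
        if not needed <= set(df.columns):
            raise ValueError(
                f"{path}: ppi table needs columns {sorted(needed)}, "
                f"found {list(df.columns)}"
            )
        for i, row in df.iterrows():
            raw = row["combined_score"].strip()
            if raw == "":
                raise ValueError(f"{path}: row {i + 2} is missing its score")
            try:
                score = int(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: row {i + 2} has non-integer score {raw!r}"
                ) from exc
            edges.append((row["node_a"].strip(), row["node_b"].strip(), score))
    else:
        if df.shape[1] < 2:
            raise ValueError(f"{path}: regulator table needs two columns")
        a_col, b_col = df.columns[:2]
        for _i, row in df.iterrows():
            edges.append((row[a_col].strip(), row[b_col].strip(), None))
    return InteractionTable(kind, edges)  # range/self-loop checks live here


def write_edges_tsv(table: InteractionTable, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        if table.kind == "ppi":
            fh.write("node_a\tnode_b\tcombined_score\n")
            for a, b, s in sorted(table.edges):
                fh.write(f"{a}\t{b}\t{s}\n")
        else:
            fh.write("regulator\ttarget\n")
            for a, b, _s in sorted(table.edges):
                fh.write(f"{a}\t{b}\n")
    return path


# ---------------------------------------------------------------------------
# Cytoscape-loadable network exports

def write_network(graph: nx.Graph, path: str | Path, format: str = "sif") -> Path:
    """Export a network for Cytoscape.

    SIF lines are ``source<TAB>relation<TAB>target``; the relation comes from
    each edge's ``relation`` attribute (default ``pp``).  GraphML carries the
    node ``type`` attribute (gene | disease | protein | tf | mirna) and any
    edge ``score`` attribute.
    """
    path = Path(path)
    if format == "sif":
        with path.open("w") as fh:
            for a, b, data in sorted(graph.edges(data=True)):
                relation = data.get("relation", "pp")
                if relation not in SIF_RELATIONS:
                    raise ValueError(f"unknown SIF relation '{relation}'")
                fh.write(f"{a}\t{relation}\t{b}\n")
    elif format == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network format '{format}'")
    return path


def read_sif(path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno} is not source/relation/target")
            a, relation, b = fields
            graph.add_edge(a, b, relation=relation)
    return graph
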