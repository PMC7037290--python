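"""Degree-based analytics on PPI and regulator networks.

The PPI subnetwork is induced on the common DEG symbols using STRING-style
edges at high confidence (combined score >= 900); hub proteins are nodes
whose degree in that induced subnetwork exceeds 15 (strict, configurable),
ranked by degree with an optional top-k shortlist.  Regulator networks are
bipartite TF->DEG or miRNA->DEG graphs; a regulator's degree is its number
of DEG targets and selection is inclusive: degree >= 20 for TFs,
degree >= 15 for miRNAs, both configurable.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .types import InteractionTable

DEFAULT_PPI_SCORE = 900
DEFAULT_HUB_DEGREE = 15       # strict: degree > 15
DEFAULT_TF_DEGREE = 20        # inclusive: degree >= 20
DEFAULT_MIRNA_DEGREE = 15     # inclusive: degree >= 15


def induce_ppi(
    deg_symbols: set[str],
    table: InteractionTable,
    min_score: int = DEFAULT_PPI_SCORE,
) -> nx.Graph:
    """Induced PPI subnetwork: DEG symbols present in the table, edges with
    both endpoints in the DEG set and score >= min_score (inclusive)."""
    if table.kind != "ppi":
        raise ValueError(f"expected a ppi table, got kind '{table.kind}'")
    deg_symbols = set(deg_symbols)
    graph = nx.Graph()
    for a, b, score in table.edges:
        if score >= min_score and a in deg_symbols and b in deg_symbols:
            graph.add_edge(a, b, score=score, relation="pp")
    for node in graph.nodes:
        graph.nodes[node]["type"] = "protein"
    return graph


def node_degrees(graph: nx.Graph, node_type: str = "protein") -> pd.DataFrame:
    """Per-node degree report: columns node, degree, type."""
    rows = [
        {
            "node": n,
            "degree": d,
            "type": graph.nodes[n].get("type", node_type),
        }
        for n, d in graph.degree()
    ]
    report = pd.DataFrame(rows, columns=["node", "degree", "type"])
    return report.sort_values(
        ["degree", "node"], ascending=[False, True]
    ).reset_index(drop=True)


def select_hubs(
    report: pd.DataFrame,
    min_degree: int = DEFAULT_HUB_DEGREE,
    top_k: int | None = None,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Hub shortlist: nodes with degree > min_degree (strict by default),
    ranked by degree descending; optional top-k truncation."""
    if inclusive:
        hubs = report[report["degree"] >= min_degree]
    else:
        hubs = report[report["degree"] > min_degree]
    hubs = hubs.sort_values(
        ["degree", "node"], ascending=[False, True]
    ).reset_index(drop=True)
    if top_k is not None:
        hubs = hubs.head(top_k)
    hubs = hubs.copy()
    hubs["selected"] = True
    return hubs


def regulator_network(
    deg_symbols: set[str],
    table: InteractionTable,
    kind: str,
    min_degree: int | None = None,
) -> tuple[nx.DiGraph, pd.DataFrame]:
    """Bipartite regulator->DEG network plus the regulator degree report.

    A regulator's degree counts only DEG targets; regulators with no DEG
    target are absent from the graph.  The report's ``selected`` column
    applies the inclusive >= threshold (20 for TFs, 15 for miRNAs unless
    overridden).
    """
    if kind not in ("tf", "mirna"):
        raise ValueError(f"regulator kind must be 'tf' or 'mirna', got '{kind}'")
    if table.kind != kind:
        raise ValueError(
            f"expected a '{kind}' table, got kind '{table.kind}'"
        )
    if min_degree is None:
        min_degree = DEFAULT_TF_DEGREE if kind == "tf" else DEFAULT_MIRNA_DEGREE

    deg_symbols = set(deg_symbols)
    relation = "tf-target" if kind == "tf" else "mirna-target"
    graph = nx.DiGraph()
    for regulator, target, _score in table.edges:
        if target in deg_symbols:
            graph.add_node(regulator, type=kind)
            graph.add_node(target, type="gene")
            graph.add_edge(regulator, target, relation=relation)

    rows = [
        {
            "node": r,
            "degree": graph.out_degree(r),
            "type": kind,
            "selected": graph.out_degree(r) >= min_degree,
        }
        for r in graph.nodes
        if graph.nodes[r]["type"] == kind
    ]
    report = pd.DataFrame(rows, columns=["node", "degree", "type", "selected"])
    report = report.sort_values(
        ["degree", "node"], ascending=[False, True]
    ).reset_index(drop=True)
    return graph, report
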