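"""Cross-disease overlap statistics and gene-disease network construction.

Two diseases are associated when they share at least one significantly
dysregulated gene in the same direction.  The overlap statistic is the
shared-gene count n_ij = |Gi n Gj| and the association score is the Jaccard
coefficient E(i,j) = |Gi n Gj| / |Gi u Gj|, computed separately for
up-regulated and down-regulated sets.  The gene-disease network (GDN) is a
bipartite graph centered on one disease (here typically T2D) linking each
shared gene to every disease whose DEG set contains it.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd

from .types import DiseaseGeneSet, DiseasomePair

DIRECTIONS = ("up", "down")


def shared_gene_count(
    set_i: DiseaseGeneSet, set_j: DiseaseGeneSet, direction: str
) -> tuple[int, frozenset[str]]:
    """Exact same-direction intersection: (count, shared symbols)."""
    shared = frozenset(set_i.direction(direction) & set_j.direction(direction))
    return len(shared), shared


def association_score(
    set_i: DiseaseGeneSet, set_j: DiseaseGeneSet, direction: str
) -> float | None:
    """Jaccard coefficient of the same-direction DEG sets.

    Undefined (``None``) when both sets are empty — reported as absent
    rather than 0 so that "no data" is distinguishable from "disjoint".
    """
    gi = set_i.direction(direction)
    gj = set_j.direction(direction)
    union = len(gi | gj)
    if union == 0:
        return None
    return len(gi & gj) / union


def diseasome_pair(
    set_i: DiseaseGeneSet, set_j: DiseaseGeneSet, direction: str
) -> DiseasomePair:
    n, shared = shared_gene_count(set_i, set_j, direction)
    return DiseasomePair(
        disease_i=set_i.disease_id,
        disease_j=set_j.disease_id,
        direction=direction,
        shared_genes=shared,
        n_shared=n,
        association_score=association_score(set_i, set_j, direction),
    )


def pairwise_table(
    all_sets: list[DiseaseGeneSet],
    directions: tuple[str, ...] = DIRECTIONS,
    center: str | None = None,
) -> pd.DataFrame:
    """All-pairs (or center-vs-rest) overlap table.

    Columns: disease_i, disease_j, direction, n_shared, jaccard,
    shared_genes (comma-joined, sorted).
    """
    by_id = {s.disease_id: s for s in all_sets}
    if center is not None and center not in by_id:
        raise ValueError(f"center disease '{center}' not among the DEG sets")
    if center is None:
        pairs = list(combinations([s.disease_id for s in all_sets], 2))
    else:
        pairs = [(center, d) for d in by_id if d != center]
    rows = []
    for d1, d2 in pairs:
        for direction in directions:
            pair = diseasome_pair(by_id[d1], by_id[d2], direction)
            rows.append(
                {
                    "disease_i": d1,
                    "disease_j": d2,
                    "direction": direction,
                    "n_shared": pair.n_shared,
                    "jaccard": pair.association_score,
                    "shared_genes": ",".join(sorted(pair.shared_genes)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "disease_i", "disease_j", "direction",
            "n_shared", "jaccard", "shared_genes",
        ],
    )


def build_gdn(
    center: str,
    all_sets: list[DiseaseGeneSet],
    direction: str,
) -> nx.Graph:
    """Bipartite gene-disease network centered on one disease.

    ``direction`` is "up", "down" or "both".  The network contains the
    center disease, every other disease sharing at least one same-direction
    DEG with it, and exactly those shared genes as gene nodes.  Gene nodes
    carry a ``disease_degree`` attribute (number of linked diseases) so
    multi-disease genes are easy to report; edges carry ``relation=
    "gene-disease"`` and the ``direction`` label for export.
    """
    by_id = {s.disease_id: s for s in all_sets}
    if center not in by_id:
        raise ValueError(f"center disease '{center}' not among the DEG sets")
    directions = DIRECTIONS if direction == "both" else (direction,)
    for d in directions:
        if d not in DIRECTIONS:
            raise ValueError(f"unknown direction '{d}'")

    graph = nx.Graph()
    graph.add_node(center, type="disease")
    for other_id, other in by_id.items():
        if other_id == center:
            continue
        for d in directions:
            _n, shared = shared_gene_count(by_id[center], other, d)
            for gene in shared:
                graph.add_node(other_id, type="disease")
                graph.add_node(gene, type="gene")
                graph.add_edge(center, gene, relation="gene-disease", direction=d)
                graph.add_edge(other_id, gene, relation="gene-disease", direction=d)
    for node, data in graph.nodes(data=True):
        if data["type"] == "gene":
            graph.nodes[node]["disease_degree"] = sum(
                1 for nb in graph.neighbors(node)
                if graph.nodes[nb]["type"] == "disease"
            )
    return graph
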