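"""Core in-memory containers shared by all pipeline stages.

The pipeline moves four kinds of objects between stages: per-disease
log2 expression matrices with case/control labels (:class:`ExpressionStudy`),
signed differentially-expressed-gene sets (:class:`DiseaseGeneSet`),
flat gene-set libraries in GMT spirit (:class:`GeneSetLibrary`), and typed
interaction edge lists (:class:`InteractionTable`).  Everything downstream
(diseasome scores, enrichment, hub extraction) consumes these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: strings treated as a missing gene symbol after trimming/upper-casing
MISSING_SYMBOLS = frozenset({"", "NA", "NULL", "---", "NAN"})

VALID_GROUPS = ("case", "control")
INTERACTION_KINDS = ("ppi", "tf", "mirna")


def clean_symbol(raw: str) -> str | None:
    """Normalize a gene symbol: trim whitespace, upper-case.

    Returns ``None`` for missing/null placeholders ("", "NA", "null",
    "---"), which callers must drop and count.
    """
    sym = str(raw).strip().upper()
    if sym in MISSING_SYMBOLS:
        return None
    return sym


@dataclass
class ExpressionStudy:
    """One disease's gene x sample log2 expression matrix with group labels."""

    disease_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), log2 intensity
    group_labels: list[str]  # per sample, "case" or "control"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def validate(self, min_group_size: int = 2) -> None:
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_samples != len(self.sample_ids) or n_samples != len(self.group_labels):
            raise ValueError(
                f"matrix has {n_samples} columns but {len(self.sample_ids)} "
                f"sample ids and {len(self.group_labels)} group labels"
            )
        bad = sorted(set(self.group_labels) - set(VALID_GROUPS))
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        for grp in VALID_GROUPS:
            n = self.group_labels.count(grp)
            if n < min_group_size:
                raise ValueError(
                    f"group '{grp}' has {n} samples in study "
                    f"'{self.disease_id}'; at least {min_group_size} required "
                    "for the unpaired t-test"
                )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids; collapse duplicates first")

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices belonging to ``group`` ("case" or "control")."""
        return np.array(
            [i for i, g in enumerate(self.group_labels) if g == group], dtype=int
        )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def equals(self, other: "ExpressionStudy", rtol: float = 0.0, atol: float = 1e-9) -> bool:
        return (
            self.disease_id == other.disease_id
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.group_labels == other.group_labels
            and self.values.shape == other.values.shape
            and np.allclose(self.values, other.values, rtol=rtol, atol=atol)
        )


@dataclass
class DiseaseGeneSet:
    """Signed DEG sets for one disease: up-regulated and down-regulated symbols."""

    disease_id: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.up = set(self.up)
        self.down = set(self.down)
        overlap = self.up & self.down
        if overlap:
            raise ValueError(
                f"genes called both up and down in '{self.disease_id}': "
                f"{sorted(overlap)[:5]}"
            )

    def direction(self, direction: str) -> set[str]:
        if direction == "up":
            return self.up
        if direction == "down":
            return self.down
        raise ValueError(f"unknown direction '{direction}' (expected 'up' or 'down')")


@dataclass
class GeneSetLibrary:
    """A flat gene-set library: named terms mapping to member symbol sets."""

    library_name: str
    terms: list[tuple[str, str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t[0] for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate term ids in library '{self.library_name}'")
        for term_id, _desc, members in self.terms:
            if not members:
                raise ValueError(f"term '{term_id}' has no members")

    def __len__(self) -> int:
        return len(self.terms)

    def term(self, term_id: str) -> frozenset[str]:
        for tid, _d, members in self.terms:
            if tid == term_id:
                return members
        raise KeyError(term_id)


@dataclass
class InteractionTable:
    """Typed edge list: undirected scored PPI, or directed regulator->target.

    PPI edges are stored canonically ordered (lexicographically smaller
    endpoint first) and carry an integer STRING-style combined score in
    [0, 1000].  TF and miRNA edges are directed regulator->target and
    score-free.
    """

    kind: str
    edges: list[tuple[str, str, int | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_KINDS:
            raise ValueError(
                f"unknown interaction kind '{self.kind}' (expected one of "
                f"{INTERACTION_KINDS})"
            )
        canonical: dict[tuple[str, str], int | None] = {}
        for a, b, score in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node '{a}'")
            if self.kind == "ppi":
                if score is None:
                    raise ValueError(f"ppi edge ({a}, {b}) is missing its score")
                score = int(score)
                if not 0 <= score <= 1000:
                    raise ValueError(
                        f"ppi edge ({a}, {b}) score {score} outside [0, 1000]"
                    )
                key = (a, b) if a < b else (b, a)
            else:
                key = (a, b)
            canonical[key] = score
        self.edges = [(a, b, s) for (a, b), s in canonical.items()]

    def __len__(self) -> int:
        return len(self.edges)

    def regulators(self) -> set[str]:
        if self.kind == "ppi":
            raise ValueError("ppi tables have no regulator side")
        return {a for a, _b, _s in self.edges}

    def targets(self) -> set[str]:
        if self.kind == "ppi":
            raise ValueError("ppi tables have no target side")
        return {b for _a, b, _s in self.edges}


@dataclass
class DiseasomePair:
    """Cross-disease overlap for one ordered-insensitive disease pair.

    ``n_shared`` is the count of same-direction shared DEGs and
    ``association_score`` is the Jaccard coefficient
    |Gi n Gj| / |Gi u Gj| (``None`` when both sets are empty).
    """

    disease_i: str
    disease_j: str
    direction: str
    shared_genes: frozenset[str]
    n_shared: int
    association_score: float | None

    def __post_init__(self) -> None:
        if self.n_shared != len(self.shared_genes):
            raise ValueError("n_shared inconsistent with shared_genes")
        if self.association_score is not None and not (
            0.0 <= self.association_score <= 1.0
        ):
            raise ValueError("association score outside [0, 1]")
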