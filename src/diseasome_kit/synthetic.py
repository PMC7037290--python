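"""Synthetic multi-disease expression panels with planted ground truth.

Every pipeline stage is testable without external downloads: this module
generates case/control log2 expression matrices with planted mean-shift
DE genes, cross-disease DEG overlaps planted by an explicit plan, gene-set
libraries with one planted enriched term, and interaction tables (PPI,
TF->target, miRNA->target) with planted high-degree nodes.  All generators
are deterministic for a fixed seed, and the planted truth is returned as a
machine-readable object (and written as a JSON sidecar) so tests can assert
exact recovery.

Model
-----
Control samples for gene *i* are i.i.d. Normal(baseline, noise_sd) on the
log2 scale; case samples of a planted up-regulated gene are shifted by
+effect_size, down-regulated by -effect_size, so the population log2 fold
change equals the planted effect exactly.  The i.i.d. Gaussian noise matches
the assumptions of the unpaired t-test downstream, which makes the null
calibration of the whole pipeline analytically predictable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import DiseaseGeneSet, ExpressionStudy, GeneSetLibrary, InteractionTable

BASELINE_LOG2 = 8.0  # arbitrary but fixed; cancels in all downstream statistics

#: a small reserved block of realistic symbols so symbol-handling code paths
#: (case normalization etc.) are exercised on plausible input
REALISTIC_SYMBOLS = (
    "ENTPD1", "PACSIN2", "DNM1", "DNM2", "TFRC", "PDE4D", "ITGB8",
    "IGFBP5", "NRG1", "CD47", "FBLN1", "PEG10",
)

MISSING_TOKENS = ("", "NA", "null", "---")


def _symbol(i: int) -> str:
    if i < len(REALISTIC_SYMBOLS):
        return REALISTIC_SYMBOLS[i]
    return f"G{i:06d}"


def gene_universe(n_genes: int) -> list[str]:
    """The ordered symbol universe a scenario with ``n_genes`` genes uses."""
    return [_symbol(i) for i in range(n_genes)]


@dataclass
class PanelScenario:
    """Parameters of a planted multi-disease expression panel.

    ``overlap_plan`` maps a disease pair (tuple of two disease ids) to
    ``(n_shared_up, n_shared_down)`` planted counts of DEGs shared with the
    planned sign by both diseases of the pair.
    """

    n_genes: int = 2000
    diseases: tuple[str, ...] = ("T2D", "AD", "MS")
    n_case: int = 10
    n_control: int = 10
    de_fraction: float = 0.05
    effect_size: float = 2.0
    noise_sd: float = 0.7
    overlap_plan: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    seed: int = 0
    missing_symbol_fraction: float = 0.02  # junk rows added when writing TSVs

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size is a positive magnitude")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError(
                "need at least 2 case and 2 control samples "
                "(the unpaired t-test is undefined below that)"
            )
        for pair in self.overlap_plan:
            for d in pair:
                if d not in self.diseases:
                    raise ValueError(f"overlap_plan names unknown disease '{d}'")

    @property
    def n_de(self) -> int:
        """Planted DE genes per disease, split as evenly as possible up/down."""
        return round(self.de_fraction * self.n_genes)

    @property
    def n_up(self) -> int:
        return self.n_de - self.n_de // 2

    @property
    def n_down(self) -> int:
        return self.n_de // 2


@dataclass
class PanelTruth:
    """Planted ground truth: per-disease signed DE sets.

    Pair truth is the intersection of the two disease truths by
    construction; :meth:`shared` recomputes it rather than storing a copy.
    """

    up: dict[str, set[str]]
    down: dict[str, set[str]]

    def for_disease(self, disease: str) -> DiseaseGeneSet:
        return DiseaseGeneSet(disease, set(self.up[disease]), set(self.down[disease]))

    def shared(self, d1: str, d2: str, direction: str) -> set[str]:
        table = self.up if direction == "up" else self.down
        return table[d1] & table[d2]


def plan_truth(scenario: PanelScenario) -> PanelTruth:
    """Assign planted DE symbols: shared genes first, then private, then nulls.

    Raises ``ValueError`` naming the violated constraint when the overlap
    plan demands more shared genes than a disease's per-direction DE budget,
    or when the total planted symbols exceed ``n_genes``.
    """
    order = {d: i for i, d in enumerate(scenario.diseases)}
    up: dict[str, set[str]] = {d: set() for d in scenario.diseases}
    down: dict[str, set[str]] = {d: set() for d in scenario.diseases}
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        if cursor + n > scenario.n_genes:
            raise ValueError(
                f"planted truth needs more than n_genes={scenario.n_genes} symbols"
            )
        out = [_symbol(i) for i in range(cursor, cursor + n)]
        cursor += n
        return out

    # shared genes first, in deterministic pair order
    pairs = sorted(scenario.overlap_plan, key=lambda p: (order[p[0]], order[p[1]]))
    for pair in pairs:
        n_shared_up, n_shared_down = scenario.overlap_plan[pair]
        if n_shared_up < 0 or n_shared_down < 0:
            raise ValueError(f"negative planted count for pair {pair}")
        for sym in take(n_shared_up):
            up[pair[0]].add(sym)
            up[pair[1]].add(sym)
        for sym in take(n_shared_down):
            down[pair[0]].add(sym)
            down[pair[1]].add(sym)

    for d in scenario.diseases:
        if len(up[d]) > scenario.n_up:
            raise ValueError(
                f"overlap_plan plants {len(up[d])} shared up-regulated genes for "
                f"'{d}' but its up budget is {scenario.n_up} "
                f"(de_fraction x n_genes = {scenario.n_de} split up/down)"
            )
        if len(down[d]) > scenario.n_down:
            raise ValueError(
                f"overlap_plan plants {len(down[d])} shared down-regulated genes "
                f"for '{d}' but its down budget is {scenario.n_down}"
            )

    # disease-private DE genes fill the remaining budget; no symbol reuse
    for d in scenario.diseases:
        up[d].update(take(scenario.n_up - len(up[d])))
        down[d].update(take(scenario.n_down - len(down[d])))

    return PanelTruth(up=up, down=down)


def _disease_rng(scenario: PanelScenario, disease: str) -> np.random.Generator:
    idx = scenario.diseases.index(disease)
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, idx]))


def generate_expression_study(
    scenario: PanelScenario,
    disease: str,
    truth: PanelTruth | None = None,
) -> tuple[ExpressionStudy, DiseaseGeneSet]:
    """Generate one disease's case/control matrix plus its planted truth slice.

    Deterministic for a fixed scenario seed: each disease draws from its own
    seed stream, so studies are reproducible independently of generation
    order.
    """
    if disease not in scenario.diseases:
        raise ValueError(f"disease '{disease}' not in scenario")
    if truth is None:
        truth = plan_truth(scenario)
    rng = _disease_rng(scenario, disease)

    genes = [_symbol(i) for i in range(scenario.n_genes)]
    n_samples = scenario.n_case + scenario.n_control
    values = BASELINE_LOG2 + rng.normal(0.0, scenario.noise_sd,
                                        size=(scenario.n_genes, n_samples))
    case_cols = np.arange(scenario.n_case)
    gene_index = {g: i for i, g in enumerate(genes)}
    up_rows = [gene_index[g] for g in truth.up[disease]]
    down_rows = [gene_index[g] for g in truth.down[disease]]
    values[np.ix_(up_rows, case_cols)] += scenario.effect_size
    values[np.ix_(down_rows, case_cols)] -= scenario.effect_size

    sample_ids = [f"{disease}_case_{i+1}" for i in range(scenario.n_case)]
    sample_ids += [f"{disease}_ctrl_{i+1}" for i in range(scenario.n_control)]
    labels = ["case"] * scenario.n_case + ["control"] * scenario.n_control
    study = ExpressionStudy(disease, genes, sample_ids, values, labels)
    study.validate()
    return study, truth.for_disease(disease)


def generate_panel(
    scenario: PanelScenario,
) -> tuple[list[ExpressionStudy], PanelTruth]:
    """Generate one study per disease under a single shared truth assignment."""
    truth = plan_truth(scenario)
    studies = [
        generate_expression_study(scenario, d, truth)[0] for d in scenario.diseases
    ]
    return studies, truth


def generate_gmt_library(
    n_terms: int,
    term_size_range: tuple[int, int],
    planted_term: set[str],
    universe: list[str],
    seed: int = 0,
    library_name: str = "synthetic_library",
    planted_term_id: str = "PLANTED_TERM",
) -> GeneSetLibrary:
    """Build a gene-set library whose first term equals ``planted_term`` exactly.

    The remaining ``n_terms - 1`` terms are uniform random draws from the
    universe, sized uniformly within ``term_size_range``.
    """
    lo, hi = term_size_range
    if hi > len(universe):
        raise ValueError(
            f"term size {hi} exceeds universe of {len(universe)} symbols"
        )
    if not set(planted_term) <= set(universe):
        raise ValueError("planted_term contains symbols outside the universe")
    if n_terms < 1:
        raise ValueError("need at least the planted term")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    terms: list[tuple[str, str, frozenset[str]]] = [
        (planted_term_id, "planted enriched term", frozenset(planted_term))
    ]
    for i in range(n_terms - 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        terms.append(
            (f"RANDOM_TERM_{i+1:04d}", "random background term",
             frozenset(universe[j] for j in members))
        )
    return GeneSetLibrary(library_name, terms)


def generate_interaction_table(
    kind: str,
    n_nodes: int,
    planted_hub: tuple[str, int],
    score_range: tuple[int, int] = (900, 1000),
    seed: int = 0,
    n_background_edges: int | None = None,
    universe: list[str] | None = None,
) -> InteractionTable:
    """Build an edge table with one planted high-degree node.

    For ``kind='ppi'`` the planted hub has exactly the requested degree among
    edges whose score passes the default STRING high-confidence threshold
    (900); background edges never touch the hub, so the planted degree holds
    at any threshold up to ``score_range`` minimum.  For ``kind='tf'`` /
    ``'mirna'`` the table is bipartite regulator->target and the hub is a
    regulator with exactly that many targets.
    """
    hub, degree = planted_hub
    if degree >= n_nodes:
        raise ValueError(
            f"requested hub degree {degree} >= n_nodes {n_nodes}; "
            "a node cannot exceed n_nodes - 1 neighbours"
        )
    rng = np.random.default_rng(seed)
    if universe is None:
        prefix = {"ppi": "P", "tf": "TGT", "mirna": "TGT"}[kind]
        universe = [f"{prefix}{i:05d}" for i in range(n_nodes)]
    else:
        universe = [u for u in universe if u != hub][: n_nodes]
    if len(universe) < degree:
        raise ValueError("universe too small for the requested hub degree")

    lo, hi = score_range
    edges: list[tuple[str, str, int | None]] = []

    def score() -> int | None:
        if kind != "ppi":
            return None
        return int(rng.integers(max(lo, 900), hi + 1))

    partners = rng.choice(len(universe), size=degree, replace=False)
    for j in partners:
        edges.append((hub, universe[j], score()))

    if n_background_edges is None:
        n_background_edges = n_nodes
    if kind == "ppi":
        for _ in range(n_background_edges):
            a, b = rng.choice(len(universe), size=2, replace=False)
            edges.append((universe[a], universe[b], int(rng.integers(lo, hi + 1))))
    else:
        regulators = [f"{'TF' if kind == 'tf' else 'MIR'}{i:03d}"
                      for i in range(1, 6)]
        for _ in range(n_background_edges):
            r = regulators[int(rng.integers(len(regulators)))]
            t = universe[int(rng.integers(len(universe)))]
            edges.append((r, t, None))
    return InteractionTable(kind, edges)


# ---------------------------------------------------------------------------
# on-disk panel materialization

def write_panel(scenario: PanelScenario, out_dir: str | Path) -> dict[str, Path]:
    """Write a panel to disk: one expression TSV + group spec per disease,
    plus the truth JSON sidecar.

    A fraction of extra rows with missing symbols ("", "NA", "null", "---")
    and pure-noise values is interleaved into each TSV so readers exercise
    the discard rule for null gene symbols.
    """
    from .io_formats import write_expression_tsv, write_group_spec

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    studies, truth = generate_panel(scenario)
    paths: dict[str, Path] = {}
    n_junk = round(scenario.missing_symbol_fraction * scenario.n_genes)
    for study in studies:
        expr = out_dir / f"{study.disease_id}_expression.tsv"
        junk_rng = np.random.default_rng(
            np.random.SeedSequence(
                [scenario.seed, scenario.diseases.index(study.disease_id), 7]
            )
        )
        junk_rows = None
        if n_junk:
            junk_values = BASELINE_LOG2 + junk_rng.normal(
                0.0, scenario.noise_sd, size=(n_junk, study.n_samples)
            )
            junk_symbols = [
                MISSING_TOKENS[i % len(MISSING_TOKENS)] for i in range(n_junk)
            ]
            junk_rows = (junk_symbols, junk_values)
        write_expression_tsv(study, expr, junk_rows=junk_rows)
        groups = out_dir / f"{study.disease_id}_groups.tsv"
        write_group_spec(study, groups)
        paths[study.disease_id] = expr

    truth_path = out_dir / "truth.json"
    payload = {
        "up": {d: sorted(s) for d, s in truth.up.items()},
        "down": {d: sorted(s) for d, s in truth.down.items()},
    }
    truth_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    paths["truth"] = truth_path
    return paths


def read_truth(path: str | Path) -> PanelTruth:
    payload = json.loads(Path(path).read_text())
    return PanelTruth(
        up={d: set(s) for d, s in payload["up"].items()},
        down={d: set(s) for d, s in payload["down"].items()},
    )
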