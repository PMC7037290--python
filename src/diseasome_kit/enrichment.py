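"""Local gene-set enrichment against GMT libraries.

For a query gene set of size n drawn from a background universe of size N,
a term with K members (after intersecting with the background) and k query
members in the term is scored with the one-sided hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

which equals Fisher's exact test with the "greater" alternative.  p-values
are Benjamini-Hochberg adjusted within each library, matching the practice
of curating per-database result tables separately.  Ranking is by p; terms
with no overlap (k = 0) are omitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .deg import bh_adjust
from .types import GeneSetLibrary


@dataclass
class EnrichmentResult:
    term_id: str
    library_name: str
    overlap_genes: frozenset[str]
    k: int  # overlap count
    K: int  # term size within background
    n: int  # query size
    N: int  # background size
    p: float
    p_adj: float | None = None
    degenerate: bool = False  # K == N: every background gene is in the term


def hypergeom_enrich(
    query: set[str],
    library: GeneSetLibrary,
    background: set[str],
) -> list[EnrichmentResult]:
    """Score every library term with k >= 1 against the query.

    The query must be a subset of the background; terms are intersected
    with the background before testing.  Results are sorted by p ascending
    and BH-adjusted within the library.
    """
    if not query:
        raise ValueError("empty query gene set")
    if not background:
        raise ValueError("empty background universe")
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise ValueError(
            f"query genes outside the background universe: {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(query)
    results: list[EnrichmentResult] = []
    for term_id, _desc, members in library.terms:
        term = members & background
        K = len(term)
        overlap = frozenset(term & query)
        k = len(overlap)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                term_id=term_id,
                library_name=library.library_name,
                overlap_genes=overlap,
                k=k, K=K, n=n, N=N,
                p=min(p, 1.0),
                degenerate=(K == N),
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    if results:
        adjusted = bh_adjust([r.p for r in results])
        for r, pa in zip(results, adjusted):
            r.p_adj = float(pa)
    return results


def curate(
    results: list[EnrichmentResult],
    alpha: float = 0.05,
    exclusion_patterns: list[str] | None = None,
) -> list[EnrichmentResult]:
    """Keep results with p < alpha, then drop terms matching any exclusion
    pattern (case-insensitive regex on the term id) — the reproducible
    stand-in for manual curation of off-topic terms."""
    compiled = []
    for pat in exclusion_patterns or []:
        try:
            compiled.append(re.compile(pat, re.IGNORECASE))
        except re.error as exc:
            raise ValueError(f"malformed exclusion pattern {pat!r}: {exc}") from exc
    kept = [r for r in results if r.p < alpha]
    if compiled:
        kept = [r for r in kept
                if not any(c.search(r.term_id) for c in compiled)]
    return kept


def benchmark_validate(
    genes: set[str],
    benchmark: GeneSetLibrary,
    background: set[str],
) -> list[EnrichmentResult]:
    """Validate a gene set against a benchmark disease-gene library.

    Statistically identical to :func:`hypergeom_enrich`; kept as a named
    entry point because benchmark validation feeds the gene-disease
    validation network rather than the pathway tables.
    """
    return hypergeom_enrich(genes, benchmark, background)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "term": r.term_id,
            "source": r.library_name,
            "p": r.p,
            "p_adj": r.p_adj,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "overlap_genes": ",".join(sorted(r.overlap_genes)),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["term", "source", "p", "p_adj", "k", "K", "n", "N",
                 "overlap_genes"],
    )
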