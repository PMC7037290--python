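"""Hypergeometric gene-set enrichment with the p < 0.05 curation filter.

Builds a library with one planted term equal to the query and 19 random
terms, scores every overlapping term with the one-sided hypergeometric
tail, and curates by significance and an exclusion pattern.
"""

from diseasome_kit import curate, generate_gmt_library, hypergeom_enrich
from diseasome_kit.enrichment import results_to_frame
from diseasome_kit.synthetic import gene_universe

universe = gene_universe(400)
query = set(universe[:20])
library = generate_gmt_library(
    n_terms=20, term_size_range=(10, 50), planted_term=query,
    universe=universe, seed=5,
)

results = hypergeom_enrich(query, library, background=set(universe))
kept = curate(results, alpha=0.05, exclusion_patterns=["cancer"])

print(results_to_frame(kept).head(5).to_string(index=False))
print(f"\n{len(results)} overlapping terms tested, {len(kept)} kept at p < 0.05")
print("top term:", kept[0].term_id, f"(p = {kept[0].p:.3e})")
# p is P(X >= k) for X ~ Hypergeometric(N, K, n): the chance of seeing at
# least the observed overlap if the query were drawn at random from the
# background.  The planted term attains the smallest p.
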