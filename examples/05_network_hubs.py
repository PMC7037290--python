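"""Hub proteins and regulators from planted interaction tables.

Plants a PPI table with one degree-20 hub and a TF table with one
regulator targeting 20 genes, then applies the selection rules: PPI hubs
need degree strictly greater than 15 in the DEG-induced subnetwork at
STRING score >= 900; TFs are kept at degree >= 20 (inclusive).
"""

from diseasome_kit import (
    generate_interaction_table,
    induce_ppi,
    node_degrees,
    regulator_network,
    select_hubs,
)

ppi = generate_interaction_table("ppi", n_nodes=200, planted_hub=("DNM2", 20),
                                 seed=3)
members = {a for a, _b, _s in ppi.edges} | {b for _a, b, _s in ppi.edges}
graph = induce_ppi(members, ppi, min_score=900)
hubs = select_hubs(node_degrees(graph), min_degree=15, top_k=10)
print("PPI hubs (degree > 15, top 10):")
print(hubs.to_string(index=False))

tf = generate_interaction_table("tf", n_nodes=60, planted_hub=("FOXC1", 20),
                                seed=4)
_g, report = regulator_network(tf.targets(), tf, "tf", min_degree=20)
print("\nTF regulators (selected at degree >= 20):")
print(report.head(5).to_string(index=False))
# Degree counts DEG neighbours only; the planted hub DNM2 and the planted
# regulator FOXC1 pass their respective cuts, background nodes do not.
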