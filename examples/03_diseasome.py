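"""Cross-disease overlap scores and the bipartite gene-disease network.

Plants a three-disease panel with known shared DEG counts, calls DEGs per
disease, and shows that the shared-gene counts and Jaccard association
scores recover the plan, then builds the up-direction gene-disease network
centered on T2D.
"""

from diseasome_kit import PanelScenario, build_gdn, call_degs, generate_panel, pairwise_table

scenario = PanelScenario(
    n_genes=1500,
    diseases=("T2D", "AD", "MS"),
    n_case=10, n_control=10,
    de_fraction=0.10,
    effect_size=3.0,
    noise_sd=0.4,
    overlap_plan={("T2D", "AD"): (6, 4), ("T2D", "MS"): (12, 9)},
    seed=11,
)
studies, _truth = generate_panel(scenario)
called = [call_degs(s)[1] for s in studies]

table = pairwise_table(called, center="T2D")
print(table[["disease_i", "disease_j", "direction", "n_shared", "jaccard"]]
      .to_string(index=False))

gdn = build_gdn("T2D", called, "up")
genes = [n for n, d in gdn.nodes(data=True) if d["type"] == "gene"]
diseases = [n for n, d in gdn.nodes(data=True) if d["type"] == "disease"]
print(f"\nup-direction GDN: {len(diseases)} disease nodes, "
      f"{len(genes)} shared-gene nodes")
# n_shared counts same-direction DEGs in both diseases; jaccard is
# |Gi n Gj| / |Gi u Gj|, the disease-pair association score.
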