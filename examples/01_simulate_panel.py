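"""Generate a synthetic two-disease expression panel with planted truth.

The scenario plants 10% differentially expressed genes per disease and
forces T2D and MS to share 5 up- and 3 down-regulated genes; the truth is
returned as machine-readable sets so downstream recovery can be checked.
"""

from diseasome_kit import PanelScenario, generate_panel

scenario = PanelScenario(
    n_genes=500,
    diseases=("T2D", "MS"),
    n_case=8,
    n_control=8,
    de_fraction=0.10,
    effect_size=2.0,
    noise_sd=0.7,
    overlap_plan={("T2D", "MS"): (5, 3)},
    seed=42,
)
studies, truth = generate_panel(scenario)

for study in studies:
    print(f"{study.disease_id}: {study.n_genes} genes x "
          f"{study.n_samples} samples (log2 scale)")
for d in scenario.diseases:
    print(f"planted truth {d}: {len(truth.up[d])} up, {len(truth.down[d])} down")
print("planted shared up  (T2D, MS):", sorted(truth.shared("T2D", "MS", "up")))
print("planted shared down (T2D, MS):", sorted(truth.shared("T2D", "MS", "down")))
# The shared genes are the ground truth the diseasome stage must recover.
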