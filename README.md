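# diseasome-kit

A network-based quantitative toolkit for finding molecular links between a
center disease and a panel of other diseases through shared differentially
expressed genes (DEGs).  The motivating application is the comorbidity
between type 2 diabetes (T2D) and neurological diseases (Alzheimer's, ALS,
multiple sclerosis, Parkinson's, ...), where case/control transcriptomic
profiles of each disease are compared against the T2D profile to find
shared dysregulated genes, the pathways they act in, and the hub proteins
and regulators that drive them.

## What it computes

Given one log2 expression matrix with case/control labels per disease:

1. **Preprocessing** — duplicate gene symbols are collapsed (largest-mean
   row kept), null/missing symbols discarded, and each gene row can be
   Z-score standardized, `Z_ij = (g_ij − X̄_i) / σ_i`, for cross-study
   comparability.
2. **DEG calling** — per gene, an unpaired (Welch) t-test between cases and
   controls and a log2 fold change (difference of group means).  A gene is
   *up* if `logFC > 1` and `p < 0.01`, *down* if `logFC < −1` and
   `p < 0.01` (strict inequalities; Benjamini–Hochberg adjusted p available
   via `p_mode="adjusted"`).
3. **Diseasome** — for each disease pair *(i, j)* and direction, the shared
   DEG count `n_ij = |G_i ∩ G_j|` and the Jaccard association score
   `E(i, j) = |G_i ∩ G_j| / |G_i ∪ G_j|`; plus a bipartite gene–disease
   network centered on one disease, exported as Cytoscape-loadable
   SIF/GraphML.
4. **Enrichment** — one-sided hypergeometric tests (Fisher's exact,
   "greater") of the common DEGs against GMT gene-set libraries,
   BH-adjusted within each library, curated at `p < 0.05` with optional
   term-exclusion patterns; the same machinery validates gene sets against
   benchmark disease–gene libraries.
5. **Network analytics** — the PPI subnetwork induced on common DEGs at
   STRING combined score ≥ 900, hub proteins at degree > 15 (strict,
   configurable top-k shortlist); bipartite TF→DEG and miRNA→DEG networks
   with inclusive selection at degree ≥ 20 (TF) and ≥ 15 (miRNA).

A synthetic-data module generates multi-disease panels, GMT libraries and
interaction tables with *planted* ground truth (DE genes with controlled
sign and effect, cross-disease overlaps, enriched terms, high-degree hubs)
so that every stage is testable without downloads.

## Worked example

```bash
python examples/03_diseasome.py
```

plants a three-disease panel whose overlap plan forces T2D to share 6 up /
4 down DEGs with AD and 12 up / 9 down with MS, calls DEGs per disease and
recovers the plan exactly:

```
disease_i disease_j direction  n_shared  jaccard
      T2D        AD        up         6 0.041667
      T2D        AD      down         4 0.027397
      T2D        MS        up        12 0.086957
      T2D        MS      down         9 0.063830

up-direction GDN: 3 disease nodes, 18 shared-gene nodes
```

`n_shared` is the number of same-direction DEGs shared by the pair and
`jaccard` their association score; 18 gene nodes = 6 shared with AD + 12
shared with MS in the up direction.  The other examples
(`examples/01…06`) cover panel simulation, DEG calling, enrichment, hub
extraction and the full pipeline run.

The same stages are available from the shell:

```bash
diseasome-kit simulate-panel --config scenario.yaml --out panel --seed 4
diseasome-kit call-degs --expr panel/T2D_expression.tsv \
    --groups panel/T2D_groups.tsv --out T2D_degs.tsv
diseasome-kit run --config run.yaml          # full pipeline
```

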