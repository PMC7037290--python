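# Methods

## Model and procedure

The pipeline treats each disease as an independent case/control comparison
on a log2-scale expression matrix and reduces comorbidity to set overlap of
signed DEG lists.

**Z-score transform.** Each gene row is standardized across all samples of
its study, `Z_ij = (g_ij − X̄_i) / σ_i`, with the sample (n−1) standard
deviation by default (`normalize.sd_mode` switches to the population
denominator).  Samples are not split by group for this transform: the
standardization indexes all samples *j* of the study.  Constant rows
(σ_i = 0) are flagged degenerate and excluded from downstream testing
rather than silently zeroed.  The transform is idempotent up to floating
tolerance and leaves the t-test invariant (it is a per-gene affine map),
which is why DEG calling operates on the *un-standardized* log2 matrix:
there the difference of group means is a genuine log2 fold change and the
|logFC| > 1 threshold keeps its units.  The Z-scored matrix is materialized
alongside for audit and cross-study comparison.

**DEG calling.** The test is an unpaired two-sided t-test; Welch's
unequal-variance form is the default because it stays calibrated when group
variances differ, with the pooled form available (`equal_var=True`).
Degrees of freedom follow Satterthwaite.  When both groups are constant the
test is vacuous (t = 0, p = 1) if the means agree and degenerate (no finite
t, never called) otherwise.  Raw p-values are BH-adjusted across genes; the
call criterion uses raw p < 0.01 by default with the adjusted value one
flag away (`p_mode="adjusted"`), since reasonable analyses differ on which
to threshold.  Both fold-change and p cuts are strict inequalities, so a
gene at logFC exactly 1.0 is neutral.

**Diseasome.** For each disease pair and direction the shared count is the
exact set intersection and the association score is the Jaccard coefficient
|G_i ∩ G_j| / |G_i ∪ G_j|.  The score is undefined (reported absent, not
zero) when both sets are empty, so "no data" is distinguishable from
"disjoint".  Up and down networks are built separately, with a combined
mode that unions direction-tagged edges.  The gene–disease network includes
the center disease, every disease sharing ≥ 1 same-direction DEG with it,
and exactly those shared genes; gene nodes carry a `disease_degree`
attribute so genes shared with several diseases are easy to report.

**Enrichment.** The statistic is the one-sided hypergeometric upper tail
P(X ≥ k) for X ~ Hypergeometric(N, K, n), identical to Fisher's exact test
with the "greater" alternative.  Terms are intersected with the background
before testing; terms with zero overlap are omitted; BH adjustment is
applied within each library because result tables are curated per library.
The background universe defaults to all cleaned symbols of the studies and
is configurable.  Combined/rank scores beyond p are deliberately not
computed; curation keeps p < 0.05 and drops terms matching user-supplied
exclusion patterns — a reproducible stand-in for manual curation of
off-topic terms.

**Network analytics.** The PPI subnetwork is induced on the common-DEG
symbols with edges at combined score ≥ 900 (inclusive, STRING's
highest-confidence preset).  Degrees are computed on that induced
subnetwork, not the full interactome.  Hub selection is strict
(degree > 15) for proteins and inclusive (degree ≥ 20 / ≥ 15) for TFs and
miRNAs; both the threshold and an optional top-k shortlist are exposed so
either convention can be reproduced.  A regulator's degree counts only DEG
targets, and regulators with none are absent from the graph.

## Synthetic panels

The generator emulates RMA-style log2 microarray output: control samples
i.i.d. Normal(8.0, noise_sd) per gene, planted up/down genes shifted by
±effect_size in cases only.  Shared genes are assigned first (per the
overlap plan), then disease-private DE genes, then nulls, with no symbol
reused across roles — so pair truth equals the intersection of disease
truths by construction.  Defaults are effect 2.0 log2 units, sd 0.7, 10 vs
10 samples, 5% DE fraction: a realistic high-power microarray regime in
which a 2-unit shift is detectable but not trivial.  The i.i.d. Gaussian
noise matches the t-test's assumptions, making null calibration and BH
FDR control analytically expected; what passing tests therefore show is
that the implementation is correct under its own model, not that the model
captures real microarray artefacts (probe effects, batch structure,
heavy-tailed noise, correlated genes are all absent).  A small reserved
block of realistic gene symbols and a configurable fraction of
missing-symbol rows exercise symbol cleaning and the null-symbol discard
rule.

## Numerical and design choices

- Sample (n−1) sd in the Z transform; duplicate collapse before
  normalization (the reverse would distort the largest-mean criterion);
  collapse ties keep the first row in file order.
- The association-score denominator is the union, per the Jaccard
  definition; a variant with the intersection in the denominator would be
  identically 1 and is not provided.
- PPI scores follow STRING's 0–1000 integer convention; thresholds are
  inclusive for scores, strict for PPI hub degree, inclusive for regulator
  degree — each configurable.
- Enrichment p-values use the exact hypergeometric survival function;
  K = N (term covers the background) is reported with a degeneracy flag
  and p = 1.
- Symbol cleaning: trim, upper-case; "", "NA", "null", "---" are missing.
- All generators draw from per-disease seed streams spawned from the
  scenario seed, so studies are reproducible independently of generation
  order and regeneration is byte-identical.
- Pipeline reports contain no timestamp; identical inputs give
  byte-identical reports, and every aggregated count is re-derived from
  the materialized stage TSVs before the report is written.

## Problem sizes

The test suite and the acceptance script run on synthetic panels of
300–2,600 genes with 5–12 samples per group, 20-seed replicate sets for the
calibration/FDR checks, and 1,000-instance oracle comparisons — sizes at
which every statistical property asserted is stable while the whole suite
completes in seconds.

## Limitations

- No probe-level processing (CEL/RMA), GEO parsing, batch correction or
  quantile normalization: inputs are assumed to be cleaned log2 matrices.
- No empirical-Bayes variance moderation; small-sample power is what the
  plain Welch test provides.
- Only degree centrality is implemented for hub ranking.
- Enrichment treats gene sets as flat (no GO-graph propagation), and
  offline backgrounds necessarily differ from web-service defaults, so
  p-values are comparable within a run, not across tools.
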