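# Methods

This note documents the models implemented in `mapgen`, the parameter
choices that matter, what the synthetic generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Multi-modal topic model

Diseases are documents; each gene occurrence in a modality gene set is
a token. The model is multi-field LDA with one shared per-disease
topic distribution and one topic–gene distribution per modality:

- θ_d ~ Dirichlet(α), shared across the three modalities of disease d;
- φ_k⁽ᵐ⁾ ~ Dirichlet(β_m) over modality m's gene vocabulary;
- token (d, m) draws topic z ~ θ_d, then gene g ~ φ_z⁽ᵐ⁾.

Inference is collapsed Gibbs sampling with the standard conditional
P(z=k) ∝ (n_dk+α)(n_kg⁽ᵐ⁾+β_m)/(n_k⁽ᵐ⁾+β_m·V_m). Point estimates of
θ and φ are averages of their posterior means over every post-burn-in
sweep. The inner loop is jit-compiled (numba) and seeded, so fits are
deterministic and fast enough for hundreds of diseases in seconds.

Defaults: α = 1/K, β_m = 0.01, 500 sweeps with 250 burn-in (400/200 in
the evaluation and pipeline settings, which mix well at these sizes —
planted partitions are recovered with adjusted Rand index 1.0). On
synthetic corpora K is set to the number of planted topics; for real
corpora K is a user choice (the library default is 50).

**Imputation.** A query with a missing modality is folded in: Gibbs on
the query's tokens only, φ frozen. Every gene of the missing modality
is scored by Σ_k θ_q[k]·φ_k[g]; scores sum to one. Genes are ranked,
and each imputed feature records its *source diseases* — the training
diseases whose same-modality set contains the gene.

**Held-out AUC.** The evaluation holds out n_eval = 60 diseases
carrying all three modalities, fits on the remainder, and for each
held-out disease and modality deletes that modality, folds the disease
in, and computes the ROC AUC of the imputed scores against membership
of the deleted set; per-modality values are macro-averaged. Holding
out the evaluation diseases from training (rather than refitting per
disease) mirrors the intended use, where the query disease is not part
of the training corpus. n_eval = 60 keeps the standard error of the
macro-average small, which matters mostly for the permuted null
(below). The AUC of a planted corpus saturates below 1 for structural
reasons: noise genes in the held-out set are unpredictable, and
unobserved same-pool genes among the negatives score as high as the
positives.

**Null baseline.** `permute_corpus` shuffles each modality's gene sets
independently across diseases, destroying the cross-modality structure
the imputation exploits while preserving within-modality set sizes.
Individual permuted AUCs are bimodal (a permuted disease's present
modalities occasionally point, by chance, at the held-out set's
topic), so the chance-level check (0.5 ± 0.05) is applied to the
per-seed mean over the three modalities; per-modality values are
additionally required to lie strictly below their planted
counterparts.

**Latent feature extraction.** From the ranked imputation the top
fraction is kept (library default 0.01 of the vocabulary for
real-scale corpora; the synthetic demo uses 0.4 because its planted
pool spans a sixth of the vocabulary and the posterior ranking needs
margin). Features are then dropped if (i) the gene already appears in
any present modality of the query, or (ii) after removing
name-excluded diseases, no source disease remains. Name exclusion is
case-insensitive substring matching with trailing-wildcard patterns
("Pulmonary", "Lung", "Fibrosis", "Respir**", "Chest", "Pneumo**");
a feature survives if *any* retained disease supports it — the most
conservative reading of "derived from obviously related diseases",
since gene-level evidence from an unrelated disease is still evidence.
Disease relatedness is the count, per disease, of latent features it
supports, sorted descending.

## Enrichment

For each organ or cell-type context a 2×2 table over the annotated
background (feature∧context, feature∧¬context, ¬feature∧context,
¬feature∧¬context) is tested with Pearson's chi-square without
continuity correction; tables with a zero margin are defined as null
(χ² = 0, p = 1). The test is two-sided as stated; direction is
reported via the odds ratio. q-values are Benjamini–Hochberg adjusted
p-values across the contexts of one kind — BH is the minimal standard
choice where the adjustment method is otherwise unspecified. Genes
outside the annotated background are dropped with a warning; the
background is the set of genes with at least one annotation row.

## Differential expression

A deliberately small DESeq2-style test:

- **Size factors.** Bulk: median-of-ratios against the geometric-mean
  pseudo-reference over genes detected in every sample (library-size
  fallback with a warning when no such gene exists). Single cell: a
  pooled approximation of sum-factor deconvolution — cells are pooled
  (by cell type, or by condition group inside a per-cell-type
  contrast), library sizes normalized within pools, and
  median-of-ratios across pooled pseudo-bulk profiles sets the
  between-pool scale. Factors are rescaled to geometric mean one.
  Pooling matters: with a single dominant transcript (the planted
  ~1000-fold receptor upregulation) plain library-size factors absorb
  the effect into normalization.
- **Dispersion.** Gene-wise method of moments on normalized counts,
  α̂ = max((s² − μ)/μ², 10⁻⁸): no shrinkage trend, no independent
  filtering, no outlier replacement. This keeps the test desk-scale
  and matches a configuration with outlier replacement disabled.
- **Test.** NB GLM with log link and log-size-factor offsets,
  intercept + group indicator. Bulk: Wald test of the group
  coefficient against the normal reference. Single cell:
  likelihood-ratio test of the group term with fitted means floored at
  10⁻⁶, with the signed root of the LR statistic referred to a
  t distribution with n − 2 degrees of freedom (a small-sample-robust
  reference in the spirit of t-based testing for single-cell data).
  P-values are BH-adjusted per contrast; DE genes require
  |log2FC| ≥ 1 and adjusted p < 0.05.

On small planted fixtures the bulk test agrees with pydeseq2 (the
reference DESeq2 implementation) to < 0.1 in log2FC and makes
identical DE calls; the agreement test is part of the suite. A known
estimator property: when a large fraction of genes shifts in one
direction, median-of-ratios factors absorb part of the shift and
log2FC estimates contract toward zero — gene *calls* are unaffected at
the planted effect sizes used here.

**Expression summaries.** Per gene and cell-type cluster: the fraction
of cells with a nonzero count and the mean of ln(1 + counts per
10,000). QC keeps cells with at least `min_genes` detected genes and
at most `max_pct_mito` percent mitochondrial counts (library defaults
200 and 20; the synthetic demo uses a detected-gene floor of 5 because
its matrices carry only a few dozen genes).

## Ligand–receptor bridging

A pair matches the DE list when *any* subunit of its DE-gene side is a
DE gene (a complex is reportable from one differential subunit), but a
pair is localized to the partner organ only when *all* partner-side
subunits reach the expression floor (`frac_expressing ≥ min_frac`,
default 0.2) in at least one cell type there — a functional complex
needs every subunit. The maximal-expression cell type is recorded per
subunit. Symbol matching is exact and case-sensitive after whitespace
trimming.

## KEGG mining

KGML `<entry>` elements are nodes (gene entries mapped to symbol sets
through a KEGG-id→symbol TSV; compound entries kept as traversable
intermediates, since signaling chains route through second messengers
such as Ca²⁺), `<relation>` elements are directed edges from `entry1`
to `entry2`; group entries are expanded by replicating every incident
edge to each component. Relation subtypes are ignored — positioning is
purely reachability, with no path-length cap, computed per anchor via
graph descendants (paths must have length ≥ 1, so a pair member never
self-hits).

Anchoring is per receptor subunit: for every receptor subunit present
in a pathway, a feature reachable from it is a downstream hit and a
feature reaching it an upstream hit, each reported under that
subunit's name. Only when *no* receptor subunit is present does the
ligand node anchor the downstream/upstream search (reported under the
full complex name). This subunit-level anchoring is what makes
multi-subunit receptors yield one row per subunit actually wired into
the pathway, and no rows for subunits a pathway does not contain.

## Map assembly

Cross-organ survivors contribute organ-localized ligand and receptor
nodes and `direct_lr` edges. Pathway hits of retained pairs add
feature nodes — in the receptor's organ for downstream hits, in the
ligand's organ for upstream hits — with edges labeled by the
supporting pathway ids. Feature genes with identical connectivity
(same organ, same in/out edge signature) are merged into one node
(e.g. the three calmodulin genes). Nodes carry their top-3 cell types
by mean log-CP10K as evidence. Finally, every feature node lacking an
outgoing pathway edge to a same-organ map ligand receives an `unknown`
("?") edge toward that ligand: the loop's open question, emitted only
toward ligands already in the map. The map serializes to GraphML (for
graph tooling) and JSON (for exact comparisons).

The map stores per-node cell-type evidence but asserts nothing about
whether two same-organ steps occur within one cell type or in trans
across cell types; the underlying data cannot distinguish these.

## Synthetic study conditions

The generators plant known structure so every stage has a recoverable
truth:

- **Disease corpus** (default 200 diseases, 6 topics, vocabulary 300
  genes per modality, ~25 genes per disease-modality, 10–15% uniform
  noise): per-topic gene pools are disjoint by default (an overlap
  parameter exists), giving the sharpest recovery surface for the AUC
  benchmark. The pipeline demo renames part of one topic's Ae pool to
  the canonical latent genes (CALM1/2/3, PCK1, ELMO1, CAMK4 plus
  decoys) and names some of that topic's diseases with excluded
  (fibrosis-like) and related (diabetes, Alzheimer, neoplasm, ...)
  names; the query disease is generated from that topic with its Ae
  modality missing.
- **Count matrices**: one NB draw per gene and column,
  counts ~ NB(base · sizefactor · 2^(log2FC·group), dispersion); no
  zero inflation beyond the NB. The bulk demo (30 vs 30 samples,
  dispersion 0.08, |log2FC| 2.5 on all 112 fixture DE genes) is a
  scaled-down stand-in for a patient cohort; the single-cell demos
  plant the liver partner-gene profiles (KNG1/PCK1 in hepatocytes,
  IL6R/IL6ST in endothelium and cholangiocytes) and the lung effects
  (2¹⁰-fold BDKRB1 and ~3-fold calmodulin upregulation in
  macrophages, IL6 downregulation in endothelial and dendritic
  cells), plus high-mitochondria cells for QC testing.
- **Curated tables**: the ligand–receptor fixture carries every pair
  of the published bridging tables plus ≥ 20 decoy pairs whose genes
  never appear among DE genes; the KGML fixtures realize exactly the
  published pathway positions (receptor→…→ELMO1 in hsa04062,
  IFNGR1/2→…→CAMK4 in hsa04380, IL6R→…→PCK1 in hsa04151,
  CALM1/2/3→…→IL6 in hsa05163, KNG1–BDKRB1→…→CALM1/2/3 through a
  calcium compound node in hsa05200) plus a decoy pathway and a
  dedicated group-entry file. Pathways contain only the pair members
  needed for those positions; ligand entries are omitted where an
  absent-receptor pair would otherwise anchor on them and create
  unprinted rows.

What the generators do **not** emulate: real vocabulary sizes
(thousands of diseases, tens of thousands of genes), overlapping and
hierarchical disease topics, curation noise in gene-set databases,
patient-level covariates and batch effects in expression data,
zero-inflation and ambient RNA in single-cell counts, or true KEGG
topology complexity (bidirectional relations, maplinks, nested
groups). Passing tests therefore demonstrate the correctness of the
algorithms under their stated models and the internal consistency of
the pipeline — not that the worked instance's biology would be
recovered from real resources at full scale, where headline gene
counts depend on specific database versions.

## Numerical choices and degenerate inputs

Probability vectors are renormalized to machine precision after sample
averaging (invariant: sums within 10⁻⁹). Ties in rankings break
lexicographically (genes by symbol, enrichment contexts by name,
relatedness by disease name) so outputs are order-invariant and
deterministic. Degenerate cases are defined, not special-cased away:
zero-margin contingency tables are null; all-zero genes test null;
all-zero columns, empty corpora, empty gene sets, and queries sharing
no vocabulary with the training corpus raise errors. GLM failures fall
back to an empirical estimate with p = 1 rather than propagate. Every
stochastic component takes an explicit seed; pipeline manifests
contain no timestamps, so identical seeds produce byte-identical
artifacts.

## Known limitations

- The topic model assumes one shared topic distribution across
  modalities; modality-specific topic usage is not modeled.
- Cells are treated as replicates in single-cell contrasts
  (pseudo-replication); patient-level random effects are out of scope.
- The Wald/LRT tests use method-of-moments dispersions without
  shrinkage, which is anti-conservative for very small replicate
  numbers; the acceptance-scale settings (≥ 15 per group) are within
  its comfortable regime.
- Pathway mining ignores relation signs: an inhibitory chain counts as
  a connection, as positioning — not regulation direction — is the
  question being answered.
- The "?" edge encodes absence of evidence in the supplied pathway
  set, not evidence of absence.
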