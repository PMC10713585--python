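# mapgen

Machine-generated inter-organ disease mechanism maps.

Many chronic diseases are studied organ by organ, yet their biology
often spans several organs connected by secreted ligands and their
receptors. `mapgen` implements a generative computational pipeline that
proposes such inter-organ mechanisms from public-style disease-omics
resources, using idiopathic pulmonary fibrosis (IPF) and a lung–liver
crosstalk loop as its worked instance. The pipeline chains:

1. **Multi-modal topic modeling** of a disease–gene corpus. Each
   disease is a "document" with up to three gene-set modalities —
   altered expression (Ae), biomarker (Bm), genetic variation (Gv).
   The model is multi-field latent Dirichlet allocation: a shared
   per-disease topic distribution θ (Dirichlet(α) prior) and
   independent per-modality topic–gene distributions φ⁽ᵐ⁾
   (Dirichlet(β_m) priors), estimated by collapsed Gibbs sampling. A
   query disease with a missing modality is folded in and the modality
   is imputed by the posterior-predictive mass
   s(g) = Σ_k θ_q[k]·φ⁽ᵐ⁾[k, g]. Imputation quality is measured by
   held-out ROC AUC; imputed genes surviving self- and
   related-disease-name exclusion become the *latent features* of the
   query disease.
2. **Organ/cell-type enrichment** of the latent features via 2×2
   chi-square tests of independence against an annotation table, with
   Benjamini–Hochberg q-values (this selects the partner organ — the
   liver in the worked instance).
3. **Negative-binomial differential expression** (DESeq2-style:
   median-of-ratios size factors, NB GLM with log link and offsets,
   Wald test for bulk and a t-referenced likelihood-ratio test for
   single-cell contrasts) defining DE genes at |log2FC| ≥ 1 and
   adjusted p < 0.05.
4. **Ligand–receptor bridging** of the DE genes through a curated pair
   table (both directions: DE gene as ligand, DE gene as receptor),
   and filtering to pairs whose partner side is actually expressed in
   the partner organ's single-cell data.
5. **KEGG pathway mining**: KGML files are parsed into directed entry
   graphs and each latent feature is positioned *downstream* (reachable
   from a receptor node) or *upstream* (reaching a ligand node) of each
   bridged pair.
6. **Map assembly**: direct ligand→receptor edges across organs,
   pathway edges within organs, and a "?" edge where the loop lacks a
   known pathway link — an explicit open question.

All inputs can be generated synthetically with planted structure, so
the whole pipeline is testable offline at desk scale.

## Worked example

Generate the curated-table fixtures and bridge the DE-gene list:

```sh
mapgen simulate --out fixtures
mapgen bridge --degenes fixtures/degenes.tsv --lrdb fixtures/lr_table.tsv \
    --direction ligand --out step2.tsv
```

`step2.tsv` holds the 13 ligand→receptor pairs found among the 112
DE genes (7 ligands, 8 receptors covering 10 genes), e.g.:

```
ligand receptor       evidence
 CCL18    ACKR1 PMID: 26740381
CXCL10    ACKR1 PMID: 26740381
CXCL10    CXCR3 KEGG: hsa04060
```

Mining the pathway fixtures for latent features positioned around
those pairs:

```python
import io
from mapgen import synthetic as syn, bridge as br, kegg as kg

fx = syn.build_table_fixtures()
pairs = br.identify_ligands(set(fx.degenes), fx.lr_pairs).pairs
graphs = [kg.parse_kgml(io.BytesIO(x.encode()), fx.symbol_map)
          for n, x in sorted(fx.kgml.items()) if n != "group_demo"]
print(kg.hits_table(kg.find_targets(graphs, pairs, fx.latent_features)))
```

prints the nine pathway positions, among them:

```
 Pathway Ligand Receptor Feature   Position
hsa04151    IL6     IL6R    PCK1 downstream
hsa05163    IL6     IL6R   CALM1   upstream
```

i.e. PCK1 lies downstream of the IL6–IL6R pair in the PI3K–Akt pathway
and the calmodulins upstream of IL6 signaling in hsa05163.

The full synthetic run:

```sh
mapgen run --synthetic --seed 7 --out run7
```

executes every stage and writes `run7/mechanism_map.{json,graphml}`
containing the six-edge lung–liver loop

```
KNG1@liver -> BDKRB1@lung            direct_lr
BDKRB1@lung -> CALM1/CALM2/CALM3@lung  pathway (hsa05200)
CALM1/CALM2/CALM3@lung -> IL6@lung     pathway (hsa05163)
IL6@lung -> IL6R/IL6ST@liver         direct_lr
IL6R/IL6ST@liver -> PCK1@liver       pathway (hsa04151)
PCK1@liver -> KNG1@liver             unknown ("?")
```

read as: liver-secreted kininogen (KNG1) activates its bradykinin
receptor (BDKRB1) on lung cells, driving the calmodulin pathway and
IL6; circulating IL6 engages its hepatic receptor complex and the
gluconeogenic effector PCK1; the PCK1→KNG1 link closing the loop has
no known pathway support, hence the "?" edge. Every node carries its
top supporting cell types (hepatocytes for KNG1 and PCK1, macrophages
for the calmodulin upregulation), and `manifest.json` records seeds
and parameters; reruns with the same seed are byte-identical.

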