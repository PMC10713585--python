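"""Synthetic inputs with planted, recoverable structure.

Everything the pipeline consumes can be generated here: a multi-modal
disease-gene corpus with planted topics, negative-binomial bulk and
single-cell count matrices with planted fold changes and QC outliers,
an organ/cell-type annotation table with planted over-representation,
and the curated table fixtures (ligand-receptor database, KGML pathway
files, KEGG-id symbol map, DE-gene and latent-feature lists).

The table fixtures embed the published lung-liver worked instance: the
ligand-receptor pairs, the pathway positions of the signaling targets,
and decoy entries that must never surface downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree

from .containers import MODALITIES, CountMatrix, DiseaseRecord, LRPair

# ---------------------------------------------------------------------------
# Disease corpus with planted topics
# ---------------------------------------------------------------------------


@dataclass
class CorpusSpec:
    """Parameters of the planted-topic disease corpus.

    ``noise_rate`` is the fraction of gene draws taken uniformly from
    the whole modality vocabulary instead of the disease's topic pools.
    ``pool_overlap`` optionally blends a fraction of vocabulary-wide
    genes into each topic pool (pools are disjoint by default).
    """

    n_diseases: int = 200
    n_genes_per_modality: dict[str, int] = field(
        default_factory=lambda: {"Ae": 300, "Bm": 300, "Gv": 300}
    )
    n_topics_true: int = 6
    genes_per_disease: float = 25.0
    noise_rate: float = 0.1
    topics_per_disease: int = 1
    pool_overlap: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_diseases < 1 or self.n_topics_true < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        if self.genes_per_disease < 1:
            raise ValueError("genes_per_disease must be >= 1")
        if self.topics_per_disease < 1:
            raise ValueError("topics_per_disease must be >= 1")
        for mod in MODALITIES:
            if mod not in self.n_genes_per_modality:
                raise ValueError(f"missing vocabulary size for modality {mod}")
            if self.n_genes_per_modality[mod] < self.n_topics_true:
                raise ValueError(
                    f"{mod}: {self.n_topics_true} topics exceed the "
                    f"distinguishable gene pool of {self.n_genes_per_modality[mod]}"
                )


def modality_vocab(spec: CorpusSpec, modality: str) -> list[str]:
    """Deterministic gene symbols for one modality's vocabulary."""
    return [f"{modality}G{i:04d}" for i in range(spec.n_genes_per_modality[modality])]


def simulate_disease_corpus(
    spec: CorpusSpec,
) -> tuple[list[DiseaseRecord], dict]:
    """Generate a disease corpus whose gene sets are unions of topic-pool draws.

    Returns the corpus and the planted truth: per-disease topic
    assignments and the per-topic, per-modality gene pools.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    pools: dict[str, list[list[str]]] = {}
    for mod in MODALITIES:
        vocab = np.array(modality_vocab(spec, mod))
        shuffled = rng.permutation(vocab)
        size = len(vocab) // spec.n_topics_true
        mod_pools = [
            list(shuffled[k * size : (k + 1) * size]) for k in range(spec.n_topics_true)
        ]
        if spec.pool_overlap > 0:
            n_extra = int(round(spec.pool_overlap * size))
            for pool in mod_pools:
                extra = rng.choice(vocab, size=n_extra, replace=False)
                pool.extend(g for g in extra if g not in pool)
        pools[mod] = mod_pools

    corpus: list[DiseaseRecord] = []
    assignments: dict[str, tuple[int, ...]] = {}
    for d in range(spec.n_diseases):
        topics = tuple(
            sorted(
                rng.choice(
                    spec.n_topics_true,
                    size=min(spec.topics_per_disease, spec.n_topics_true),
                    replace=False,
                )
            )
        )
        did = f"D{d:04d}"
        assignments[did] = topics
        modality_genes: dict[str, set[str]] = {}
        for mod in MODALITIES:
            vocab = modality_vocab(spec, mod)
            pool_union = sorted({g for t in topics for g in pools[mod][t]})
            size = max(1, int(rng.poisson(spec.genes_per_disease)))
            genes: set[str] = set()
            for _ in range(size):
                if rng.random() < spec.noise_rate:
                    genes.add(vocab[rng.integers(len(vocab))])
                else:
                    genes.add(pool_union[rng.integers(len(pool_union))])
            modality_genes[mod] = genes
        corpus.append(DiseaseRecord(did, f"Disease {d:04d}", modality_genes))

    truth = {"topic_assignments": assignments, "pools": pools}
    return corpus, truth


def permute_corpus(corpus: list[DiseaseRecord], seed: int) -> list[DiseaseRecord]:
    """Destroy cross-modality structure by shuffling each modality's gene
    sets independently across diseases (a null corpus for AUC baselines)."""
    rng = np.random.default_rng(seed)
    permuted = []
    sets_by_mod = {
        mod: [rec.modality_genes[mod] for rec in corpus if mod in rec.modality_genes]
        for mod in MODALITIES
    }
    orders = {mod: rng.permutation(len(sets_by_mod[mod])) for mod in MODALITIES}
    cursors = dict.fromkeys(MODALITIES, 0)
    for rec in corpus:
        genes = {}
        for mod in rec.modalities:
            idx = orders[mod][cursors[mod]]
            cursors[mod] += 1
            genes[mod] = set(sets_by_mod[mod][idx])
        permuted.append(DiseaseRecord(rec.disease_id, rec.name, genes))
    return permuted


# ---------------------------------------------------------------------------
# Negative-binomial count matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSimSpec:
    """Parameters of a simulated count matrix (bulk or single-cell).

    ``planted_de`` entries are ``(gene, log2fc)`` for bulk matrices or
    ``(gene, log2fc, cell_type)`` for per-cell-type effects; the fold
    change is applied to the first group label (bulk) or to every cell
    of the named type (single-cell). ``cell_type_profiles`` overrides
    the base mean per (cell type, gene). ``mito_fraction`` is the mean
    mitochondrial fraction of ordinary cells; ``n_high_mito`` cells are
    planted near 50% to exercise QC filtering.
    """

    n_genes: int = 100
    gene_names: list[str] | None = None
    base_mean: float | np.ndarray = 50.0
    dispersion: float | np.ndarray = 0.1
    n_samples_per_group: int = 10
    group_labels: tuple[str, str] = ("IPF", "nonIPF")
    planted_de: list[tuple] = field(default_factory=list)
    n_cells_per_type: dict[str, int] = field(default_factory=dict)
    organ: str = "lung"
    cell_type_profiles: dict[str, dict[str, float]] = field(default_factory=dict)
    mito_fraction: float = 0.05
    n_high_mito: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ValueError("dispersions must be > 0")
        if np.any(np.asarray(self.base_mean) <= 0):
            raise ValueError("base means must be > 0")

    def genes(self) -> list[str]:
        if self.gene_names is not None:
            if len(self.gene_names) != self.n_genes:
                raise ValueError("gene_names length must equal n_genes")
            return list(self.gene_names)
        return [f"G{i:04d}" for i in range(self.n_genes)]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """NB(mean=mu, var=mu + disp*mu^2) via numpy's (n, p) parameterization."""
    n = 1.0 / disp
    p = n / (n + np.maximum(mu, 0.0))
    return rng.negative_binomial(np.broadcast_to(n, mu.shape), p)


def simulate_counts(spec: ExpressionSimSpec, mode: str = "bulk") -> CountMatrix:
    """Simulate an integer count matrix under the stated NB model.

    Counts are NB(mean * sizefactor * 2^(log2FC * group), dispersion).
    Single-cell mode attaches ``cell_type``, ``organ``, ``percent_mito``
    and ``n_genes_detected`` columns to the metadata.
    """
    spec.validate()
    if mode not in ("bulk", "single_cell"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(spec.seed)
    genes = spec.genes()
    gene_index = {g: i for i, g in enumerate(genes)}
    base = np.broadcast_to(np.asarray(spec.base_mean, dtype=float), (spec.n_genes,))
    disp = np.broadcast_to(np.asarray(spec.dispersion, dtype=float), (spec.n_genes,))

    if mode == "bulk":
        for entry in spec.planted_de:
            if len(entry) != 2:
                raise ValueError("bulk planted_de entries must be (gene, log2fc)")
        n = 2 * spec.n_samples_per_group
        groups = [spec.group_labels[0]] * spec.n_samples_per_group + [
            spec.group_labels[1]
        ] * spec.n_samples_per_group
        sf = np.exp(rng.normal(0.0, 0.15, size=n))
        lfc = np.zeros(spec.n_genes)
        for gene, log2fc in spec.planted_de:
            lfc[gene_index[gene]] = log2fc
        is_test = np.array([g == spec.group_labels[0] for g in groups], dtype=float)
        mu = base[:, None] * sf[None, :] * 2.0 ** (lfc[:, None] * is_test[None, :])
        counts = _nb_draw(rng, mu, disp[:, None])
        cols = [f"S{j:03d}" for j in range(n)]
        meta = pd.DataFrame({"group": groups}, index=cols)
        return CountMatrix(pd.DataFrame(counts, index=genes, columns=cols), meta)

    if not spec.n_cells_per_type:
        raise ValueError("single_cell mode requires n_cells_per_type")
    planted: dict[str, dict[str, float]] = {}
    for entry in spec.planted_de:
        if len(entry) != 3:
            raise ValueError(
                "single_cell planted_de entries must be (gene, log2fc, cell_type)"
            )
        gene, log2fc, cell_type = entry
        planted.setdefault(cell_type, {})[gene] = log2fc

    columns, cell_types = [], []
    mus = []
    for cell_type in spec.n_cells_per_type:
        profile = spec.cell_type_profiles.get(cell_type, {})
        mean = base.copy()
        for gene, value in profile.items():
            mean[gene_index[gene]] = value
        for gene, log2fc in planted.get(cell_type, {}).items():
            mean[gene_index[gene]] = mean[gene_index[gene]] * 2.0**log2fc
        for c in range(spec.n_cells_per_type[cell_type]):
            columns.append(f"{cell_type}_{c:04d}")
            cell_types.append(cell_type)
            mus.append(mean)
    n_cells = len(columns)
    sf = np.exp(rng.normal(0.0, 0.3, size=n_cells))
    mu = np.stack(mus, axis=1) * sf[None, :]
    counts = _nb_draw(rng, mu, disp[:, None])

    percent_mito = rng.uniform(0.0, 2.0 * spec.mito_fraction * 100.0, size=n_cells)
    high_mito = np.zeros(n_cells, dtype=bool)
    if spec.n_high_mito:
        chosen = rng.choice(n_cells, size=min(spec.n_high_mito, n_cells), replace=False)
        high_mito[chosen] = True
        percent_mito[chosen] = rng.uniform(45.0, 55.0, size=len(chosen))
    meta = pd.DataFrame(
        {
            "cell_type": cell_types,
            "organ": spec.organ,
            "percent_mito": percent_mito,
            "n_genes_detected": (counts > 0).sum(axis=0),
            "high_mito_planted": high_mito,
        },
        index=columns,
    )
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=columns), meta)


# ---------------------------------------------------------------------------
# Annotation table with planted organ/cell-type over-representation
# ---------------------------------------------------------------------------

ORGANS = ("liver", "lung", "kidney", "spleen", "brain", "heart")
CELL_TYPES_ANNOT = (
    "hepatocyte",
    "kupffer cell",
    "endothelial cell",
    "t cell",
    "macrophage",
    "cardiomyocyte",
)


def simulate_annotation_table(
    background: list[str],
    planted_genes: list[str],
    planted_organ: str = "liver",
    planted_cell_type: str = "hepatocyte",
    base_rate: float = 0.12,
    planted_rate: float = 0.60,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-to-context annotation rows with one over-represented context.

    Every background gene is annotated to each context with probability
    ``base_rate``; ``planted_genes`` hit the planted organ and cell type
    with probability ``planted_rate`` (a ~5x over-representation at the
    defaults), which downstream enrichment must recover.
    """
    rng = np.random.default_rng(seed)
    planted = set(planted_genes)
    rows = []
    for kind, contexts, special in (
        ("organ", ORGANS, planted_organ),
        ("cell_type", CELL_TYPES_ANNOT, planted_cell_type),
    ):
        for context in contexts:
            for gene in background:
                rate = (
                    planted_rate
                    if (context == special and gene in planted)
                    else base_rate
                )
                if rng.random() < rate:
                    rows.append({"gene": gene, "context": context, "kind": kind})
    df = pd.DataFrame(rows).drop_duplicates()
    # guarantee non-empty contexts
    for kind, contexts in (("organ", ORGANS), ("cell_type", CELL_TYPES_ANNOT)):
        for context in contexts:
            present = ((df["context"] == context) & (df["kind"] == kind)).any()
            if not present:
                df = pd.concat(
                    [
                        df,
                        pd.DataFrame(
                            [{"gene": background[0], "context": context, "kind": kind}]
                        ),
                    ],
                    ignore_index=True,
                )
    return df.sort_values(["kind", "context", "gene"], ignore_index=True)


# ---------------------------------------------------------------------------
# Curated table fixtures: ligand-receptor pairs, KGML pathways, gene lists
# ---------------------------------------------------------------------------

# Ligand (lung DE gene) -> receptor pairs, with their curation evidence tags.
TABLE1_PAIRS: tuple[tuple[tuple[str, ...], tuple[str, ...], str], ...] = (
    (("CCL18",), ("ACKR1",), "PMID: 26740381"),
    (("CXCL9",), ("ACKR1",), "PMID: 26740381"),
    (("CXCL10",), ("ACKR1",), "PMID: 26740381"),
    (("CXCL11",), ("ACKR1",), "PMID: 26740381"),
    (("CXCL9",), ("CXCR3",), "KEGG: hsa04060"),
    (("CXCL10",), ("CXCR3",), "KEGG: hsa04060"),
    (("CXCL11",), ("CXCR3",), "KEGG: hsa04060"),
    (("CXCL11",), ("ACKR3",), "KEGG: hsa04060"),
    (("IL6",), ("IL6R", "IL6ST"), "KEGG: hsa04060"),
    (("IFNG",), ("IFNGR1", "IFNGR2"), "KEGG: hsa04060"),
    (("SELE",), ("CEACAM1",), "PMID: 1378450"),
    (("SELE",), ("CD44",), "PMC4571854"),
    (("SELE",), ("GLG1",), "PMID: 11404363"),
)

# Ligand -> receptor (lung DE gene) pairs.
TABLE2_PAIRS: tuple[tuple[tuple[str, ...], tuple[str, ...], str], ...] = (
    (("PF4V1",), ("CXCR3",), "KEGG: hsa04060"),
    (("CXCL9",), ("CXCR3",), "KEGG: hsa04060"),
    (("CXCL10",), ("CXCR3",), "KEGG: hsa04060"),
    (("CXCL11",), ("CXCR3",), "KEGG: hsa04060"),
    (("CXCL13",), ("CXCR3",), "KEGG: hsa04060"),
    (("PF4",), ("CXCR3",), "KEGG: hsa04060"),
    (("CXCL13",), ("CXCR5",), "KEGG: hsa04060"),
    (("CXCL16",), ("CXCR6",), "KEGG: hsa04060"),
    (("KNG1",), ("BDKRB1",), "KEGG: hsa04080"),
    (("SLURP1",), ("CHRNA1",), "KEGG: hsa04080"),
    (("SLURP2",), ("CHRNA1",), "KEGG: hsa04080"),
    (("ENTPD1",), ("TMIGD3",), "PMID: 21677139"),
    (("DSG1",), ("DSC3",), "PMID: 27298358"),
    (("DSG2",), ("DSC3",), "PMID: 27298358"),
    (("CD274",), ("PDCD1",), "PMID: 23954143"),
    (("PDCD1LG2",), ("PDCD1",), "PMID: 23954143"),
    (("SELPLG",), ("SELE",), "PMC4571854"),
)

#: The DE-gene-side gene symbols the two bridging steps must recover.
STEP1_LIGANDS = frozenset(
    {"CCL18", "CXCL9", "CXCL10", "CXCL11", "IL6", "IFNG", "SELE"}
)
STEP3_RECEPTORS = frozenset(
    {"CXCR3", "CXCR5", "CXCR6", "BDKRB1", "CHRNA1", "TMIGD3", "DSC3", "PDCD1", "SELE"}
)

#: Expected pathway-mining rows: (pathway, ligand, receptor, feature, position).
TABLE3_HITS: frozenset[tuple[str, str, str, str, str]] = frozenset(
    [
        ("hsa04062", "CXCL9", "CXCR3", "ELMO1", "downstream"),
        ("hsa04062", "CXCL10", "CXCR3", "ELMO1", "downstream"),
        ("hsa04062", "CXCL11", "CXCR3", "ELMO1", "downstream"),
        ("hsa04380", "IFNG", "IFNGR1", "CAMK4", "downstream"),
        ("hsa04380", "IFNG", "IFNGR2", "CAMK4", "downstream"),
        ("hsa04151", "IL6", "IL6R", "PCK1", "downstream"),
        ("hsa05163", "IL6", "IL6R", "CALM1", "upstream"),
        ("hsa05163", "IL6", "IL6R", "CALM2", "upstream"),
        ("hsa05163", "IL6", "IL6R", "CALM3", "upstream"),
    ]
)
TABLE4_HITS: frozenset[tuple[str, str, str, str, str]] = frozenset(
    [
        ("hsa04062", "PF4V1", "CXCR3", "ELMO1", "downstream"),
        ("hsa04062", "CXCL9", "CXCR3", "ELMO1", "downstream"),
        ("hsa04062", "CXCL10", "CXCR3", "ELMO1", "downstream"),
        ("hsa04062", "CXCL11", "CXCR3", "ELMO1", "downstream"),
        ("hsa04062", "CXCL13", "CXCR3", "ELMO1", "downstream"),
        ("hsa04062", "CXCL13", "CXCR5", "ELMO1", "downstream"),
        ("hsa04062", "PF4", "CXCR3", "ELMO1", "downstream"),
        ("hsa04062", "CXCL16", "CXCR6", "ELMO1", "downstream"),
        ("hsa05200", "KNG1", "BDKRB1", "CALM1", "downstream"),
        ("hsa05200", "KNG1", "BDKRB1", "CALM2", "downstream"),
        ("hsa05200", "KNG1", "BDKRB1", "CALM3", "downstream"),
    ]
)

#: Entrez-style KEGG identifiers for the genes appearing in the fixtures.
KEGG_IDS: dict[str, str] = {
    "CXCR3": "hsa:2833",
    "CXCR5": "hsa:643",
    "CXCR6": "hsa:10663",
    "GNB1": "hsa:2782",
    "PIK3CB": "hsa:5291",
    "DOCK2": "hsa:1794",
    "ELMO1": "hsa:9844",
    "RAC1": "hsa:5879",
    "IFNGR1": "hsa:3459",
    "IFNGR2": "hsa:3460",
    "JAK2": "hsa:3717",
    "STAT1": "hsa:6772",
    "CAMK4": "hsa:814",
    "IL6": "hsa:3569",
    "IL6R": "hsa:3570",
    "NFKB1": "hsa:4790",
    "PIK3CA": "hsa:5290",
    "AKT1": "hsa:207",
    "FOXO1": "hsa:2308",
    "PCK1": "hsa:5105",
    "KNG1": "hsa:3827",
    "BDKRB1": "hsa:623",
    "PLCB1": "hsa:23236",
    "CALM1": "hsa:801",
    "CALM2": "hsa:805",
    "CALM3": "hsa:808",
    "GCK": "hsa:2645",
    "GPI": "hsa:2821",
    "PFKL": "hsa:5211",
    "GRPA": "hsa:9001",
    "GRPB": "hsa:9002",
    "GRPC": "hsa:9003",
}

#: Canonical latent signaling targets planted throughout the fixtures.
CANONICAL_FEATURES = ("CALM1", "CALM2", "CALM3", "PCK1", "ELMO1", "CAMK4")


def _kgml(
    pathway_id: str,
    title: str,
    entries: list[tuple[int, str, str]],
    relations: list[tuple[int, int, str]],
    groups: list[tuple[int, list[int]]] | None = None,
) -> str:
    """Serialize a minimal KGML document (entry/relation/group dialect)."""
    root = etree.Element(
        "pathway",
        name=f"path:{pathway_id}",
        org="hsa",
        number=pathway_id[3:],
        title=title,
    )
    for entry_id, name, entry_type in entries:
        etree.SubElement(
            root, "entry", id=str(entry_id), name=name, type=entry_type
        )
    for group_id, components in groups or []:
        group = etree.SubElement(
            root, "entry", id=str(group_id), name="undefined", type="group"
        )
        for comp in components:
            etree.SubElement(group, "component", id=str(comp))
    for entry1, entry2, subtype in relations:
        rel = etree.SubElement(
            root, "relation", entry1=str(entry1), entry2=str(entry2), type="PPrel"
        )
        etree.SubElement(rel, "subtype", name=subtype, value="-->")
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def _gene_chain(symbols: list[str]) -> list[tuple[int, str, str]]:
    return [(i + 1, KEGG_IDS[s], "gene") for i, s in enumerate(symbols)]


def _build_kgml_fixtures() -> dict[str, str]:
    kgml: dict[str, str] = {}

    # Chemokine signaling: three receptors funnel into one axis ending at ELMO1.
    symbols = ["CXCR3", "CXCR5", "CXCR6", "GNB1", "PIK3CB", "DOCK2", "ELMO1", "RAC1"]
    idx = {s: i + 1 for i, s in enumerate(symbols)}
    kgml["hsa04062"] = _kgml(
        "hsa04062",
        "Chemokine signaling pathway",
        _gene_chain(symbols),
        [
            (idx["CXCR3"], idx["GNB1"], "activation"),
            (idx["CXCR5"], idx["GNB1"], "activation"),
            (idx["CXCR6"], idx["GNB1"], "activation"),
            (idx["GNB1"], idx["PIK3CB"], "activation"),
            (idx["PIK3CB"], idx["DOCK2"], "activation"),
            (idx["DOCK2"], idx["ELMO1"], "binding/association"),
            (idx["ELMO1"], idx["RAC1"], "activation"),
        ],
    )

    # Osteoclast differentiation: both IFNG receptor subunits reach CAMK4.
    symbols = ["IFNGR1", "IFNGR2", "JAK2", "STAT1", "CAMK4"]
    idx = {s: i + 1 for i, s in enumerate(symbols)}
    kgml["hsa04380"] = _kgml(
        "hsa04380",
        "Osteoclast differentiation",
        _gene_chain(symbols),
        [
            (idx["IFNGR1"], idx["JAK2"], "activation"),
            (idx["IFNGR2"], idx["JAK2"], "activation"),
            (idx["JAK2"], idx["STAT1"], "activation"),
            (idx["STAT1"], idx["CAMK4"], "expression"),
        ],
    )

    # PI3K-Akt: IL6R signals through to the gluconeogenic effector PCK1.
    symbols = ["IL6R", "PIK3CA", "AKT1", "FOXO1", "PCK1"]
    idx = {s: i + 1 for i, s in enumerate(symbols)}
    kgml["hsa04151"] = _kgml(
        "hsa04151",
        "PI3K-Akt signaling pathway",
        _gene_chain(symbols),
        [
            (idx["IL6R"], idx["PIK3CA"], "activation"),
            (idx["PIK3CA"], idx["AKT1"], "activation"),
            (idx["AKT1"], idx["FOXO1"], "inhibition"),
            (idx["FOXO1"], idx["PCK1"], "expression"),
        ],
    )

    # Human cytomegalovirus infection: calmodulins sit upstream of IL6.
    symbols = ["CALM1", "CALM2", "CALM3", "NFKB1", "IL6", "IL6R"]
    idx = {s: i + 1 for i, s in enumerate(symbols)}
    kgml["hsa05163"] = _kgml(
        "hsa05163",
        "Human cytomegalovirus infection",
        _gene_chain(symbols),
        [
            (idx["CALM1"], idx["NFKB1"], "activation"),
            (idx["CALM2"], idx["NFKB1"], "activation"),
            (idx["CALM3"], idx["NFKB1"], "activation"),
            (idx["NFKB1"], idx["IL6"], "expression"),
            (idx["IL6"], idx["IL6R"], "activation"),
        ],
    )

    # Pathways in cancer: KNG1-BDKRB1 reaches the calmodulins through a
    # calcium compound node; the three CALM genes share one KGML entry.
    entries = [
        (1, KEGG_IDS["KNG1"], "gene"),
        (2, KEGG_IDS["BDKRB1"], "gene"),
        (3, KEGG_IDS["PLCB1"], "gene"),
        (4, "cpd:C00076", "compound"),
        (5, f"{KEGG_IDS['CALM1']} {KEGG_IDS['CALM2']} {KEGG_IDS['CALM3']}", "gene"),
    ]
    kgml["hsa05200"] = _kgml(
        "hsa05200",
        "Pathways in cancer",
        entries,
        [
            (1, 2, "activation"),
            (2, 3, "activation"),
            (3, 4, "activation"),
            (4, 5, "activation"),
        ],
    )

    # Decoy pathway: no pair member, no latent feature.
    symbols = ["GCK", "GPI", "PFKL"]
    idx = {s: i + 1 for i, s in enumerate(symbols)}
    kgml["hsa00010"] = _kgml(
        "hsa00010",
        "Glycolysis / Gluconeogenesis",
        _gene_chain(symbols),
        [(idx["GCK"], idx["GPI"], "activation"), (idx["GPI"], idx["PFKL"], "activation")],
    )

    # Dedicated group-entry dialect exercise: group {GRPA, GRPB} -> GRPC.
    kgml["group_demo"] = _kgml(
        "hsa09999",
        "Group entry demo",
        [(1, KEGG_IDS["GRPA"], "gene"), (2, KEGG_IDS["GRPB"], "gene"),
         (3, KEGG_IDS["GRPC"], "gene")],
        [(4, 3, "activation")],
        groups=[(4, [1, 2])],
    )
    return kgml


@dataclass
class TableFixtures:
    """The bundled curated-table fixtures with their planted truth."""

    lr_pairs: list[LRPair]
    decoy_pairs: list[LRPair]
    degenes: list[str]
    latent_features: list[str]
    kgml: dict[str, str]
    symbol_map: dict[str, str]


def build_table_fixtures(n_decoy_pairs: int = 24) -> TableFixtures:
    """Curated-table fixtures realizing the published worked instance.

    The ligand-receptor table carries every printed pair plus decoys
    whose members are absent from the DE-gene list; the KGML files
    realize exactly the printed pathway positions of the latent
    signaling targets; the DE-gene and latent-feature lists carry the
    canonical members padded with inert fillers.
    """
    if n_decoy_pairs < 20:
        raise ValueError("at least 20 decoy pairs required")
    seen: dict = {}
    for lig, rec, ev in TABLE1_PAIRS + TABLE2_PAIRS:
        seen.setdefault((lig, rec), LRPair(lig, rec, ev))
    real_pairs = list(seen.values())

    decoys = []
    for i in range(n_decoy_pairs):
        lig = (f"DLG{i:02d}",) if i % 3 else (f"DLG{i:02d}A", f"DLG{i:02d}B")
        rec = (f"DRC{i:02d}",) if i % 2 else (f"DRC{i:02d}A", f"DRC{i:02d}B")
        decoys.append(LRPair(lig, rec, "synthetic decoy"))

    core_degenes = sorted(STEP1_LIGANDS | STEP3_RECEPTORS)
    fillers = [f"DEG{i:03d}" for i in range(112 - len(core_degenes))]
    degenes = core_degenes + fillers

    latent = list(CANONICAL_FEATURES) + [f"LAT{i:03d}" for i in range(14)]

    return TableFixtures(
        lr_pairs=real_pairs + decoys,
        decoy_pairs=decoys,
        degenes=degenes,
        latent_features=latent,
        kgml=_build_kgml_fixtures(),
        symbol_map={kegg_id: symbol for symbol, kegg_id in KEGG_IDS.items()},
    )


def write_table_fixtures(fixtures: TableFixtures, outdir) -> dict[str, str]:
    """Write the fixture bundle as plain-text files; returns path names."""
    import pathlib

    from . import io as mio

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "kgml").mkdir(exist_ok=True)
    paths = {}
    mio.write_lr_table(fixtures.lr_pairs, outdir / "lr_table.tsv")
    paths["lr_table"] = str(outdir / "lr_table.tsv")
    mio.write_symbol_map(fixtures.symbol_map, outdir / "symbol_map.tsv")
    paths["symbol_map"] = str(outdir / "symbol_map.tsv")
    for name, xml in fixtures.kgml.items():
        path = outdir / "kgml" / f"{name}.xml"
        path.write_text(xml)
        paths[name] = str(path)
    for label, genes in (
        ("degenes", fixtures.degenes),
        ("latent_features", fixtures.latent_features),
    ):
        path = outdir / f"{label}.tsv"
        path.write_text("gene\n" + "\n".join(genes) + "\n")
        paths[label] = str(path)
    return paths
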