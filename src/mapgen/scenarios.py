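"""Ready-made synthetic study scenarios for the end-to-end pipeline.

These builders compose the generic generators in :mod:`mapgen.synthetic`
into the lung-liver worked instance: a disease corpus whose
fibrosis-like topic carries the canonical latent signaling genes, an
annotation table with liver/hepatocyte over-representation of that
topic's genes, a bulk lung cohort with the DE genes planted, a liver
single-cell matrix expressing the cross-organ partners (KNG1, IL6R,
IL6ST, PCK1) in the expected cell types, and paired IPF/control lung
single-cell matrices with the macrophage BDKRB1 and calmodulin
upregulation planted.
"""

from __future__ import annotations

import numpy as np

from .containers import CountMatrix, DiseaseRecord
from .synthetic import (
    CorpusSpec,
    ExpressionSimSpec,
    TableFixtures,
    simulate_annotation_table,
    simulate_counts,
    simulate_disease_corpus,
)

#: Disease names that the exclusion filter must remove as query-related.
EXCLUDED_NAMES = (
    "Pulmonary Fibrosis",
    "Lung Neoplasm",
    "Respiratory Failure",
    "Pneumoconiosis",
    "Chest Wall Disorder",
    "Cystic Fibrosis",
)

#: Plausible related-disease names for the fibrosis-like topic.
RELATED_NAMES = (
    "Malignant Neoplasm of Breast",
    "Diabetes Mellitus",
    "Alzheimer Disease",
    "Obesity",
    "Atherosclerosis",
    "Rheumatoid Arthritis",
    "Systemic Lupus Erythematosus",
    "Multiple Sclerosis",
    "Hypertensive Disease",
    "Arteriosclerosis",
)


def build_demo_corpus(
    fixtures: TableFixtures, seed: int = 0
) -> tuple[list[DiseaseRecord], DiseaseRecord, dict, list[str]]:
    """Disease corpus with a fibrosis-like topic carrying the latent genes.

    Returns (corpus, query, truth, latent_pool): the query emulates the
    fibrosis disease with its altered-expression modality missing; the
    fibrosis-like topic's Ae pool is renamed so its first genes are the
    fixture latent features (CALM1/2/3, PCK1, ELMO1, CAMK4 and decoys),
    which imputation must surface.
    """
    spec = CorpusSpec(
        n_diseases=240,
        n_genes_per_modality={"Ae": 360, "Bm": 300, "Gv": 300},
        n_topics_true=6,
        genes_per_disease=25.0,
        noise_rate=0.1,
        seed=seed,
    )
    corpus, truth = simulate_disease_corpus(spec)

    pool0 = sorted(truth["pools"]["Ae"][0])
    targets = fixtures.latent_features
    rename = dict(zip(pool0[: len(targets)], targets))
    for rec in corpus:
        rec.modality_genes["Ae"] = {
            rename.get(g, g) for g in rec.modality_genes["Ae"]
        }
    truth["pools"]["Ae"] = [
        [rename.get(g, g) for g in pool] for pool in truth["pools"]["Ae"]
    ]

    topic0 = [
        rec for rec in corpus if truth["topic_assignments"][rec.disease_id] == (0,)
    ]
    for rec, name in zip(topic0, EXCLUDED_NAMES):
        rec.name = name
    for rec, name in zip(topic0[len(EXCLUDED_NAMES):], RELATED_NAMES * 4):
        rec.name = name

    rng = np.random.default_rng(seed + 1)
    query_genes = {}
    for mod in ("Bm", "Gv"):
        pool = sorted(truth["pools"][mod][0])
        chosen = rng.choice(len(pool), size=25, replace=False)
        query_genes[mod] = {pool[i] for i in chosen}
    query = DiseaseRecord("QUERY", "Idiopathic Pulmonary Fibrosis", query_genes)
    return corpus, query, truth, truth["pools"]["Ae"][0]


def build_demo_annotation(
    background: list[str], latent_pool: list[str], seed: int = 0
):
    """Annotation table with the latent pool planted into liver/hepatocyte."""
    return simulate_annotation_table(
        background=sorted(background),
        planted_genes=sorted(latent_pool),
        planted_organ="liver",
        planted_cell_type="hepatocyte",
        seed=seed,
    )


def build_demo_bulk(fixtures: TableFixtures, seed: int = 0) -> CountMatrix:
    """Bulk lung cohort with every fixture DE gene planted at |log2FC| 2.5.

    The matrix also carries the decoy ligand-receptor genes (unplanted,
    so they must never be called DE) and inert background genes.
    """
    decoy_genes = sorted(
        {g for p in fixtures.decoy_pairs for g in p.ligand_subunits}
        | {g for p in fixtures.decoy_pairs for g in p.receptor_subunits}
    )
    background = [f"BG{i:03d}" for i in range(150)]
    genes = list(fixtures.degenes) + decoy_genes + background
    rng = np.random.default_rng(seed + 11)
    base = rng.lognormal(np.log(120.0), 0.5, size=len(genes))
    planted = [
        (g, 2.5 if i % 3 else -2.5) for i, g in enumerate(fixtures.degenes)
    ]
    spec = ExpressionSimSpec(
        n_genes=len(genes),
        gene_names=genes,
        base_mean=base,
        dispersion=0.08,
        n_samples_per_group=30,
        group_labels=("IPF", "nonIPF"),
        planted_de=planted,
        seed=seed + 12,
    )
    return simulate_counts(spec, mode="bulk")


#: Liver cell-type means for the cross-organ partner genes.
LIVER_PROFILES = {
    "hepatocyte": {"KNG1": 8.0, "IL6R": 2.5, "IL6ST": 2.5, "PCK1": 6.0},
    "endothelial cell": {"KNG1": 0.8, "IL6R": 4.0, "IL6ST": 3.5, "PCK1": 0.4},
    "cholangiocyte": {"KNG1": 0.5, "IL6R": 3.0, "IL6ST": 3.0, "PCK1": 0.3},
    "kupffer cell": {},
    "t cell": {"KNG1": 0.3},
}

LIVER_CELLS = {
    "hepatocyte": 120,
    "endothelial cell": 80,
    "cholangiocyte": 60,
    "kupffer cell": 60,
    "t cell": 60,
}


def build_demo_liver_sc(fixtures: TableFixtures, seed: int = 0) -> CountMatrix:
    """Healthy liver single-cell matrix over the pair-partner genes.

    Only KNG1, IL6R/IL6ST and PCK1 are substantially expressed (in the
    cell types of ``LIVER_PROFILES``); all other ligand-receptor genes
    sit at a near-zero baseline so cross-organ filtering drops them.
    """
    real_pairs = [p for p in fixtures.lr_pairs if p not in fixtures.decoy_pairs]
    partner_genes = sorted(
        {g for p in real_pairs for g in p.ligand_subunits}
        | {g for p in real_pairs for g in p.receptor_subunits}
    )
    housekeeping = [f"HK{i:03d}" for i in range(20)]
    genes = partner_genes + ["PCK1"] + housekeeping
    profiles = {
        cell_type: {**{g: 5.0 for g in housekeeping}, **means}
        for cell_type, means in LIVER_PROFILES.items()
    }
    spec = ExpressionSimSpec(
        n_genes=len(genes),
        gene_names=genes,
        base_mean=0.02,
        dispersion=0.5,
        n_cells_per_type=dict(LIVER_CELLS),
        organ="liver",
        cell_type_profiles=profiles,
        mito_fraction=0.04,
        n_high_mito=10,
        seed=seed + 21,
    )
    return simulate_counts(spec, mode="single_cell")


LUNG_CELLS = {
    "macrophage": 80,
    "fibroblast": 60,
    "endothelial cell": 60,
    "dendritic cell": 50,
    "at1 cell": 50,
    "at2 cell": 60,
    "t/nkt cell": 50,
    "monocyte": 50,
    "ciliated cell": 40,
    "club cell": 40,
}

#: Baseline (healthy) lung means for the mechanism genes.
LUNG_BASELINE = {
    "BDKRB1": 0.3,
    "IL6": 0.2,
    "CALM1": 3.0,
    "CALM2": 3.0,
    "CALM3": 3.0,
}
LUNG_OVERRIDES = {
    "endothelial cell": {"IL6": 1.5},
    "fibroblast": {"IL6": 1.5},
    "dendritic cell": {"IL6": 0.8},
}

#: Planted IPF-vs-control per-cell-type effects (gene, log2fc, cell type).
LUNG_PLANTED_DE = [
    ("BDKRB1", 10.0, "macrophage"),
    ("CALM1", 1.5, "macrophage"),
    ("CALM2", 1.5, "macrophage"),
    ("CALM3", 1.5, "macrophage"),
    ("CALM1", 1.0, "fibroblast"),
    ("CALM2", 1.0, "fibroblast"),
    ("IL6", -1.2, "endothelial cell"),
    ("IL6", -1.2, "dendritic cell"),
    ("IL6", -0.9, "macrophage"),
]


def build_demo_lung_sc(seed: int = 0) -> tuple[CountMatrix, CountMatrix]:
    """(IPF, control) lung single-cell matrices with planted cell-type DE.

    The headline planted effect is the ~1000-fold (2^10) BDKRB1
    upregulation confined to macrophages, with milder calmodulin
    upregulation and IL6 downregulation in selected cell types.
    """
    housekeeping = [f"HK{i:03d}" for i in range(20)]
    genes = sorted(LUNG_BASELINE) + housekeeping
    profiles = {}
    for cell_type in LUNG_CELLS:
        means = {g: 5.0 for g in housekeeping}
        means.update(LUNG_BASELINE)
        means.update(LUNG_OVERRIDES.get(cell_type, {}))
        profiles[cell_type] = means
    common = dict(
        n_genes=len(genes),
        gene_names=genes,
        base_mean=0.1,
        dispersion=0.4,
        n_cells_per_type=dict(LUNG_CELLS),
        organ="lung",
        cell_type_profiles=profiles,
        mito_fraction=0.04,
        n_high_mito=8,
    )
    ipf = simulate_counts(
        ExpressionSimSpec(**common, planted_de=list(LUNG_PLANTED_DE), seed=seed + 31),
        mode="single_cell",
    )
    control = simulate_counts(
        ExpressionSimSpec(**common, seed=seed + 32), mode="single_cell"
    )
    return ipf, control
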