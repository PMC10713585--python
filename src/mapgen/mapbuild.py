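"""Mechanism-map assembly and the end-to-end pipeline.

The map is an organ-annotated directed graph. Nodes are gene (or gene
complex) nodes localized to an organ, with supporting cell-type
evidence; edges are direct ligand-receptor interactions across organs
(``direct_lr``), pathway-mediated links within an organ (``pathway``,
labeled with the supporting KEGG pathway ids), or open links
(``unknown``) marking a feature with no pathway route back to a map
ligand — the "?" of the generated mechanism.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field, asdict

import networkx as nx
import pandas as pd

from . import bridge as br
from . import diffexp as de
from . import enrichment as en
from . import io as mio
from . import kegg as kg
from . import scenarios
from . import synthetic as syn
from . import topics as tp

logger = logging.getLogger(__name__)

DIRECT_LR = "direct_lr"
PATHWAY = "pathway"
UNKNOWN = "unknown"


@dataclass
class MapNode:
    key: str
    genes: tuple[str, ...]
    organ: str
    role: str  # ligand | receptor | feature
    cell_type_evidence: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def label(self) -> str:
        return "/".join(self.genes)


@dataclass
class MapEdge:
    source: str
    target: str
    kind: str  # direct_lr | pathway | unknown
    pathway_ids: tuple[str, ...] = ()
    provenance: tuple[str, ...] = ()


@dataclass
class MechanismMap:
    """The assembled inter-organ mechanism graph."""

    nodes: dict[str, MapNode]
    edges: list[MapEdge]

    def edge(self, source: str, target: str) -> MapEdge | None:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        return None

    def validate(self) -> None:
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"dangling edge {e.source}->{e.target}")
            if e.kind == UNKNOWN and e.pathway_ids:
                raise ValueError("unknown edges carry no pathway ids")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for key, node in sorted(self.nodes.items()):
            g.add_node(
                key,
                genes=";".join(node.genes),
                organ=node.organ,
                role=node.role,
                cell_types=";".join(ct for ct, _, _ in node.cell_type_evidence),
            )
        for e in self.edges:
            g.add_edge(
                e.source,
                e.target,
                kind=e.kind,
                pathways=";".join(e.pathway_ids),
                provenance=";".join(e.provenance),
            )
        return g

    def to_dict(self) -> dict:
        return {
            "nodes": [asdict(self.nodes[k]) for k in sorted(self.nodes)],
            "edges": sorted(
                (asdict(e) for e in self.edges),
                key=lambda d: (d["source"], d["target"], d["kind"]),
            ),
        }

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True, default=list)
            fh.write("\n")


def _node_key(label: str, organ: str) -> str:
    return f"{label}@{organ}"


def _top_cell_types(
    summaries_by_organ: dict[str, pd.DataFrame], organ: str, genes: tuple[str, ...]
) -> list[tuple[str, float, float]]:
    summary = summaries_by_organ.get(organ)
    if summary is None:
        return []
    rows = summary[summary["gene"].isin(genes)]
    if rows.empty:
        return []
    by_type = (
        rows.groupby("cell_type")[["frac_expressing", "mean_log_cp10k"]]
        .mean()
        .sort_values("mean_log_cp10k", ascending=False)
        .head(3)
    )
    return [
        (str(ct), float(row["frac_expressing"]), float(row["mean_log_cp10k"]))
        for ct, row in by_type.iterrows()
    ]


def assemble_map(
    retained: list[br.CrossOrganPair],
    hits: list[kg.TargetHit],
    summaries_by_organ: dict[str, pd.DataFrame],
    primary_organ: str = "lung",
    partner_organ: str = "liver",
) -> MechanismMap:
    """Fuse bridging survivors and pathway hits into the mechanism map.

    Direct ligand-receptor edges cross the organs; downstream pathway
    hits add feature nodes in the receptor's organ, upstream hits in
    the ligand's organ. Feature genes with identical connectivity are
    merged into one complex-style node. Each feature node lacking an
    outgoing pathway route to a map ligand receives an ``unknown`` edge
    toward the same-organ ligand(s), closing the loop as an open
    question.
    """
    nodes: dict[str, MapNode] = {}
    edges: dict[tuple[str, str, str], MapEdge] = {}

    if not retained:
        logger.warning("no cross-organ pairs retained; the map is empty")
        return MechanismMap({}, [])

    pair_nodes: dict = {}
    for cand in retained:
        pair = cand.pair
        if cand.direction == br.DEGENE_IS_LIGAND:
            lig_organ, rec_organ = primary_organ, partner_organ
        else:
            lig_organ, rec_organ = partner_organ, primary_organ
        lig_key = _node_key(pair.ligand_label, lig_organ)
        rec_key = _node_key(pair.receptor_label, rec_organ)
        nodes.setdefault(
            lig_key, MapNode(lig_key, pair.ligand_subunits, lig_organ, "ligand")
        )
        nodes.setdefault(
            rec_key, MapNode(rec_key, pair.receptor_subunits, rec_organ, "receptor")
        )
        edges.setdefault(
            (lig_key, rec_key, DIRECT_LR),
            MapEdge(lig_key, rec_key, DIRECT_LR,
                    provenance=(f"pair:{pair.ligand_label}-{pair.receptor_label}",)),
        )
        pair_nodes[pair.key] = (lig_key, rec_key, lig_organ, rec_organ)

    matched_hits = []
    for hit in hits:
        for cand in retained:
            pair = cand.pair
            if hit.ligand != pair.ligand_label:
                continue
            if hit.receptor not in pair.receptor_subunits and (
                hit.receptor != pair.receptor_label
            ):
                continue
            matched_hits.append((hit, pair.key))
            break

    for hit, pair_key in matched_hits:
        lig_key, rec_key, lig_organ, rec_organ = pair_nodes[pair_key]
        if hit.position == kg.DOWNSTREAM:
            organ = rec_organ
            feat_key = _node_key(hit.feature, organ)
            source, target = rec_key, feat_key
        else:
            organ = lig_organ
            feat_key = _node_key(hit.feature, organ)
            source, target = feat_key, lig_key
        nodes.setdefault(feat_key, MapNode(feat_key, (hit.feature,), organ, "feature"))
        edge = edges.setdefault(
            (source, target, PATHWAY), MapEdge(source, target, PATHWAY)
        )
        if hit.pathway_id not in edge.pathway_ids:
            edge.pathway_ids = tuple(sorted(edge.pathway_ids + (hit.pathway_id,)))
        provenance = f"hit:{hit.pathway_id}:{hit.ligand}-{hit.receptor}:{hit.feature}"
        if provenance not in edge.provenance:
            edge.provenance = edge.provenance + (provenance,)

    # Merge feature genes with identical connectivity into one node.
    def signature(key: str):
        incoming = frozenset(
            (e.source, e.kind, e.pathway_ids)
            for e in edges.values() if e.target == key
        )
        outgoing = frozenset(
            (e.target, e.kind, e.pathway_ids)
            for e in edges.values() if e.source == key
        )
        return (nodes[key].organ, incoming, outgoing)

    feature_keys = [k for k, n in nodes.items() if n.role == "feature"]
    by_signature: dict = {}
    for key in sorted(feature_keys):
        by_signature.setdefault(signature(key), []).append(key)
    remap: dict[str, str] = {}
    for keys in by_signature.values():
        if len(keys) < 2:
            continue
        genes = tuple(sorted(g for k in keys for g in nodes[k].genes))
        organ = nodes[keys[0]].organ
        merged_key = _node_key("/".join(genes), organ)
        for k in keys:
            remap[k] = merged_key
            del nodes[k]
        nodes[merged_key] = MapNode(merged_key, genes, organ, "feature")
    if remap:
        merged_edges: dict[tuple[str, str, str], MapEdge] = {}
        for e in edges.values():
            source = remap.get(e.source, e.source)
            target = remap.get(e.target, e.target)
            key = (source, target, e.kind)
            if key in merged_edges:
                prior = merged_edges[key]
                prior.pathway_ids = tuple(
                    sorted(set(prior.pathway_ids) | set(e.pathway_ids))
                )
                prior.provenance = tuple(
                    dict.fromkeys(prior.provenance + e.provenance)
                )
            else:
                merged_edges[key] = MapEdge(
                    source, target, e.kind, e.pathway_ids, e.provenance
                )
        edges = merged_edges

    # Open "?" edges: feature nodes without a pathway route to a map ligand.
    ligand_keys = {k for k, n in nodes.items() if n.role == "ligand"}
    for key in sorted(k for k, n in nodes.items() if n.role == "feature"):
        has_route = any(
            e.source == key and e.kind == PATHWAY and e.target in ligand_keys
            for e in edges.values()
        )
        if has_route:
            continue
        for lig_key in sorted(ligand_keys):
            if nodes[lig_key].organ == nodes[key].organ:
                edges.setdefault(
                    (key, lig_key, UNKNOWN),
                    MapEdge(key, lig_key, UNKNOWN, provenance=("open-question",)),
                )

    for node in nodes.values():
        node.cell_type_evidence = _top_cell_types(
            summaries_by_organ, node.organ, node.genes
        )

    result = MechanismMap(nodes, sorted(edges.values(),
                                        key=lambda e: (e.source, e.target, e.kind)))
    result.validate()
    return result


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run.

    With ``synthetic=True`` every input is generated from ``seed``.
    Otherwise file paths must be supplied; ``degenes_path`` and
    ``latent_path`` optionally bypass the expression and topic stages
    with precomputed gene lists (fixture-driven runs).
    """

    out_dir: str = "mapgen_run"
    synthetic: bool = True
    seed: int = 0
    # model / filter parameters
    n_topics: int = 6
    n_iter: int = 400
    burn_in: int = 200
    alpha_topic: float | None = None
    beta_topic: float = 0.01
    top_fraction: float = 0.4
    exclusion_patterns: list[str] = field(
        default_factory=lambda: list(tp.DEFAULT_EXCLUSION_PATTERNS)
    )
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    q_threshold: float = 0.05
    min_frac: float = 0.2
    qc_min_genes: int = 5
    qc_max_pct_mito: float = 20.0
    primary_organ: str = "lung"
    partner_organ: str | None = None  # None: top enriched organ
    # file inputs (synthetic=False)
    corpus_path: str | None = None
    query_path: str | None = None
    annotation_path: str | None = None
    bulk_prefix: str | None = None
    liver_sc_prefix: str | None = None
    lung_sc_ipf_prefix: str | None = None
    lung_sc_control_prefix: str | None = None
    lr_table_path: str | None = None
    kgml_paths: list[str] = field(default_factory=list)
    symbol_map_path: str | None = None
    degenes_path: str | None = None
    latent_path: str | None = None


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def _read_gene_list(path) -> list[str]:
    lines = pathlib.Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines[1:] if ln.strip()]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute topics -> enrichment -> DE -> bridge -> mine -> map.

    Writes every intermediate table plus the final map (GraphML and
    JSON) and a manifest under ``config.out_dir``; returns the artifact
    bundle in memory. Deterministic under a fixed seed.
    """
    out = pathlib.Path(config.out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    manifest: dict = {
        "package": "mapgen",
        "version": _version(),
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items()
            if not k.endswith("_path") and k not in ("kgml_paths", "out_dir")
        },
        "stages": {},
    }

    # ---- simulate / load inputs -------------------------------------------
    @_stage("simulate")
    def _inputs():
        fixtures = syn.build_table_fixtures()
        if config.synthetic:
            corpus, query, truth, latent_pool = scenarios.build_demo_corpus(
                fixtures, config.seed
            )
            ae_background = sorted(
                {g for r in corpus for g in r.modality_genes["Ae"]}
            )
            annotation = scenarios.build_demo_annotation(
                ae_background, latent_pool, config.seed
            )
            bulk = scenarios.build_demo_bulk(fixtures, config.seed)
            liver = scenarios.build_demo_liver_sc(fixtures, config.seed)
            lung_ipf, lung_ctrl = scenarios.build_demo_lung_sc(config.seed)
            mio.write_gmt(corpus, out / "inputs" / "corpus.gmt")
            mio.write_gmt([query], out / "inputs" / "query.gmt")
            mio.write_annotation(annotation, out / "inputs" / "annotation.tsv")
            mio.write_counts(bulk, out / "inputs" / "bulk")
            mio.write_counts(liver, out / "inputs" / "liver_sc")
            mio.write_counts(lung_ipf, out / "inputs" / "lung_sc_ipf")
            mio.write_counts(lung_ctrl, out / "inputs" / "lung_sc_control")
            syn.write_table_fixtures(fixtures, out / "inputs" / "tables")
            lr_pairs = fixtures.lr_pairs
            kgml_sources = {
                name: out / "inputs" / "tables" / "kgml" / f"{name}.xml"
                for name in fixtures.kgml
                if name != "group_demo"
            }
            symbol_map = fixtures.symbol_map
        else:
            corpus = mio.read_gmt(config.corpus_path) if config.corpus_path else None
            query = mio.read_gmt(config.query_path)[0] if config.query_path else None
            annotation = (
                mio.read_annotation(config.annotation_path)
                if config.annotation_path else None
            )
            bulk = mio.read_counts(config.bulk_prefix) if config.bulk_prefix else None
            liver = (
                mio.read_counts(config.liver_sc_prefix)
                if config.liver_sc_prefix else None
            )
            lung_ipf = (
                mio.read_counts(config.lung_sc_ipf_prefix)
                if config.lung_sc_ipf_prefix else None
            )
            lung_ctrl = (
                mio.read_counts(config.lung_sc_control_prefix)
                if config.lung_sc_control_prefix else None
            )
            lr_pairs = None
            kgml_sources = {
                pathlib.Path(p).stem: pathlib.Path(p) for p in config.kgml_paths
            }
            symbol_map = (
                mio.read_symbol_map(config.symbol_map_path)
                if config.symbol_map_path else {}
            )
        return (corpus, query, annotation, bulk, liver, lung_ipf, lung_ctrl,
                lr_pairs, kgml_sources, symbol_map)

    (corpus, query, annotation, bulk, liver, lung_ipf, lung_ctrl,
     lr_pairs, kgml_sources, symbol_map) = _inputs()

    # ---- topics ------------------------------------------------------------
    @_stage("topics")
    def _topics():
        if config.latent_path:
            genes = _read_gene_list(config.latent_path)
            return None, genes, None
        model = tp.fit(
            corpus, K=config.n_topics, alpha=config.alpha_topic,
            beta=config.beta_topic, n_iter=config.n_iter,
            burn_in=config.burn_in, seed=config.seed,
        )
        generated = tp.impute_modality(model, query, "Ae", seed=config.seed + 1)
        latent = tp.extract_latent_features(
            generated, query, corpus,
            exclusion_patterns=config.exclusion_patterns,
            top_fraction=config.top_fraction,
        )
        relatedness = tp.disease_relatedness(latent, corpus)
        features = pd.DataFrame(
            [
                {"gene": f.gene, "modality": f.modality, "score": f.score,
                 "n_sources": len(f.source_diseases)}
                for f in latent.features
            ]
        )
        features.to_csv(out / "latent_features.tsv", sep="\t", index=False)
        relatedness.to_csv(out / "disease_relatedness.tsv", sep="\t", index=False)
        return latent, latent.genes(), relatedness

    latent_set, latent_genes, relatedness = _topics()
    manifest["stages"]["topics"] = {"n_latent_features": len(latent_genes)}

    # ---- enrichment --------------------------------------------------------
    @_stage("enrich")
    def _enrich():
        if annotation is None:
            return None, None, config.partner_organ or "liver"
        table = en.AnnotationTable.from_frame(annotation)
        organ = en.enrich(set(latent_genes), table, "organ", config.q_threshold)
        cells = en.enrich(set(latent_genes), table, "cell_type", config.q_threshold)
        organ.to_csv(out / "enrichment_organ.tsv", sep="\t", index=False)
        cells.to_csv(out / "enrichment_cell_type.tsv", sep="\t", index=False)
        partner = config.partner_organ or str(organ.iloc[0]["context"])
        return organ, cells, partner

    organ_enrich, cell_enrich, partner_organ = _enrich()
    manifest["stages"]["enrich"] = {"partner_organ": partner_organ}

    # ---- bulk differential expression -------------------------------------
    @_stage("de")
    def _de():
        if config.degenes_path:
            return None, _read_gene_list(config.degenes_path)
        result = de.nb_de_test(
            bulk, mode="bulk", lfc_threshold=config.lfc_threshold,
            alpha=config.alpha, test_level="IPF", ref_level="nonIPF",
        )
        result.to_csv(out / "bulk_de.tsv", sep="\t", index=False)
        return result, sorted(result.loc[result["is_degene"], "gene"])

    de_table, degenes = _de()
    manifest["stages"]["de"] = {"n_degenes": len(degenes)}

    # ---- single-cell summaries and per-cell-type DE ------------------------
    @_stage("summaries")
    def _summaries():
        summaries = {}
        if liver is not None:
            liver_qc = de.qc_filter_cells(
                liver, config.qc_min_genes, config.qc_max_pct_mito
            )
            summaries["liver"] = de.summarize_expression(liver_qc)
            summaries["liver"].to_csv(
                out / "summary_liver.tsv", sep="\t", index=False
            )
        celltype_de = {}
        if lung_ipf is not None and lung_ctrl is not None:
            ipf_qc = de.qc_filter_cells(
                lung_ipf, config.qc_min_genes, config.qc_max_pct_mito
            )
            ctrl_qc = de.qc_filter_cells(
                lung_ctrl, config.qc_min_genes, config.qc_max_pct_mito
            )
            summaries["lung"] = de.summarize_expression(ctrl_qc)
            summaries["lung"].to_csv(out / "summary_lung.tsv", sep="\t", index=False)
            celltype_de = de.per_celltype_de(ipf_qc, ctrl_qc)
            stacked = pd.concat(
                [t.assign(cell_type=ct) for ct, t in celltype_de.items()],
                ignore_index=True,
            )
            stacked.to_csv(out / "lung_celltype_de.tsv", sep="\t", index=False)
        return summaries, celltype_de

    summaries_by_organ, celltype_de = _summaries()
    manifest["stages"]["summaries"] = {
        "organs": sorted(summaries_by_organ),
        "n_celltype_contrasts": len(celltype_de),
    }

    # ---- ligand-receptor bridging ------------------------------------------
    @_stage("bridge")
    def _bridge():
        pairs = lr_pairs
        if pairs is None:
            if not config.lr_table_path:
                raise FileNotFoundError("no ligand-receptor table supplied")
            pairs = mio.read_lr_table(config.lr_table_path)
        lig = br.identify_ligands(degenes, pairs)
        rec = br.identify_receptors(degenes, pairs)
        br.bridge_table(lig).to_csv(out / "step2_pairs.tsv", sep="\t", index=False)
        br.bridge_table(rec).to_csv(out / "step4_pairs.tsv", sep="\t", index=False)
        retained = []
        if partner_organ in summaries_by_organ:
            retained = br.cross_organ_candidates(
                lig, summaries_by_organ[partner_organ], partner_organ,
                config.min_frac,
            ) + br.cross_organ_candidates(
                rec, summaries_by_organ[partner_organ], partner_organ,
                config.min_frac,
            )
        return lig, rec, retained

    lig_bridge, rec_bridge, retained = _bridge()
    manifest["stages"]["bridge"] = {
        "n_ligand_pairs": len(lig_bridge.pairs),
        "n_receptor_pairs": len(rec_bridge.pairs),
        "n_cross_organ": len(retained),
    }

    # ---- KEGG mining --------------------------------------------------------
    @_stage("mine")
    def _mine():
        graphs = [
            kg.parse_kgml(str(path), symbol_map)
            for _, path in sorted(kgml_sources.items())
        ]
        hits = kg.find_targets(
            graphs, lig_bridge.pairs + rec_bridge.pairs, latent_genes
        )
        kg.hits_table(hits).to_csv(out / "pathway_hits.tsv", sep="\t", index=False)
        return hits

    hits = _mine()
    manifest["stages"]["mine"] = {"n_hits": len(hits)}

    # ---- map ----------------------------------------------------------------
    @_stage("map")
    def _map():
        mech = assemble_map(
            retained, hits, summaries_by_organ,
            primary_organ=config.primary_organ, partner_organ=partner_organ,
        )
        mech.write_graphml(out / "mechanism_map.graphml")
        mech.write_json(out / "mechanism_map.json")
        return mech

    mech_map = _map()
    manifest["stages"]["map"] = {
        "n_nodes": len(mech_map.nodes),
        "n_edges": len(mech_map.edges),
        "n_unknown_edges": sum(1 for e in mech_map.edges if e.kind == UNKNOWN),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    artifacts.update(
        latent=latent_set, latent_genes=latent_genes, relatedness=relatedness,
        organ_enrichment=organ_enrich, cell_enrichment=cell_enrich,
        de_table=de_table, degenes=degenes, summaries=summaries_by_organ,
        celltype_de=celltype_de, ligand_bridge=lig_bridge,
        receptor_bridge=rec_bridge, retained=retained, hits=hits,
        map=mech_map, manifest=manifest, partner_organ=partner_organ,
    )
    return artifacts


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("mapgen")
    except Exception:  # pragma: no cover
        return "unknown"
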