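"""Mechanism-map assembly and pipeline orchestration."""

import pandas as pd
import pytest

from mapgen import bridge as br
from mapgen import kegg as kg
from mapgen import mapbuild as mb
from mapgen.containers import LRPair


def _summaries():
    liver = pd.DataFrame(
        [
            ("KNG1", "hepatocyte", "liver", 0.9, 5.6),
            ("IL6R", "endothelial cell", "liver", 0.7, 2.4),
            ("IL6ST", "endothelial cell", "liver", 0.7, 2.2),
            ("PCK1", "hepatocyte", "liver", 0.8, 4.8),
        ],
        columns=["gene", "cell_type", "organ", "frac_expressing",
                 "mean_log_cp10k"],
    )
    lung = pd.DataFrame(
        [
            ("BDKRB1", "macrophage", "lung", 0.4, 1.2),
            ("IL6", "endothelial cell", "lung", 0.5, 1.5),
            ("CALM1", "macrophage", "lung", 0.8, 2.8),
            ("CALM2", "macrophage", "lung", 0.8, 2.7),
            ("CALM3", "macrophage", "lung", 0.8, 2.9),
        ],
        columns=["gene", "cell_type", "organ", "frac_expressing",
                 "mean_log_cp10k"],
    )
    return {"liver": liver, "lung": lung}


def _retained():
    il6 = LRPair(("IL6",), ("IL6R", "IL6ST"), "KEGG: hsa04060")
    kng1 = LRPair(("KNG1",), ("BDKRB1",), "KEGG: hsa04080")
    return [
        br.CrossOrganPair(il6, br.DEGENE_IS_LIGAND,
                          {"IL6R": ("endothelial cell", 0.7, 2.4),
                           "IL6ST": ("endothelial cell", 0.7, 2.2)}),
        br.CrossOrganPair(kng1, br.DEGENE_IS_RECEPTOR,
                          {"KNG1": ("hepatocyte", 0.9, 5.6)}),
    ]


def _hits(with_pck1=True):
    hits = [
        kg.TargetHit("hsa05200", "KNG1", "BDKRB1", f, kg.DOWNSTREAM)
        for f in ("CALM1", "CALM2", "CALM3")
    ] + [
        kg.TargetHit("hsa05163", "IL6", "IL6R", f, kg.UPSTREAM)
        for f in ("CALM1", "CALM2", "CALM3")
    ]
    if with_pck1:
        hits.append(kg.TargetHit("hsa04151", "IL6", "IL6R", "PCK1",
                                 kg.DOWNSTREAM))
    # an unrelated hit whose pair was not retained must be ignored
    hits.append(kg.TargetHit("hsa04062", "CXCL9", "CXCR3", "ELMO1",
                             kg.DOWNSTREAM))
    return hits


EXPECTED_CHAIN = [
    ("KNG1@liver", "BDKRB1@lung", mb.DIRECT_LR, ()),
    ("BDKRB1@lung", "CALM1/CALM2/CALM3@lung", mb.PATHWAY, ("hsa05200",)),
    ("CALM1/CALM2/CALM3@lung", "IL6@lung", mb.PATHWAY, ("hsa05163",)),
    ("IL6@lung", "IL6R/IL6ST@liver", mb.DIRECT_LR, ()),
    ("IL6R/IL6ST@liver", "PCK1@liver", mb.PATHWAY, ("hsa04151",)),
    ("PCK1@liver", "KNG1@liver", mb.UNKNOWN, ()),
]


class TestAssembleMap:
    def test_fixture_chain_is_reproduced(self):
        mech = mb.assemble_map(_retained(), _hits(), _summaries())
        edges = {(e.source, e.target, e.kind, e.pathway_ids) for e in mech.edges}
        assert edges == set(EXPECTED_CHAIN)
        assert len(mech.edges) == 6
        unknown = [e for e in mech.edges if e.kind == mb.UNKNOWN]
        assert len(unknown) == 1

    def test_cell_type_evidence_localizes_nodes(self):
        mech = mb.assemble_map(_retained(), _hits(), _summaries())
        kng1 = mech.nodes["KNG1@liver"]
        assert kng1.cell_type_evidence[0][0] == "hepatocyte"
        calm = mech.nodes["CALM1/CALM2/CALM3@lung"]
        assert calm.genes == ("CALM1", "CALM2", "CALM3")
        assert calm.cell_type_evidence[0][0] == "macrophage"

    def test_no_hits_gives_direct_edges_only(self):
        mech = mb.assemble_map(_retained(), [], _summaries())
        assert all(e.kind == mb.DIRECT_LR for e in mech.edges)
        assert len(mech.edges) == 2
        assert all(n.role != "feature" for n in mech.nodes.values())

    def test_provenance_resolves_for_every_edge(self):
        mech = mb.assemble_map(_retained(), _hits(), _summaries())
        for edge in mech.edges:
            assert edge.provenance
            if edge.kind == mb.PATHWAY:
                assert all(p.startswith("hit:") for p in edge.provenance)
            elif edge.kind == mb.DIRECT_LR:
                assert all(p.startswith("pair:") for p in edge.provenance)

    def test_organs_partition_nodes_and_graph_is_well_formed(self):
        mech = mb.assemble_map(_retained(), _hits(), _summaries())
        mech.validate()
        assert {n.organ for n in mech.nodes.values()} == {"lung", "liver"}

    def test_deleting_a_feature_deletes_exactly_its_edges(self):
        full = mb.assemble_map(_retained(), _hits(), _summaries())
        reduced = mb.assemble_map(
            _retained(), _hits(with_pck1=False), _summaries()
        )
        assert "PCK1@liver" not in reduced.nodes
        full_edges = {(e.source, e.target, e.kind) for e in full.edges}
        reduced_edges = {(e.source, e.target, e.kind) for e in reduced.edges}
        missing = full_edges - reduced_edges
        assert missing == {
            ("IL6R/IL6ST@liver", "PCK1@liver", mb.PATHWAY),
            ("PCK1@liver", "KNG1@liver", mb.UNKNOWN),
        }

    def test_empty_bridges_give_empty_map(self, caplog):
        with caplog.at_level("WARNING"):
            mech = mb.assemble_map([], _hits(), _summaries())
        assert mech.nodes == {}
        assert mech.edges == []

    def test_serialization_round_trip(self, tmp_path):
        import json

        import networkx as nx

        mech = mb.assemble_map(_retained(), _hits(), _summaries())
        mech.write_json(tmp_path / "map.json")
        mech.write_graphml(tmp_path / "map.graphml")
        loaded = json.loads((tmp_path / "map.json").read_text())
        assert {n["key"] for n in loaded["nodes"]} == set(mech.nodes)
        graph = nx.read_graphml(tmp_path / "map.graphml")
        assert set(graph.nodes) == set(mech.nodes)


class TestPipeline:
    def test_fixture_driven_run_reproduces_the_chain(self, fixtures, tmp_path):
        from mapgen import synthetic as syn

        paths = syn.write_table_fixtures(fixtures, tmp_path / "tables")
        config = mb.PipelineConfig(
            out_dir=str(tmp_path / "run"),
            synthetic=True,
            seed=3,
            degenes_path=paths["degenes"],
            latent_path=paths["latent_features"],
        )
        artifacts = mb.run_pipeline(config)
        mech = artifacts["map"]
        edges = {(e.source, e.target, e.kind) for e in mech.edges}
        assert {(s, t, k) for s, t, k, _ in EXPECTED_CHAIN} == edges

    def test_missing_lr_table_names_the_bridge_stage(self, fixtures, tmp_path):
        from mapgen import synthetic as syn

        paths = syn.write_table_fixtures(fixtures, tmp_path / "tables")
        config = mb.PipelineConfig(
            out_dir=str(tmp_path / "run"),
            synthetic=False,
            degenes_path=paths["degenes"],
            latent_path=paths["latent_features"],
        )
        with pytest.raises(mb.PipelineError) as err:
            mb.run_pipeline(config)
        assert err.value.stage == "bridge"
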