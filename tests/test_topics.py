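"""Topic model: recovery of planted structure, imputation, extraction."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mapgen import synthetic as syn
from mapgen import topics as tp
from mapgen.containers import DiseaseRecord


def _planted_corpus(**kw):
    base = dict(
        n_diseases=40,
        n_genes_per_modality={"Ae": 60, "Bm": 60, "Gv": 60},
        n_topics_true=2,
        genes_per_disease=12,
        noise_rate=0.0,
        seed=11,
    )
    base.update(kw)
    return syn.simulate_disease_corpus(syn.CorpusSpec(**base))


class TestFit:
    def test_single_disease_single_topic_theta_is_one(self):
        rec = DiseaseRecord("D1", "Solo", {"Ae": {"A", "B"}, "Bm": {"C"}})
        model = tp.fit([rec], K=1, n_iter=20, burn_in=10, seed=0)
        assert model.theta.shape == (1, 1)
        assert model.theta[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_planted_partition_recovered_exactly(self):
        corpus, truth = _planted_corpus()
        model = tp.fit(corpus, K=2, n_iter=200, burn_in=100, seed=2)
        labels = model.theta.argmax(axis=1)
        true = [truth["topic_assignments"][r.disease_id][0] for r in corpus]
        assert adjusted_rand_score(true, labels) == 1.0

    def test_same_seed_identical_estimates(self):
        corpus, _ = _planted_corpus()
        a = tp.fit(corpus, K=2, n_iter=60, burn_in=30, seed=5)
        b = tp.fit(corpus, K=2, n_iter=60, burn_in=30, seed=5)
        assert np.array_equal(a.theta, b.theta)
        for mod in tp.MODALITIES:
            assert np.array_equal(a.phi[mod], b.phi[mod])

    def test_probability_normalization(self):
        corpus, _ = _planted_corpus()
        model = tp.fit(corpus, K=3, n_iter=60, burn_in=30, seed=5)
        assert np.allclose(model.theta.sum(axis=1), 1.0, atol=1e-9)
        for mod in tp.MODALITIES:
            assert np.allclose(model.phi[mod].sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize(
        "kw", [{"K": 0}, {"K": 99}, {"alpha": -1.0}, {"beta": 0.0}]
    )
    def test_invalid_arguments_rejected(self, kw):
        corpus, _ = _planted_corpus()
        with pytest.raises(ValueError):
            tp.fit(corpus, n_iter=10, burn_in=5, **{"K": 2, **kw})

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            tp.fit([], K=1)


class TestImpute:
    def test_single_topic_ranking_is_frequency_ranking(self):
        corpus, _ = _planted_corpus(n_topics_true=1, noise_rate=0.3, seed=3)
        model = tp.fit(corpus, K=1, n_iter=40, burn_in=20, seed=3)
        query = DiseaseRecord(
            "Q", "query", {"Bm": set(list(model.vocab["Bm"])[:5])}
        )
        feats = tp.impute_modality(model, query, "Ae", seed=4)
        freq = {
            g: len(model.membership["Ae"].get(g, ())) for g in model.vocab["Ae"]
        }
        scores = [freq[f.gene] for f in feats]
        assert scores == sorted(scores, reverse=True)

    def test_planted_query_top_genes_come_from_its_topic(self):
        corpus, truth = _planted_corpus()
        model = tp.fit(corpus, K=2, n_iter=200, burn_in=100, seed=6)
        pool_bm = set(truth["pools"]["Bm"][0])
        query = DiseaseRecord("Q", "query", {"Bm": set(list(pool_bm)[:10])})
        feats = tp.impute_modality(model, query, "Ae", seed=7)
        pool_ae = set(truth["pools"]["Ae"][0])
        top = [f.gene for f in feats[: len(pool_ae) // 2]]
        assert set(top) <= pool_ae

    def test_scores_sum_to_one(self):
        corpus, _ = _planted_corpus()
        model = tp.fit(corpus, K=2, n_iter=60, burn_in=30, seed=8)
        query = DiseaseRecord("Q", "q", {"Bm": set(list(model.vocab["Bm"])[:8])})
        feats = tp.impute_modality(model, query, "Ae", seed=9)
        assert sum(f.score for f in feats) == pytest.approx(1.0, abs=1e-9)
        assert all("Q" not in f.source_diseases for f in feats)

    def test_error_when_modality_present_or_unseen_vocab(self):
        corpus, _ = _planted_corpus()
        model = tp.fit(corpus, K=2, n_iter=40, burn_in=20, seed=8)
        present = DiseaseRecord("Q", "q", {"Ae": {"x"}, "Bm": {"y"}})
        with pytest.raises(ValueError):
            tp.impute_modality(model, present, "Ae")
        unseen = DiseaseRecord("Q", "q", {"Bm": {"NOT-IN-VOCAB"}})
        with pytest.raises(ValueError):
            tp.impute_modality(model, unseen, "Ae")


class TestExtractLatent:
    def _setup(self):
        corpus = [
            DiseaseRecord("D1", "Idiopathic Pulmonary Fibrosis", {"Ae": {"g1"}}),
            DiseaseRecord("D2", "Diabetes Mellitus", {"Ae": {"g1", "g2"}}),
            DiseaseRecord("D3", "Pneumonia", {"Ae": {"g3"}}),
            DiseaseRecord("D4", "Respiratory Failure", {"Ae": {"g2"}}),
        ]
        query = DiseaseRecord("Q", "query", {"Bm": {"g9"}, "Gv": {"g4"}})
        feats = [
            tp.GeneratedFeature("g1", "Ae", 0.5, frozenset({"D1", "D2"})),
            tp.GeneratedFeature("g2", "Ae", 0.3, frozenset({"D2", "D4"})),
            tp.GeneratedFeature("g3", "Ae", 0.15, frozenset({"D3"})),
            tp.GeneratedFeature("g4", "Ae", 0.05, frozenset({"D2"})),
        ]
        return corpus, query, feats

    def test_name_exclusion_and_survival(self):
        corpus, query, feats = self._setup()
        latent = tp.extract_latent_features(
            feats, query, corpus, top_fraction=1.0
        )
        genes = {f.gene for f in latent.features}
        # g1 survives via Diabetes Mellitus; g3's only source (Pneumonia,
        # prefix wildcard) is excluded; g4 is in the query's own Gv set.
        assert genes == {"g1", "g2"}
        by_gene = {f.gene: f for f in latent.features}
        assert by_gene["g1"].source_diseases == {"D2"}
        assert by_gene["g2"].source_diseases == {"D2"}

    def test_all_generated_in_own_modalities_gives_empty_set(self):
        corpus, _, _ = self._setup()
        query = DiseaseRecord("Q", "q", {"Bm": {"g1", "g2", "g3", "g4"}})
        feats = [
            tp.GeneratedFeature(g, "Ae", 0.25, frozenset({"D2"}))
            for g in ("g1", "g2", "g3", "g4")
        ]
        latent = tp.extract_latent_features(feats, query, corpus, top_fraction=1.0)
        assert latent.features == []

    def test_input_order_invariance(self):
        corpus, query, feats = self._setup()
        a = tp.extract_latent_features(feats, query, corpus, top_fraction=1.0)
        b = tp.extract_latent_features(feats[::-1], query, corpus, top_fraction=1.0)
        assert a.features == b.features

    @pytest.mark.parametrize("frac", [0.0, -0.5, 1.5])
    def test_top_fraction_validation(self, frac):
        corpus, query, feats = self._setup()
        with pytest.raises(ValueError):
            tp.extract_latent_features(feats, query, corpus, top_fraction=frac)


class TestRelatedness:
    def test_single_feature_counts_each_source_once(self):
        corpus = [
            DiseaseRecord("D1", "Alpha", {"Ae": {"g"}}),
            DiseaseRecord("D2", "Beta", {"Ae": {"g"}}),
        ]
        latent = tp.LatentFeatureSet(
            [tp.GeneratedFeature("g", "Ae", 1.0, frozenset({"D1", "D2"}))], "Q"
        )
        table = tp.disease_relatedness(latent, corpus)
        assert dict(zip(table["disease_name"], table["count"])) == {
            "Alpha": 1, "Beta": 1,
        }

    def test_planted_counts_and_conservation(self):
        corpus = [
            DiseaseRecord("D1", "Hub", {"Ae": {"a"}}),
            DiseaseRecord("D2", "Spoke", {"Ae": {"a"}}),
        ]
        feats = [
            tp.GeneratedFeature(f"g{i}", "Ae", 0.1,
                                frozenset({"D1"} | ({"D2"} if i < 2 else set())))
            for i in range(5)
        ]
        latent = tp.LatentFeatureSet(feats, "Q")
        table = tp.disease_relatedness(latent, corpus)
        counts = dict(zip(table["disease_name"], table["count"]))
        assert counts == {"Hub": 5, "Spoke": 2}
        assert sum(counts.values()) == sum(len(f.source_diseases) for f in feats)
        # descending order, display filter
        assert list(table["count"]) == sorted(table["count"], reverse=True)
        assert list(tp.disease_relatedness(latent, corpus, min_count=4)[
            "disease_name"
        ]) == ["Hub"]
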