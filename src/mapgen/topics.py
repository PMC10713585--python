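"""Multi-modal topic modeling of disease-gene associations.

A corpus of diseases, each described by up to three gene-set modalities
(altered expression ``Ae``, biomarker ``Bm``, genetic variation ``Gv``),
is modeled with multi-field latent Dirichlet allocation: one shared
per-disease topic distribution theta and independent per-modality
topic-gene distributions phi, estimated by collapsed Gibbs sampling.

A disease with a missing modality is folded into the fitted model and
the missing modality is imputed as the posterior-predictive gene
distribution sum_k theta_q[k] * phi[k, modality]. Held-out imputation
quality is scored by ROC AUC against the deleted gene set. Imputed
features surviving self- and related-disease exclusion form the latent
feature set used by the downstream mechanism-mapping stages.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._gibbs import gibbs_fit, gibbs_fold_in
from .containers import MODALITIES, DiseaseRecord


@dataclass
class TopicModelFit:
    """Point estimates from averaged post-burn-in Gibbs samples."""

    K: int
    alpha: float
    beta: dict[str, float]
    disease_ids: list[str]
    theta: np.ndarray  # (n_diseases, K), rows sum to 1
    phi: dict[str, np.ndarray]  # modality -> (K, V_m), rows sum to 1
    vocab: dict[str, list[str]]
    membership: dict[str, dict[str, frozenset[str]]]
    n_iter: int
    burn_in: int
    seed: int

    def theta_of(self, disease_id: str) -> np.ndarray:
        return self.theta[self.disease_ids.index(disease_id)]


@dataclass(frozen=True)
class GeneratedFeature:
    """An imputed (gene, modality) feature with its supporting diseases."""

    gene: str
    modality: str
    score: float
    source_diseases: frozenset[str]


@dataclass
class LatentFeatureSet:
    """Imputed features surviving exclusion filtering, score-ranked."""

    features: list[GeneratedFeature]
    query_disease: str

    def genes(self) -> list[str]:
        return [f.gene for f in self.features]


def _tokenize(
    corpus: list[DiseaseRecord], vocab_index: dict[str, dict[str, int]],
    offsets: dict[str, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    docs, mods, words = [], [], []
    for d, rec in enumerate(corpus):
        for m_idx, mod in enumerate(MODALITIES):
            for gene in sorted(rec.modality_genes.get(mod, ())):
                if gene in vocab_index[mod]:
                    docs.append(d)
                    mods.append(m_idx)
                    words.append(offsets[mod] + vocab_index[mod][gene])
    return (
        np.asarray(docs, dtype=np.int64),
        np.asarray(mods, dtype=np.int64),
        np.asarray(words, dtype=np.int64),
    )


def fit(
    corpus: list[DiseaseRecord],
    K: int = 50,
    alpha: float | None = None,
    beta: float | dict[str, float] = 0.01,
    n_iter: int = 500,
    burn_in: int = 250,
    seed: int = 0,
) -> TopicModelFit:
    """Fit the multi-field LDA model by collapsed Gibbs sampling.

    ``alpha`` defaults to 1/K. Estimates are averaged over post-burn-in
    sweeps; runs are deterministic under a fixed seed.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if K < 1 or K > len(corpus):
        raise ValueError("K must satisfy 1 <= K <= number of diseases")
    if alpha is None:
        alpha = 1.0 / K
    beta_m = dict.fromkeys(MODALITIES, beta) if np.isscalar(beta) else dict(beta)
    if alpha <= 0 or any(b <= 0 for b in beta_m.values()):
        raise ValueError("hyperparameters must be positive")
    if not 0 <= burn_in < n_iter:
        raise ValueError("need 0 <= burn_in < n_iter")
    for rec in corpus:
        if sum(len(g) for g in rec.modality_genes.values()) == 0:
            raise ValueError(f"{rec.disease_id}: no genes")

    vocab = {
        mod: sorted({g for rec in corpus for g in rec.modality_genes.get(mod, ())})
        for mod in MODALITIES
    }
    vocab_index = {mod: {g: i for i, g in enumerate(vocab[mod])} for mod in MODALITIES}
    offsets, off = {}, 0
    for mod in MODALITIES:
        offsets[mod] = off
        off += len(vocab[mod])
    vocab_sizes = np.asarray([max(len(vocab[m]), 1) for m in MODALITIES], np.int64)
    word_mod = np.concatenate(
        [np.full(len(vocab[m]), i, dtype=np.int64) for i, m in enumerate(MODALITIES)]
    ) if off else np.zeros(0, dtype=np.int64)

    doc, mod, word = _tokenize(corpus, vocab_index, offsets)
    beta_arr = np.asarray([beta_m[m] for m in MODALITIES], dtype=float)
    theta, phi_flat = gibbs_fit(
        doc, mod, word, word_mod, vocab_sizes, len(corpus), K,
        float(alpha), beta_arr, n_iter, burn_in, seed,
    )
    theta = theta / theta.sum(axis=1, keepdims=True)

    phi: dict[str, np.ndarray] = {}
    for mod_name in MODALITIES:
        lo = offsets[mod_name]
        block = phi_flat[:, lo : lo + len(vocab[mod_name])]
        if block.shape[1]:
            block = block / block.sum(axis=1, keepdims=True)
        phi[mod_name] = block

    membership = {
        mod: {}
        for mod in MODALITIES
    }
    for rec in corpus:
        for mod_name in rec.modalities:
            for gene in rec.modality_genes[mod_name]:
                membership[mod_name].setdefault(gene, set()).add(rec.disease_id)
    membership = {
        mod: {g: frozenset(s) for g, s in genes.items()}
        for mod, genes in membership.items()
    }

    return TopicModelFit(
        K=K, alpha=alpha, beta=beta_m,
        disease_ids=[rec.disease_id for rec in corpus],
        theta=theta, phi=phi, vocab=vocab, membership=membership,
        n_iter=n_iter, burn_in=burn_in, seed=seed,
    )


def fold_in(
    fit_result: TopicModelFit,
    query: DiseaseRecord,
    exclude_modality: str | None = None,
    n_iter: int = 200,
    burn_in: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Estimate topic proportions for a query with phi frozen."""
    offsets, off = {}, 0
    for mod in MODALITIES:
        offsets[mod] = off
        off += len(fit_result.vocab[mod])
    words = []
    for mod in query.modalities:
        if mod == exclude_modality:
            continue
        index = {g: i for i, g in enumerate(fit_result.vocab[mod])}
        words.extend(
            offsets[mod] + index[g]
            for g in sorted(query.modality_genes[mod])
            if g in index
        )
    if not words:
        raise ValueError("query shares no vocabulary with the training corpus")
    phi_flat = np.concatenate(
        [fit_result.phi[m] for m in MODALITIES if fit_result.phi[m].shape[1]], axis=1
    )
    theta_q = gibbs_fold_in(
        np.asarray(words, dtype=np.int64), np.ascontiguousarray(phi_flat),
        float(fit_result.alpha), n_iter, burn_in, seed,
    )
    return theta_q / theta_q.sum()


def impute_modality(
    fit_result: TopicModelFit,
    query: DiseaseRecord,
    missing: str,
    n_iter: int = 200,
    burn_in: int = 100,
    seed: int = 0,
) -> list[GeneratedFeature]:
    """Impute a missing modality for a query disease.

    Every vocabulary gene of the missing modality is scored with the
    posterior-predictive mass sum_k theta_query[k] * phi[k][gene]; the
    scores sum to one over the vocabulary. Features are returned ranked
    by score (ties by gene symbol), with ``source_diseases`` set to the
    training diseases whose same-modality set contains the gene.
    """
    if missing not in MODALITIES:
        raise ValueError(f"unknown modality {missing!r}")
    if missing in query.modalities:
        raise ValueError(f"query already has modality {missing}")
    theta_q = fold_in(fit_result, query, None, n_iter, burn_in, seed)
    scores = theta_q @ fit_result.phi[missing]
    members = fit_result.membership.get(missing, {})
    features = [
        GeneratedFeature(
            gene=gene,
            modality=missing,
            score=float(score),
            source_diseases=frozenset(
                members.get(gene, frozenset()) - {query.disease_id}
            ),
        )
        for gene, score in zip(fit_result.vocab[missing], scores)
    ]
    features.sort(key=lambda f: (-f.score, f.gene))
    return features


def evaluate_auc(
    corpus: list[DiseaseRecord],
    K: int,
    alpha: float | None = None,
    beta: float | dict[str, float] = 0.01,
    n_eval: int = 20,
    seed: int = 0,
    n_iter: int = 400,
    burn_in: int = 200,
) -> dict[str, float]:
    """Held-out missing-modality imputation AUC, macro-averaged per modality.

    ``n_eval`` diseases carrying all three modalities are held out; the
    model is fitted on the remainder. For each held-out disease and each
    modality, that modality is deleted, the disease is folded in, and
    the imputation scores are evaluated by ROC AUC against membership of
    the deleted gene set.
    """
    eligible = [rec for rec in corpus if len(rec.modalities) == 3]
    if len(eligible) < n_eval:
        raise ValueError(
            f"only {len(eligible)} diseases have all three modalities; "
            f"n_eval={n_eval} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_eval, replace=False)
    held_out = [eligible[i] for i in chosen]
    held_ids = {rec.disease_id for rec in held_out}
    train = [rec for rec in corpus if rec.disease_id not in held_ids]

    model = fit(train, K=K, alpha=alpha, beta=beta, n_iter=n_iter,
                burn_in=burn_in, seed=seed)

    aucs: dict[str, list[float]] = {mod: [] for mod in MODALITIES}
    for i, rec in enumerate(held_out):
        for mod in MODALITIES:
            query = rec.drop_modality(mod)
            try:
                features = impute_modality(
                    model, query, mod,
                    seed=int((seed + 7919 * (i + 1)) % 2**31),
                )
            except ValueError:
                continue
            truth = rec.modality_genes[mod]
            labels = np.array([f.gene in truth for f in features], dtype=int)
            if labels.sum() in (0, len(labels)):
                continue
            scores = np.array([f.score for f in features])
            aucs[mod].append(roc_auc_score(labels, scores))
    return {
        mod: float(np.mean(vals)) if vals else float("nan")
        for mod, vals in aucs.items()
    }


def _name_matches(name: str, patterns: list[str]) -> bool:
    lowered = name.lower()
    for pattern in patterns:
        stem = pattern.lower().rstrip("*")
        if stem and stem in lowered:
            return True
    return False


#: Name patterns marking obviously fibrosis/lung-related diseases; the
#: trailing wildcards accept any continuation of the stem.
DEFAULT_EXCLUSION_PATTERNS = [
    "Pulmonary", "Lung", "Fibrosis", "Respir**", "Chest", "Pneumo**",
]


def extract_latent_features(
    generated: list[GeneratedFeature],
    query: DiseaseRecord,
    corpus: list[DiseaseRecord],
    exclusion_patterns: list[str] | None = None,
    top_fraction: float = 0.01,
) -> LatentFeatureSet:
    """Filter imputed features down to the latent feature set.

    Keeps the top ``top_fraction`` of the score ranking, then drops
    features present in any of the query's own modalities and features
    whose supporting diseases are all name-excluded. A feature survives
    if at least one retained (non-excluded) disease supports it; its
    ``source_diseases`` are reduced to the retained supporters.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if exclusion_patterns is None:
        exclusion_patterns = DEFAULT_EXCLUSION_PATTERNS
    ranked = sorted(generated, key=lambda f: (-f.score, f.gene))
    n_keep = max(1, math.ceil(top_fraction * len(ranked)))
    top = ranked[:n_keep]

    own_genes = {g for genes in query.modality_genes.values() for g in genes}
    excluded_ids = {
        rec.disease_id
        for rec in corpus
        if _name_matches(rec.name, exclusion_patterns)
    }
    excluded_ids.add(query.disease_id)

    kept: list[GeneratedFeature] = []
    for feature in top:
        if feature.gene in own_genes:
            continue
        retained_sources = feature.source_diseases - excluded_ids
        if not retained_sources:
            continue
        kept.append(
            GeneratedFeature(
                feature.gene, feature.modality, feature.score,
                frozenset(retained_sources),
            )
        )
    return LatentFeatureSet(features=kept, query_disease=query.disease_id)


def disease_relatedness(
    latent: LatentFeatureSet,
    corpus: list[DiseaseRecord],
    min_count: int = 0,
) -> pd.DataFrame:
    """Count, per disease, how many latent features it supports.

    Returns a table of (disease_name, count) sorted by descending count
    (ties by name); ``min_count`` reproduces display filters such as
    "counts above 20".
    """
    names = {rec.disease_id: rec.name for rec in corpus}
    counts: dict[str, int] = {}
    for feature in latent.features:
        for did in feature.source_diseases:
            name = names.get(did, did)
            counts[name] = counts.get(name, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["disease_name", "count"],
    )
    return df[df["count"] > min_count].reset_index(drop=True) if min_count else df
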