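"""Collapsed Gibbs sampling kernels for the multi-field topic model.

The sampler state lives in flat integer arrays so the inner loops can be
jit-compiled. Gene vocabularies of the different modalities are packed
into one global word index space with per-modality offsets; the
topic-word count matrix is normalized per modality slice.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_fit(
    doc: np.ndarray,
    mod: np.ndarray,
    word: np.ndarray,
    word_mod: np.ndarray,
    vocab_sizes: np.ndarray,
    n_docs: int,
    n_topics: int,
    alpha: float,
    beta: np.ndarray,
    n_iter: int,
    burn_in: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Collapsed Gibbs over tokens; returns post-burn-in averaged theta/phi.

    ``doc``, ``mod``, ``word`` are parallel token arrays (document id,
    modality id, global word id). ``word_mod`` maps each global word id
    to its modality. ``beta`` is the per-modality topic-word
    concentration; ``alpha`` the shared document-topic concentration.
    """
    np.random.seed(seed)
    n_tokens = doc.shape[0]
    n_mod = vocab_sizes.shape[0]
    v_total = word_mod.shape[0]
    K = n_topics

    ndk = np.zeros((n_docs, K), dtype=np.int64)
    nkw = np.zeros((K, v_total), dtype=np.int64)
    nkm = np.zeros((K, n_mod), dtype=np.int64)
    nd = np.zeros(n_docs, dtype=np.int64)
    z = np.empty(n_tokens, dtype=np.int64)

    for i in range(n_tokens):
        k = np.random.randint(0, K)
        z[i] = k
        ndk[doc[i], k] += 1
        nkw[k, word[i]] += 1
        nkm[k, mod[i]] += 1
        nd[doc[i]] += 1

    theta_sum = np.zeros((n_docs, K))
    phi_sum = np.zeros((K, v_total))
    cumulative = np.empty(K)
    n_samples = 0

    for iteration in range(n_iter):
        for i in range(n_tokens):
            d = doc[i]
            m = mod[i]
            w = word[i]
            k_old = z[i]
            ndk[d, k_old] -= 1
            nkw[k_old, w] -= 1
            nkm[k_old, m] -= 1
            total = 0.0
            for k in range(K):
                p = (
                    (ndk[d, k] + alpha)
                    * (nkw[k, w] + beta[m])
                    / (nkm[k, m] + beta[m] * vocab_sizes[m])
                )
                total += p
                cumulative[k] = total
            u = np.random.random() * total
            k_new = 0
            while cumulative[k_new] < u:
                k_new += 1
            z[i] = k_new
            ndk[d, k_new] += 1
            nkw[k_new, w] += 1
            nkm[k_new, m] += 1

        if iteration >= burn_in:
            n_samples += 1
            for d in range(n_docs):
                denom = nd[d] + K * alpha
                for k in range(K):
                    theta_sum[d, k] += (ndk[d, k] + alpha) / denom
            for k in range(K):
                for w in range(v_total):
                    m = word_mod[w]
                    phi_sum[k, w] += (nkw[k, w] + beta[m]) / (
                        nkm[k, m] + beta[m] * vocab_sizes[m]
                    )

    return theta_sum / n_samples, phi_sum / n_samples


@njit(cache=True)
def gibbs_fold_in(
    word: np.ndarray,
    phi: np.ndarray,
    alpha: float,
    n_iter: int,
    burn_in: int,
    seed: int,
) -> np.ndarray:
    """Fold a query document into a frozen topic-word model.

    Gibbs runs on the query tokens only; ``phi`` is the fitted (K x
    V_total) topic-word matrix. Returns the averaged query topic
    proportions.
    """
    np.random.seed(seed)
    n_tokens = word.shape[0]
    K = phi.shape[0]
    nqk = np.zeros(K, dtype=np.int64)
    z = np.empty(n_tokens, dtype=np.int64)
    for i in range(n_tokens):
        k = np.random.randint(0, K)
        z[i] = k
        nqk[k] += 1

    theta_sum = np.zeros(K)
    cumulative = np.empty(K)
    n_samples = 0
    for iteration in range(n_iter):
        for i in range(n_tokens):
            w = word[i]
            k_old = z[i]
            nqk[k_old] -= 1
            total = 0.0
            for k in range(K):
                total += (nqk[k] + alpha) * phi[k, w]
                cumulative[k] = total
            u = np.random.random() * total
            k_new = 0
            while cumulative[k_new] < u:
                k_new += 1
            z[i] = k_new
            nqk[k_new] += 1
        if iteration >= burn_in:
            n_samples += 1
            denom = n_tokens + K * alpha
            for k in range(K):
                theta_sum[k] += (nqk[k] + alpha) / denom
    return theta_sum / n_samples
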