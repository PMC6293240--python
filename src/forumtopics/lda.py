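"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Each forum document is modeled as a mixture over K topics and each topic as
a distribution over the vocabulary. Inference integrates out the topic-word
and document-topic parameters and resamples one token's topic label at a
time from

    p(z_t = k | rest)  ∝  (n_dk + alpha_k) · (n_wk + beta) / (n_·k + V·beta)

where the counts exclude token t. The sampler reproduces the MALLET-style
outputs practitioners use downstream: topic keys (top keywords plus a
per-topic "strength", the optimized Dirichlet concentration alpha_k) and
the document-by-topic file-feature matrix whose rows are smoothed topic
proportions summing to 1.

The per-token loop is numba-compiled; all randomness flows through numba's
seeded generator so a (corpus, config, seed) triple yields bit-identical
assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import digamma, gammaln

from .preprocess import BagOfWordsCorpus, Vocabulary

__all__ = [
    "LdaConfig",
    "TopicModelState",
    "TopicKey",
    "FileFeatureSet",
    "fit_lda",
    "optimize_alpha",
    "minka_fixed_point",
    "extract_topic_keys",
    "extract_file_feature_set",
    "export_top_pairs",
    "corpus_log_likelihood",
    "write_topic_keys_tsv",
    "write_feature_set_tsv",
    "write_feature_matrix_csv",
]

ALPHA_FLOOR = 1e-6


@dataclass(frozen=True)
class LdaConfig:
    """Sampler configuration.

    ``alpha`` defaults to the symmetric 50/K vector and ``beta`` to 0.01
    (common MALLET defaults). ``optimize_alpha_every`` = 0 keeps alpha
    fixed; a positive cadence re-estimates the asymmetric alpha from the
    current document-topic counts every that many sweeps once ``burn_in``
    sweeps have passed.
    """

    K: int
    alpha: tuple[float, ...] | None = None
    beta: float = 0.01
    n_iterations: int = 1000
    optimize_alpha_every: int = 50
    burn_in: int = 100
    seed: int = 0
    top_words: int = 20

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if self.alpha is not None:
            if len(self.alpha) != self.K:
                raise ValueError("alpha must have length K")
            if any(a <= 0 for a in self.alpha):
                raise ValueError("alpha entries must be positive")

    def initial_alpha(self) -> np.ndarray:
        if self.alpha is not None:
            return np.asarray(self.alpha, dtype=np.float64)
        return np.full(self.K, 50.0 / self.K)


@dataclass
class TopicModelState:
    """Fitted sampler state: token-level assignments plus the count
    matrices they induce (kept exactly consistent after every sweep)."""

    token_doc: np.ndarray      # token -> document index
    token_word: np.ndarray     # token -> vocabulary id
    assignments: np.ndarray    # token -> topic label
    n_wk: np.ndarray           # V x K topic-word counts
    n_dk: np.ndarray           # D x K document-topic counts
    n_k: np.ndarray            # K   per-topic token totals
    alpha: np.ndarray
    beta: float
    vocabulary: Vocabulary
    doc_ids: tuple[str, ...]
    log_likelihood_history: list[tuple[int, float]] = field(
        default_factory=list)

    @property
    def K(self) -> int:
        return int(self.n_wk.shape[1])

    @property
    def V(self) -> int:
        return int(self.n_wk.shape[0])

    @property
    def D(self) -> int:
        return int(self.n_dk.shape[0])

    def counts_consistent(self) -> bool:
        """Recount from assignments and compare — the sampler invariant."""
        n_wk = np.zeros_like(self.n_wk)
        n_dk = np.zeros_like(self.n_dk)
        for d, w, k in zip(self.token_doc, self.token_word, self.assignments):
            n_wk[w, k] += 1
            n_dk[d, k] += 1
        return (np.array_equal(n_wk, self.n_wk)
                and np.array_equal(n_dk, self.n_dk)
                and np.array_equal(n_wk.sum(axis=0), self.n_k))

    def topic_word_distributions(self) -> np.ndarray:
        """Smoothed phi: (n_wk + beta) / (n_·k + V·beta), shape K x V."""
        phi = (self.n_wk + self.beta) / (self.n_k + self.V * self.beta)
        return phi.T.copy()


@njit(cache=False)
def _nb_seed(seed):  # pragma: no cover - trivial jit shim
    np.random.seed(seed)


@njit(cache=False)
def _nb_init(token_doc, token_word, K, n_wk, n_dk, n_k, z):
    for t in range(z.size):
        k = np.random.randint(0, K)
        z[t] = k
        n_wk[token_word[t], k] += 1
        n_dk[token_doc[t], k] += 1
        n_k[k] += 1


@njit(cache=False)
def _nb_sweeps(token_doc, token_word, z, n_wk, n_dk, n_k,
               alpha, beta, V, n_sweeps):
    K = alpha.size
    p = np.empty(K)
    vbeta = V * beta
    for _ in range(n_sweeps):
        for t in range(z.size):
            d = token_doc[t]
            w = token_word[t]
            k = z[t]
            n_wk[w, k] -= 1
            n_dk[d, k] -= 1
            n_k[k] -= 1
            total = 0.0
            for j in range(K):
                val = (n_dk[d, j] + alpha[j]) * (n_wk[w, j] + beta) \
                    / (n_k[j] + vbeta)
                p[j] = val
                total += val
            u = np.random.random() * total
            acc = 0.0
            newk = K - 1
            for j in range(K):
                acc += p[j]
                if u < acc:
                    newk = j
                    break
            z[t] = newk
            n_wk[w, newk] += 1
            n_dk[d, newk] += 1
            n_k[newk] += 1


def fit_lda(bow: BagOfWordsCorpus, config: LdaConfig,
            log_likelihood_every: int = 0) -> TopicModelState:
    """Run the collapsed Gibbs sampler on a bag-of-words corpus.

    Sweeps visit documents in corpus order and tokens in document order.
    With ``log_likelihood_every`` > 0 the collapsed joint log-likelihood is
    recorded at that sweep cadence for convergence monitoring.
    """
    n_tokens = bow.n_tokens
    if n_tokens == 0:
        raise ValueError("corpus has no tokens; nothing to model")
    if config.K > n_tokens:
        raise ValueError("K exceeds the total token count")

    token_doc = np.empty(n_tokens, dtype=np.int32)
    token_word = np.empty(n_tokens, dtype=np.int32)
    pos = 0
    for d, doc in enumerate(bow.docs):
        for w in doc:
            token_doc[pos] = d
            token_word[pos] = w
            pos += 1

    V = len(bow.vocabulary)
    D = len(bow.docs)
    n_wk = np.zeros((V, config.K), dtype=np.int64)
    n_dk = np.zeros((D, config.K), dtype=np.int64)
    n_k = np.zeros(config.K, dtype=np.int64)
    z = np.empty(n_tokens, dtype=np.int32)
    alpha = config.initial_alpha()

    _nb_seed(config.seed)
    _nb_init(token_doc, token_word, config.K, n_wk, n_dk, n_k, z)

    state = TopicModelState(
        token_doc=token_doc, token_word=token_word, assignments=z,
        n_wk=n_wk, n_dk=n_dk, n_k=n_k, alpha=alpha, beta=config.beta,
        vocabulary=bow.vocabulary, doc_ids=bow.doc_ids)

    # schedule of (sweep index after which) alpha updates
    opt_at: set[int] = set()
    if config.optimize_alpha_every > 0:
        s = max(config.burn_in, config.optimize_alpha_every)
        while s <= config.n_iterations:
            opt_at.add(s)
            s += config.optimize_alpha_every
    ll_at = set()
    if log_likelihood_every > 0:
        ll_at = set(range(log_likelihood_every, config.n_iterations + 1,
                          log_likelihood_every))

    done = 0
    checkpoints = sorted(opt_at | ll_at | {config.n_iterations})
    for stop in checkpoints:
        if stop <= done:
            continue
        _nb_sweeps(token_doc, token_word, z, n_wk, n_dk, n_k,
                   state.alpha, config.beta, V, stop - done)
        done = stop
        if stop in opt_at:
            state.alpha = optimize_alpha(state)
        if stop in ll_at:
            state.log_likelihood_history.append(
                (stop, corpus_log_likelihood(state)))
    return state


def minka_fixed_point(n_dk: np.ndarray, alpha0: np.ndarray,
                      max_iter: int = 1000, tol: float = 1e-10) -> np.ndarray:
    """Minka's fixed-point update for an asymmetric Dirichlet prior on the
    document-topic counts (Dirichlet-multinomial maximum likelihood).

    Topics never used in any document are floored at a tiny positive value
    so the prior stays proper.
    """
    n_dk = np.asarray(n_dk, dtype=np.float64)
    lengths = n_dk.sum(axis=1)
    D = n_dk.shape[0]
    alpha = np.asarray(alpha0, dtype=np.float64).copy()
    for _ in range(max_iter):
        a0 = alpha.sum()
        num = digamma(n_dk + alpha).sum(axis=0) - D * digamma(alpha)
        den = digamma(lengths + a0).sum() - D * digamma(a0)
        if den <= 0:
            break
        new = alpha * num / den
        new = np.maximum(new, ALPHA_FLOOR)
        if np.max(np.abs(new - alpha)) < tol * max(1.0, np.max(alpha)):
            alpha = new
            break
        alpha = new
    return alpha


def optimize_alpha(state: TopicModelState, max_iter: int = 1000) -> np.ndarray:
    """Re-estimate the asymmetric alpha from the current document-topic
    counts; returns the new vector without touching the counts."""
    return minka_fixed_point(state.n_dk, state.alpha, max_iter=max_iter)


@dataclass(frozen=True)
class TopicKey:
    topic_id: int            # 1-based, as in every report
    strength: float          # the topic's Dirichlet concentration alpha_k
    keywords: tuple[str, ...]


def extract_topic_keys(state: TopicModelState,
                       top_words: int = 20) -> list[TopicKey]:
    """Top keywords per topic by smoothed within-topic probability
    (ties broken lexicographically), with the per-topic strength."""
    if top_words < 1:
        raise ValueError("top_words must be >= 1")
    phi = state.topic_word_distributions()
    terms = state.vocabulary.terms
    n = min(top_words, len(terms))
    keys = []
    for k in range(state.K):
        order = sorted(range(len(terms)), key=lambda w: (-phi[k, w], terms[w]))
        keys.append(TopicKey(
            topic_id=k + 1,
            strength=float(state.alpha[k]),
            keywords=tuple(terms[w] for w in order[:n]),
        ))
    return keys


@dataclass(frozen=True)
class FileFeatureSet:
    """Document-by-topic strength matrix: every row is a probability
    vector over the K topics (sums to 1)."""

    matrix: np.ndarray
    doc_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != len(self.doc_ids):
            raise ValueError("matrix must be D x K with one row per doc id")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("feature strengths must lie in [0, 1]")
        if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("every feature row must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def K(self) -> int:
        return int(self.matrix.shape[1])


def extract_file_feature_set(state: TopicModelState) -> FileFeatureSet:
    """Smoothed document-topic proportions:
    row_d = (n_dk + alpha) / (len_d + sum(alpha)).

    An empty document falls back to the normalized prior alpha/sum(alpha).
    """
    lengths = state.n_dk.sum(axis=1, keepdims=True)
    mat = (state.n_dk + state.alpha) / (lengths + state.alpha.sum())
    return FileFeatureSet(matrix=mat, doc_ids=state.doc_ids)


def export_top_pairs(features: FileFeatureSet,
                     n_top: int = 5) -> dict[str, list[tuple[int, float]]]:
    """Per document, the ``n_top`` strongest (topic_id, strength) pairs,
    strength-descending with ties broken by ascending topic id."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    out: dict[str, list[tuple[int, float]]] = {}
    for i, doc_id in enumerate(features.doc_ids):
        row = features.matrix[i]
        order = sorted(range(features.K), key=lambda k: (-row[k], k))
        out[doc_id] = [(k + 1, float(row[k])) for k in order[:n_top]]
    return out


def corpus_log_likelihood(state: TopicModelState) -> float:
    """Collapsed joint log-probability log p(w, z | alpha, beta)."""
    alpha = state.alpha
    a0 = alpha.sum()
    lengths = state.n_dk.sum(axis=1)
    doc_part = (
        state.D * gammaln(a0)
        - gammaln(lengths + a0).sum()
        + gammaln(state.n_dk + alpha).sum()
        - state.D * gammaln(alpha).sum()
    )
    V, K = state.V, state.K
    beta = state.beta
    word_part = (
        K * gammaln(V * beta)
        - gammaln(state.n_k + V * beta).sum()
        + gammaln(state.n_wk + beta).sum()
        - K * V * gammaln(beta)
    )
    return float(doc_part + word_part)


def write_topic_keys_tsv(keys: Sequence[TopicKey], path: str | Path) -> Path:
    """topic_id TAB strength TAB space-joined keywords, one topic per line."""
    path = Path(path)
    lines = [f"{k.topic_id}\t{k.strength:.5f}\t{' '.join(k.keywords)}"
             for k in keys]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_feature_set_tsv(features: FileFeatureSet, path: str | Path,
                          n_top: int | None = None) -> Path:
    """doc_id TAB (topic_id TAB strength)* with strengths to 3 decimals,
    pairs sorted strength-descending."""
    n = features.K if n_top is None else n_top
    pairs = export_top_pairs(features, n_top=n)
    path = Path(path)
    lines = []
    for doc_id in features.doc_ids:
        cells = [doc_id]
        for tid, s in pairs[doc_id]:
            cells.append(str(tid))
            cells.append(f"{s:.3f}")
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_feature_matrix_csv(features: FileFeatureSet,
                             path: str | Path) -> Path:
    """Dense D x K matrix as CSV with doc_id row labels and 1-based topic
    column labels."""
    df = pd.DataFrame(
        features.matrix,
        index=list(features.doc_ids),
        columns=[f"topic_{k + 1}" for k in range(features.K)],
    )
    df.index.name = "doc_id"
    df.to_csv(path)
    return Path(path)
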