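"""Ground-truthed synthetic forum corpora.

The generator emulates the statistical structure the analysis pipeline
assumes about a scraped forum site: D forum documents drawn from a K-topic
LDA generative process over a V-word vocabulary; forums organized into a
small number of groups with shared topic profiles (the planted analogue of
thematically clustered boards); and per-forum post counts depending
log-linearly on a chosen subset of topic weights (the planted analogue of
an engagement signal that topic regression should detect).

Group profiles are Dirichlet-perturbed corners of the topic simplex: each
group owns a block of topics, and ``group_separation`` controls how far its
profile is pulled toward that block's corner (0 = indistinct groups,
infinity = disjoint topic support per group). Every quantity needed to
score recovery — topic-word distributions, document mixtures, token-level
topic labels, group labels, outcome coefficients — is returned alongside
the corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .corpus import ForumCorpus, ForumDocument
from .preprocess import Vocabulary
from .regression import TopicRanking
from .similarity import ClusterPartition

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "match_topics",
    "total_variation_distance",
    "align_topic_words",
    "assignment_purity",
    "recovery_report",
    "RecoveryReport",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic corpus.

    Defaults mirror a desk-scale forum site: 80 forum boards in 4 planted
    groups, 8 latent topics over a 500-word vocabulary, ~200 tokens per
    board, and 2 topics whose weight drives posting volume with effects
    five times the outcome noise.
    """

    seed: int = 0
    V: int = 500
    K_true: int = 8
    D: int = 80
    doc_length_mean: float = 200.0
    alpha_true: tuple[float, ...] | None = None   # None -> symmetric, sum 50
    beta_true: float = 0.05
    n_groups: int = 4
    group_separation: float = math.inf
    predictive_topics: tuple[int, ...] | None = None  # 1-based; None -> auto
    effect_sizes: tuple[float, ...] = (2.0, -1.5)
    noise_sd: float = 0.1
    outcome_intercept: float = 5.0                # ln posts at zero weight

    def __post_init__(self) -> None:
        if self.V < 2 or self.K_true < 2 or self.D < 1:
            raise ValueError("V and K_true must be >= 2 and D >= 1")
        if self.predictive_topics is None:
            # two planted drivers in different groups where possible
            auto = (3, 7) if self.K_true >= 7 else (1, 2)
            object.__setattr__(self, "predictive_topics",
                               auto[:len(self.effect_sizes)])
        if self.doc_length_mean <= 0 or self.beta_true <= 0:
            raise ValueError("doc_length_mean and beta_true must be positive")
        if self.n_groups < 0 or self.n_groups > self.K_true:
            raise ValueError("n_groups must lie in 0..K_true")
        if self.group_separation < 0:
            raise ValueError("group_separation must be >= 0")
        if len(self.predictive_topics) != len(self.effect_sizes):
            raise ValueError("one effect size per predictive topic")
        if any(not 1 <= t <= self.K_true for t in self.predictive_topics):
            raise ValueError("predictive_topics must be 1-based ids in "
                             "1..K_true")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.alpha_true is not None:
            if len(self.alpha_true) != self.K_true:
                raise ValueError("alpha_true must have length K_true")
            if any(a <= 0 for a in self.alpha_true):
                raise ValueError("alpha_true entries must be positive")

    def doc_concentration(self) -> float:
        a = self.alpha_true or (50.0 / self.K_true,) * self.K_true
        return float(sum(a))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    topic_word: np.ndarray            # K_true x V
    doc_topic: np.ndarray             # D x K_true
    group_of: dict[str, int]          # forum_id -> group label
    outcome_coefficients: dict[str, float]  # "intercept" + "topic_<id>"
    token_topics: tuple[np.ndarray, ...] = field(default_factory=tuple)

    def group_labels(self, doc_ids: Sequence[str]) -> list[int]:
        return [self.group_of[d] for d in doc_ids]


def _forum_ids(D: int) -> list[str]:
    width = len(str(99 + D))
    return [f"F{100 + i:0{width}d}" for i in range(D)]


def generate_corpus(config: GeneratorConfig,
                    source_label: str = "synthetic"
                    ) -> tuple[ForumCorpus, GroundTruth]:
    """Draw a corpus and its ground truth; fully deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    K, V, D = config.K_true, config.V, config.D

    topic_word = rng.dirichlet([config.beta_true] * V, size=K)
    topic_cdf = topic_word.cumsum(axis=1)

    # group corner = uniform over the group's topic block
    if config.n_groups > 0:
        blocks: list[list[int]] = [[] for _ in range(config.n_groups)]
        for k in range(K):
            blocks[k % config.n_groups].append(k)
        corners = np.zeros((config.n_groups, K))
        for g, blk in enumerate(blocks):
            corners[g, blk] = 1.0 / len(blk)
        if math.isinf(config.group_separation):
            profiles = corners
        else:
            mix = 1.0 / (1.0 + config.group_separation)
            profiles = (1 - mix) * corners + mix / K
        group_of_idx = np.array([d % config.n_groups for d in range(D)])
    else:
        profiles = None
        group_of_idx = np.zeros(D, dtype=int)

    kappa = config.doc_concentration()
    alpha_true = np.asarray(
        config.alpha_true or (50.0 / K,) * K, dtype=np.float64)

    doc_topic = np.empty((D, K))
    docs_tokens: list[np.ndarray] = []
    token_topics: list[np.ndarray] = []
    for d in range(D):
        if profiles is not None:
            # Dirichlet centered on the group profile; tiny floor keeps the
            # parameter proper on zero-support topics
            param = kappa * profiles[group_of_idx[d]] + 1e-4
            theta = rng.dirichlet(param)
        else:
            theta = rng.dirichlet(alpha_true)
        doc_topic[d] = theta
        n_d = max(1, int(rng.poisson(config.doc_length_mean)))
        zs = rng.choice(K, size=n_d, p=theta).astype(np.int64)
        u = rng.random(n_d)
        ws = np.empty(n_d, dtype=np.int64)
        for k in np.unique(zs):
            m = zs == k
            ws[m] = np.searchsorted(topic_cdf[k], u[m], side="right")
        np.minimum(ws, V - 1, out=ws)
        docs_tokens.append(ws)
        token_topics.append(zs)

    # planted engagement signal: ln(posts) linear in chosen topic weights
    effects = np.zeros(K)
    for t, e in zip(config.predictive_topics, config.effect_sizes):
        effects[t - 1] = e
    log_posts = (config.outcome_intercept + doc_topic @ effects
                 + rng.normal(0.0, config.noise_sd, size=D))
    post_counts = np.maximum(1, np.rint(np.exp(log_posts))).astype(int)

    ids = _forum_ids(D)
    word_width = len(str(V - 1))
    word_names = [f"w{w:0{word_width}d}" for w in range(V)]
    documents = []
    for d in range(D):
        text = " ".join(word_names[w] for w in docs_tokens[d])
        documents.append(ForumDocument(
            forum_id=ids[d],
            forum_name=f"Forum {ids[d]}",
            section=f"group_{group_of_idx[d]}",
            text=text,
            thread_count=int(max(1, post_counts[d] // 4)),
            post_count=int(post_counts[d]),
        ))
    corpus = ForumCorpus(documents=documents, source_label=source_label)

    coeffs = {"intercept": config.outcome_intercept}
    for t, e in zip(config.predictive_topics, config.effect_sizes):
        coeffs[f"topic_{t}"] = float(e)
    truth = GroundTruth(
        topic_word=topic_word,
        doc_topic=doc_topic,
        group_of={ids[d]: int(group_of_idx[d]) for d in range(D)},
        outcome_coefficients=coeffs,
        token_topics=tuple(token_topics),
    )
    return corpus, truth


def total_variation_distance(p: np.ndarray, q: np.ndarray) -> float:
    """TV distance between two distributions: half the L1 difference."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def align_topic_words(phi: np.ndarray, vocabulary: Vocabulary,
                      V: int) -> np.ndarray:
    """Re-index estimated topic-word rows onto the generator's word ids.

    The generator names word w ``w<zero-padded id>``; words absent from the
    fitted vocabulary get probability 0.
    """
    width = len(str(V - 1))
    out = np.zeros((phi.shape[0], V))
    for w in range(V):
        tok = f"w{w:0{width}d}"
        j = vocabulary.index.get(tok)
        if j is not None:
            out[:, w] = phi[:, j]
    return out


def match_topics(estimated: np.ndarray, truth: np.ndarray
                 ) -> tuple[dict[int, int], np.ndarray]:
    """Optimal one-to-one matching of estimated to true topics, minimizing
    total TV distance (linear-sum assignment).

    Returns (mapping estimated index -> true index, per-pair TV distances
    indexed by estimated topic).
    """
    est = np.asarray(estimated, dtype=np.float64)
    tru = np.asarray(truth, dtype=np.float64)
    if est.shape[0] != tru.shape[0]:
        raise ValueError("estimated and true topic counts differ")
    K = est.shape[0]
    cost = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = total_variation_distance(est[i], tru[j])
    rows, cols = linear_sum_assignment(cost)
    mapping = {int(i): int(j) for i, j in zip(rows, cols)}
    tv = np.array([cost[i, mapping[i]] for i in range(K)])
    return mapping, tv


def assignment_purity(estimated_z: Sequence[np.ndarray],
                      true_z: Sequence[np.ndarray],
                      mapping: dict[int, int]) -> float:
    """Fraction of tokens whose matched estimated topic equals the planted
    one; token streams must be aligned."""
    correct = 0
    total = 0
    for ez, tz in zip(estimated_z, true_z):
        if len(ez) != len(tz):
            raise ValueError("token streams are not aligned")
        for e, t in zip(ez, tz):
            correct += int(mapping[int(e)] == int(t))
            total += 1
    return correct / total if total else float("nan")


@dataclass(frozen=True)
class RecoveryReport:
    mean_tv_distance: float
    max_tv_distance: float
    cluster_ari: float
    ranking_hit_rate: float


def recovery_report(
    truth: GroundTruth,
    doc_ids: Sequence[str],
    estimated_topic_word: np.ndarray | None = None,
    partition: ClusterPartition | None = None,
    ranking: TopicRanking | None = None,
    topic_mapping: dict[int, int] | None = None,
) -> RecoveryReport:
    """Score pipeline outputs against the planted structure.

    Components are optional; missing ones report NaN. Cluster agreement is
    the adjusted Rand index between the threshold partition and the planted
    groups; the ranking hit rate is the fraction of planted predictive
    topics found within the top-s AIC ranks (s = number planted). When the
    ranking was computed on *fitted* features, pass ``topic_mapping``
    (0-based estimated -> true, as returned by :func:`match_topics`) so
    ranked ids are translated into the planted topic space; a ranking on
    the true document-topic matrix needs no mapping.
    """
    mean_tv = max_tv = float("nan")
    if estimated_topic_word is not None:
        _, tv = match_topics(estimated_topic_word, truth.topic_word)
        mean_tv, max_tv = float(tv.mean()), float(tv.max())

    ari = float("nan")
    if partition is not None:
        labels_of = partition.labels_of
        pred = [labels_of[d] for d in doc_ids]
        true = truth.group_labels(doc_ids)
        ari = float(adjusted_rand_score(true, pred))

    hit = float("nan")
    if ranking is not None:
        planted = {int(k.split("_")[1])
                   for k in truth.outcome_coefficients if k != "intercept"}
        if planted:
            top = ranking.topic_ids[:len(planted)]
            if topic_mapping is not None:
                top = tuple(topic_mapping[t - 1] + 1 for t in top)
            hit = len(planted & set(top)) / len(planted)

    return RecoveryReport(mean_tv_distance=mean_tv, max_tv_distance=max_tv,
                          cluster_ari=ari, ranking_hit_rate=hit)
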