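"""Euclidean-distance similarity and threshold clustering.

Each forum file is a point on the K-topic simplex (its feature-set row).
Pairwise similarity is the Euclidean distance between two such topic-weight
vectors mapped affinely onto [0, 1]: similarity = 1 − d/√2, since √2 is the
largest possible Euclidean distance between two probability vectors. Files
(or topics) whose pairwise similarity clears a cutoff — 0.80 in the
workflow this package supports — are grouped by connected components of the
thresholded similarity graph.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .lda import FileFeatureSet

__all__ = [
    "SimilarityMatrix",
    "ClusterPartition",
    "euclidean_distance",
    "distance_to_similarity",
    "reciprocal_distance_similarity",
    "file_similarity_matrix",
    "topic_similarity_matrix",
    "top_pairs",
    "threshold_clusters",
    "write_similarity_csv",
    "read_similarity_csv",
    "write_cluster_json",
]

SQRT2 = math.sqrt(2.0)


def euclidean_distance(x_i: Sequence[float], x_j: Sequence[float]) -> float:
    """Euclidean distance between two equal-length topic-weight vectors."""
    a = np.asarray(x_i, dtype=np.float64)
    b = np.asarray(x_j, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("weight vectors must be 1-D and of equal length")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def distance_to_similarity(d: float) -> float:
    """Map a distance between probability vectors to [0, 1]:
    1 − d/√2, clamped. Identical vectors score 1, maximally distant ones 0."""
    if d < 0:
        raise ValueError("distance must be nonnegative")
    return float(min(1.0, max(0.0, 1.0 - d / SQRT2)))


def reciprocal_distance_similarity(d: float) -> float:
    """Alternative bounded transform 1/(1+d), for sensitivity analysis."""
    if d < 0:
        raise ValueError("distance must be nonnegative")
    return 1.0 / (1.0 + d)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise similarity in [0, 1] with unit diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("values must be square and match labels")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("similarities must lie in [0, 1]")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("diagonal must be exactly 1")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _pairwise_similarity(rows: np.ndarray, labels: Sequence[str],
                         transform: Callable[[float], float]) -> SimilarityMatrix:
    n = rows.shape[0]
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = transform(euclidean_distance(rows[i], rows[j]))
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(labels=tuple(labels), values=values)


def file_similarity_matrix(
    features: FileFeatureSet,
    transform: Callable[[float], float] = distance_to_similarity,
) -> SimilarityMatrix:
    """All-pairs file similarity from the feature-set rows."""
    if len(features.doc_ids) < 2:
        raise ValueError("need at least 2 files")
    return _pairwise_similarity(features.matrix, features.doc_ids, transform)


def topic_similarity_matrix(
    features: FileFeatureSet,
    transform: Callable[[float], float] = distance_to_similarity,
) -> SimilarityMatrix:
    """All-pairs topic similarity.

    A topic's profile is its column of strengths across files, renormalized
    to sum 1 so the same bounded transform applies; an all-zero column
    falls back to the uniform profile.
    """
    if features.K < 2:
        raise ValueError("need at least 2 topics")
    cols = features.matrix.T.copy()
    sums = cols.sum(axis=1, keepdims=True)
    zero = (sums.ravel() == 0)
    sums[zero.nonzero()[0]] = 1.0
    cols = cols / sums
    cols[zero] = 1.0 / cols.shape[1]
    labels = [f"topic_{k + 1}" for k in range(features.K)]
    return _pairwise_similarity(cols, labels, transform)


def top_pairs(sim: SimilarityMatrix,
              cutoff: float = 0.80) -> dict[str, list[tuple[str, float]]]:
    """For each label, its associates with similarity >= cutoff (self
    excluded), scores rounded to 2 decimals, in label order."""
    out: dict[str, list[tuple[str, float]]] = {}
    n = len(sim.labels)
    for i, a in enumerate(sim.labels):
        assoc = [(sim.labels[j], round(float(sim.values[i, j]), 2))
                 for j in range(n)
                 if j != i and sim.values[i, j] >= cutoff]
        out[a] = assoc
    return out


@dataclass(frozen=True)
class ClusterPartition:
    """Partition of the labels into threshold-connected groups
    (singletons retained)."""

    threshold: float
    clusters: tuple[tuple[str, ...], ...]

    @property
    def labels_of(self) -> dict[str, int]:
        return {lbl: c for c, grp in enumerate(self.clusters) for lbl in grp}


def threshold_clusters(sim: SimilarityMatrix,
                       threshold: float = 0.80) -> ClusterPartition:
    """Connected components of the graph whose edges are pairs with
    similarity >= threshold; components ordered by smallest member label,
    members sorted within each component."""
    adj = (sim.values >= threshold).astype(np.int8)
    np.fill_diagonal(adj, 1)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[str]] = {}
    for lbl, c in zip(sim.labels, comp):
        groups.setdefault(int(c), []).append(lbl)
    clusters = sorted((tuple(sorted(g)) for g in groups.values()),
                      key=lambda g: g[0])
    return ClusterPartition(threshold=float(threshold),
                            clusters=tuple(clusters))


def write_similarity_csv(sim: SimilarityMatrix, path: str | Path) -> Path:
    df = pd.DataFrame(sim.values, index=list(sim.labels),
                      columns=list(sim.labels))
    df.index.name = "label"
    df.to_csv(path)
    return Path(path)


def read_similarity_csv(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return SimilarityMatrix(labels=tuple(str(c) for c in df.columns),
                            values=df.to_numpy(dtype=np.float64))


def save_similarity_heatmap(sim: SimilarityMatrix, path: str | Path,
                            show_labels: bool = True) -> Path:
    """Grayscale heatmap of the similarity matrix (darker = more similar)
    as a PNG side artifact."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(sim.labels)
    fig, ax = plt.subplots(figsize=(max(4, n * 0.15),) * 2)
    ax.imshow(sim.values, cmap="Greys", vmin=0.0, vmax=1.0)
    if show_labels and n <= 40:
        ax.set_xticks(range(n), sim.labels, rotation=90, fontsize=6)
        ax.set_yticks(range(n), sim.labels, fontsize=6)
    else:
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def write_cluster_json(partition: ClusterPartition, path: str | Path) -> Path:
    payload = {"threshold": partition.threshold,
               "clusters": [list(c) for c in partition.clusters]}
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
    return Path(path)
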