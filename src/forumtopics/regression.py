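"""AIC-ranked regression of topic weights against a per-file outcome.

The model is ordinary least squares of a per-forum response y_i on topic
weight scores,

    y_i = beta_0 + beta_1 * topic_1 + ... + eps_i,

used in two modes: a single-topic screen (one simple regression per topic,
ranked by AIC ascending) or greedy forward-stepwise growth of a joint model
by best AIC improvement. Because feature rows sum to 1, the last topic
column is dropped from any joint fit to avoid exact collinearity with the
intercept; single-topic screening is unaffected.

The AIC convention is Gaussian-likelihood with the intercept and the error
variance counted as parameters:

    AIC = n * ln(2*pi*RSS/n) + n + 2 * (p + 2)

where p is the number of slope coefficients. The default outcome is
log10(post_count + 1) per forum — a measure of forum engagement — but any
per-file response can be supplied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .corpus import ForumCorpus
from .lda import FileFeatureSet

__all__ = [
    "RegressionSpec",
    "TopicFit",
    "TopicRanking",
    "StepwiseResult",
    "default_outcome",
    "fit_ols",
    "compute_aic",
    "rank_topics_by_aic",
    "forward_stepwise",
    "write_ranking_tsv",
]


def default_outcome(corpus: ForumCorpus) -> np.ndarray:
    """log10(post_count + 1) per forum, in corpus (forum-id) order."""
    return np.log10(np.array([d.post_count for d in corpus],
                             dtype=np.float64) + 1.0)


@dataclass(frozen=True)
class RegressionSpec:
    """Outcome vector (aligned with the feature-set rows), its name, and
    the screening mode."""

    outcome: np.ndarray
    outcome_name: str = "log10(post_count + 1)"
    mode: Literal["single_topic_screen", "forward_stepwise"] = \
        "single_topic_screen"

    def __post_init__(self) -> None:
        y = np.asarray(self.outcome, dtype=np.float64)
        if y.ndim != 1:
            raise ValueError("outcome must be a 1-D vector")
        if not np.all(np.isfinite(y)):
            raise ValueError("outcome must be finite")
        object.__setattr__(self, "outcome", y)


def fit_ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, int, int]:
    """Least squares of y on X (X already includes the intercept column).

    Returns (coefficients, RSS, n, p) where p counts slope columns only.
    Raises on rank deficiency (naming the collinear columns) and on
    n <= p + 1.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    n, ncol = X.shape
    p = ncol - 1
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    rank = np.linalg.matrix_rank(X)
    if rank < ncol:
        # identify columns involved in the dependency via QR diagonal
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [int(i) for i in np.where(diag < 1e-10 * max(diag.max(), 1))[0]]
        raise ValueError(f"design matrix is rank deficient (rank {rank} < "
                         f"{ncol}); collinear column index(es): {bad}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    return coef, rss, n, p


def compute_aic(rss: float, n: int, p: int) -> float:
    """Gaussian AIC = n*ln(2*pi*rss/n) + n + 2*(p + 2).

    ``p`` counts slope coefficients; the intercept and error variance add
    the +2. A perfect fit (rss = 0) has unbounded likelihood and is
    rejected.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rss <= 0:
        raise ValueError("rss must be positive (perfect fits have "
                         "unbounded Gaussian likelihood)")
    return n * math.log(2.0 * math.pi * rss / n) + n + 2.0 * (p + 2)


@dataclass(frozen=True)
class TopicFit:
    topic_id: int          # 1-based
    coefficient: float
    intercept: float
    aic: float


@dataclass(frozen=True)
class TopicRanking:
    """Single-topic fits ordered by AIC ascending (best first), ties broken
    by topic id."""

    fits: tuple[TopicFit, ...]
    outcome_name: str
    degenerate_outcome: bool = False

    @property
    def topic_ids(self) -> tuple[int, ...]:
        return tuple(f.topic_id for f in self.fits)

    def fits_by_id(self, topic_id: int) -> TopicFit:
        for f in self.fits:
            if f.topic_id == topic_id:
                return f
        raise KeyError(topic_id)


def rank_topics_by_aic(features: FileFeatureSet,
                       spec: RegressionSpec) -> TopicRanking:
    """Fit y ~ intercept + topic_k for every topic and rank by AIC."""
    y = spec.outcome
    if y.size != len(features.doc_ids):
        raise ValueError("outcome length must match the number of files")
    degenerate = bool(np.allclose(y, y[0]))
    if degenerate:
        warnings.warn("outcome has zero variance; the AIC ranking is "
                      "uninformative", stacklevel=2)
    n = y.size
    ones = np.ones((n, 1))
    fits = []
    for k in range(features.K):
        X = np.hstack([ones, features.matrix[:, [k]]])
        coef, rss, n_, p = fit_ols(y, X)
        fits.append(TopicFit(topic_id=k + 1,
                             coefficient=float(coef[1]),
                             intercept=float(coef[0]),
                             aic=compute_aic(rss, n_, p)))
    fits.sort(key=lambda f: (f.aic, f.topic_id))
    return TopicRanking(fits=tuple(fits), outcome_name=spec.outcome_name,
                        degenerate_outcome=degenerate)


@dataclass(frozen=True)
class StepwiseResult:
    """Forward-stepwise selection path: topics in entry order with the AIC
    after each entry."""

    entry_order: tuple[int, ...]   # 1-based topic ids
    aic_path: tuple[float, ...]
    final_aic: float
    coefficients: dict[int, float]
    intercept: float
    outcome_name: str


def forward_stepwise(features: FileFeatureSet,
                     spec: RegressionSpec) -> StepwiseResult:
    """Grow the joint model greedily by best AIC improvement until no
    remaining topic improves AIC.

    Feature rows sum to 1, so the full set of K columns is collinear with
    the intercept; any candidate whose entry would make the design rank
    deficient is skipped (at most one column is ever dropped this way).
    """
    y = spec.outcome
    n = y.size
    if n != len(features.doc_ids):
        raise ValueError("outcome length must match the number of files")
    candidates = list(range(features.K))
    chosen: list[int] = []
    aic_path: list[float] = []
    best_aic = math.inf
    ones = np.ones((n, 1))
    while candidates:
        trial_best = None
        for k in candidates:
            cols = chosen + [k]
            if n <= len(cols) + 2:
                continue
            X = np.hstack([ones, features.matrix[:, cols]])
            try:
                _, rss, n_, p = fit_ols(y, X)
                aic = compute_aic(rss, n_, p)
            except ValueError:
                continue
            if trial_best is None or aic < trial_best[0]:
                trial_best = (aic, k)
        if trial_best is None or trial_best[0] >= best_aic:
            break
        best_aic, k = trial_best
        chosen.append(k)
        candidates.remove(k)
        aic_path.append(best_aic)
    if not chosen:
        raise ValueError("no topic admits a valid fit")
    X = np.hstack([ones, features.matrix[:, chosen]])
    coef, _, _, _ = fit_ols(y, X)
    return StepwiseResult(
        entry_order=tuple(k + 1 for k in chosen),
        aic_path=tuple(aic_path),
        final_aic=best_aic,
        coefficients={k + 1: float(c) for k, c in zip(chosen, coef[1:])},
        intercept=float(coef[0]),
        outcome_name=spec.outcome_name,
    )


def write_ranking_tsv(ranking: TopicRanking, path: str | Path,
                      labels: dict[int, str] | None = None) -> Path:
    """topic_id, optional label, coefficient, AIC — one topic per line,
    best AIC first."""
    lines = ["topic_id\ttopic_label\tcoefficient\taic"]
    for f in ranking.fits:
        label = (labels or {}).get(f.topic_id, "")
        lines.append(f"{f.topic_id}\t{label}\t{f.coefficient:.6g}\t"
                     f"{f.aic:.2f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return Path(path)
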