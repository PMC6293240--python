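"""Quantitative summaries of a manual forum categorization.

Human coders assign each forum board to a category; this module aggregates
thread/post counts per category ("popularity") and checks the empirical
observation that popularity falls off log-linearly with rank — a few
categories absorb most of the traffic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import ForumCorpus

__all__ = [
    "CategoryPopularity",
    "LogLinFit",
    "read_assignments_csv",
    "aggregate_category_popularity",
    "rank_frequency_loglin_fit",
    "write_popularity_csv",
]

UNASSIGNED = "(unassigned)"


@dataclass(frozen=True)
class CategoryPopularity:
    category: str
    n_threads: int
    n_posts: int


def read_assignments_csv(path: str | Path) -> dict[str, str]:
    """forum_id,category CSV -> mapping."""
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            out[rec["forum_id"]] = rec["category"]
    return out


def aggregate_category_popularity(
    assignments: Mapping[str, str],
    corpus: ForumCorpus,
    popularity: str = "posts",
) -> list[CategoryPopularity]:
    """Sum thread and post counts per category over the assigned forums.

    Forums absent from the assignment map are pooled under
    ``(unassigned)`` so totals are conserved. Results are sorted by the
    chosen popularity measure descending (ties by category name);
    ``popularity`` is "posts" or "threads".
    """
    if popularity not in ("posts", "threads"):
        raise ValueError("popularity must be 'posts' or 'threads'")
    known = set(corpus.forum_ids)
    unknown = sorted(set(assignments) - known)
    if unknown:
        raise ValueError(f"assignment references unknown forum "
                         f"{unknown[0]!r}")
    threads: dict[str, int] = {}
    posts: dict[str, int] = {}
    for d in corpus:
        cat = assignments.get(d.forum_id, UNASSIGNED)
        threads[cat] = threads.get(cat, 0) + d.thread_count
        posts[cat] = posts.get(cat, 0) + d.post_count
    rows = [CategoryPopularity(c, threads[c], posts[c]) for c in threads]
    key = (lambda r: (-r.n_posts, r.category)) if popularity == "posts" \
        else (lambda r: (-r.n_threads, r.category))
    return sorted(rows, key=key)


@dataclass(frozen=True)
class LogLinFit:
    """OLS fit of ln(count) on rank (1..n, counts sorted descending)."""

    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False   # constant counts: R^2 undefined, reported 0


def rank_frequency_loglin_fit(counts: Sequence[float]) -> LogLinFit:
    """Regress ln(count) on rank for counts sorted descending.

    Log-linearly decaying popularity gives a straight line (negative
    slope, R^2 near 1). Requires at least 3 strictly positive counts.
    """
    c = np.asarray(sorted(counts, reverse=True), dtype=np.float64)
    if c.size < 3:
        raise ValueError("need at least 3 counts")
    if np.any(c <= 0):
        raise ValueError("all counts must be positive (log undefined)")
    rank = np.arange(1, c.size + 1, dtype=np.float64)
    logc = np.log(c)
    sst = float(np.sum((logc - logc.mean()) ** 2))
    if sst == 0.0:
        return LogLinFit(slope=0.0, intercept=float(logc[0]),
                         r_squared=0.0, degenerate=True)
    slope, intercept = np.polyfit(rank, logc, 1)
    resid = logc - (slope * rank + intercept)
    r2 = 1.0 - float(resid @ resid) / sst
    return LogLinFit(slope=float(slope), intercept=float(intercept),
                     r_squared=r2)


def write_popularity_csv(rows: Sequence[CategoryPopularity],
                         path: str | Path) -> Path:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["category", "n_threads", "n_posts"])
        for r in rows:
            w.writerow([r.category, r.n_threads, r.n_posts])
    return Path(path)
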