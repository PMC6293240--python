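"""Forum corpus data model and I/O.

A corpus is a set of forum documents: each document is the aggregated post
text of one forum board plus its thread/post counts. Corpora are serialized
as a single JSON object so a scraped site can be archived and re-analyzed
reproducibly. A companion site summary table (one row per website) supports
corpus-level bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

__all__ = [
    "ForumDocument",
    "ForumCorpus",
    "SiteSummaryRow",
    "CorpusValidationError",
    "read_corpus_json",
    "write_corpus_json",
    "read_site_table",
    "summarize_site_table",
]


class CorpusValidationError(ValueError):
    """A corpus record violates the schema or an invariant."""


@dataclass(frozen=True)
class ForumDocument:
    """One forum board: its aggregated post text and bulk counts."""

    forum_id: str
    forum_name: str = ""
    section: str = ""
    text: str = ""
    thread_count: int = 0
    post_count: int = 0

    def __post_init__(self) -> None:
        if not self.forum_id:
            raise CorpusValidationError("forum_id must be a nonempty string")
        if self.thread_count < 0 or self.post_count < 0:
            raise CorpusValidationError(
                f"negative counts for forum {self.forum_id!r}"
            )
        if self.post_count == 0 and self.text and not self.text.isspace():
            # partial imports are allowed the other way round (text for
            # uncounted posts is not)
            raise CorpusValidationError(
                f"forum {self.forum_id!r} has text but post_count = 0"
            )


@dataclass
class ForumCorpus:
    """An ordered collection of forum documents.

    Iteration order is always lexicographic in ``forum_id`` so every
    downstream matrix (feature set, similarity) has a stable axis order.
    """

    documents: list[ForumDocument] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        ids = [d.forum_id for d in self.documents]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CorpusValidationError(
                f"duplicate forum_id: {sorted(dupes)[0]!r}"
            )
        self.documents = sorted(self.documents, key=lambda d: d.forum_id)

    def __iter__(self) -> Iterator[ForumDocument]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def forum_ids(self) -> list[str]:
        return [d.forum_id for d in self.documents]

    def __getitem__(self, forum_id: str) -> ForumDocument:
        for d in self.documents:
            if d.forum_id == forum_id:
                return d
        raise KeyError(forum_id)


_REQUIRED_FIELDS = ("forum_id", "forum_name", "section", "text",
                    "thread_count", "post_count")


def read_corpus_json(path: str | Path) -> ForumCorpus:
    """Read a corpus from its JSON serialization.

    Raises ``json.JSONDecodeError`` (which carries the byte/char offset) on
    malformed JSON and :class:`CorpusValidationError` on schema violations.
    """
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict) or "documents" not in raw:
        raise CorpusValidationError("corpus JSON must have a 'documents' key")
    docs = []
    for i, rec in enumerate(raw["documents"]):
        missing = [f for f in ("forum_id", "text", "thread_count", "post_count")
                   if f not in rec]
        if missing:
            raise CorpusValidationError(
                f"record {i}: missing required field(s) {missing}"
            )
        docs.append(ForumDocument(
            forum_id=str(rec["forum_id"]),
            forum_name=str(rec.get("forum_name", "")),
            section=str(rec.get("section", "")),
            text=str(rec["text"]),
            thread_count=int(rec["thread_count"]),
            post_count=int(rec["post_count"]),
        ))
    return ForumCorpus(documents=docs,
                       source_label=str(raw.get("source_label", "")))


def write_corpus_json(corpus: ForumCorpus, path: str | Path) -> Path:
    """Write a corpus as JSON; round-trips losslessly through
    :func:`read_corpus_json`."""
    path = Path(path)
    payload = {
        "source_label": corpus.source_label,
        "documents": [
            {f: getattr(d, f) for f in _REQUIRED_FIELDS} for d in corpus
        ],
    }
    path.write_text(json.dumps(payload, ensure_ascii=False, indent=1),
                    encoding="utf-8")
    return path


@dataclass(frozen=True)
class SiteSummaryRow:
    """One website's totals: forum/thread/post counts and membership.

    ``members`` is ``None`` when the site does not publish it; it is never
    coerced to zero.
    """

    site_name: str
    forums: int
    threads: int
    posts: int
    members: int | None = None

    def __post_init__(self) -> None:
        for f in ("forums", "threads", "posts"):
            if getattr(self, f) < 0:
                raise CorpusValidationError(f"{f} must be >= 0")
        if self.members is not None and self.members < 0:
            raise CorpusValidationError("members must be >= 0 or missing")


def read_site_table(path: str | Path) -> list[SiteSummaryRow]:
    """Read a site summary table from CSV (header:
    site_name,forums,threads,posts,members; 'NA' for missing members)."""
    df = pd.read_csv(path, dtype={"site_name": str},
                     na_values=["NA", "N/A"], keep_default_na=True)
    rows = []
    for rec in df.itertuples(index=False):
        members = None if pd.isna(rec.members) else int(rec.members)
        rows.append(SiteSummaryRow(
            site_name=rec.site_name, forums=int(rec.forums),
            threads=int(rec.threads), posts=int(rec.posts), members=members,
        ))
    return rows


def summarize_site_table(rows: Sequence[SiteSummaryRow]) -> dict:
    """Aggregate a site table: exact integer totals plus each site's share
    of posts as a percentage rounded to one decimal."""
    if not rows:
        raise ValueError("site table must have at least one row")
    total_posts = sum(r.posts for r in rows)
    if total_posts == 0:
        raise ValueError("total posts is zero; shares undefined")
    return {
        "total_forums": sum(r.forums for r in rows),
        "total_threads": sum(r.threads for r in rows),
        "total_posts": total_posts,
        "post_share_pct": {
            r.site_name: round(100.0 * r.posts / total_posts, 1) for r in rows
        },
    }
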