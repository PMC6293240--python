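"""Tokenization, vocabulary construction and bag-of-words vectorization.

Tokens are lowercased runs of letters/digits, with intra-word apostrophes
preserved ("don't", "i'm" stay single tokens — contractions carry signal in
patient-generated text). The topic model consumes token *instances*, so the
bag-of-words form keeps multiplicity rather than collapsing to a binary
matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import ForumCorpus

__all__ = [
    "tokenize",
    "load_stopwords",
    "default_stopwords",
    "Vocabulary",
    "BagOfWordsCorpus",
    "build_vocabulary",
    "vectorize_corpus",
]

# letters/digits with optional apostrophe-joined continuations; underscores
# are separators, curly apostrophes normalized first
_TOKEN_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*", re.UNICODE)


def tokenize(text: str, stopwords: Iterable[str] = ()) -> list[str]:
    """Split free text into lowercase tokens.

    Splits on anything that is not a letter, digit or intra-word apostrophe;
    strips leading/trailing apostrophes; drops stopwords and tokens shorter
    than two characters.
    """
    stop = set(stopwords)
    toks = _TOKEN_RE.findall(text.lower().replace("’", "'"))
    return [t for t in toks if len(t) >= 2 and t not in stop]


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stopword list: one lowercase token per line, blanks ignored."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return frozenset(t.strip() for t in lines if t.strip())


def default_stopwords() -> frozenset[str]:
    """The frozen English stopword list shipped with the package."""
    text = resources.files("forumtopics").joinpath(
        "data/stopwords_en.txt").read_text(encoding="utf-8")
    return frozenset(t.strip() for t in text.splitlines() if t.strip())


@dataclass(frozen=True)
class Vocabulary:
    """Lexicographically ordered term list with its inverse index."""

    terms: tuple[str, ...]
    index: dict[str, int]

    def __len__(self) -> int:
        return len(self.terms)

    @staticmethod
    def from_terms(terms: Iterable[str]) -> "Vocabulary":
        ordered = tuple(sorted(set(terms)))
        return Vocabulary(ordered, {t: i for i, t in enumerate(ordered)})


@dataclass(frozen=True)
class BagOfWordsCorpus:
    """Per-document token-id sequences (multiplicity preserved), aligned
    with the source corpus order."""

    vocabulary: Vocabulary
    docs: tuple[tuple[int, ...], ...]
    doc_ids: tuple[str, ...]

    @property
    def n_tokens(self) -> int:
        return sum(len(d) for d in self.docs)


def build_vocabulary(token_docs: Sequence[Sequence[str]],
                     min_df: int = 1) -> Vocabulary:
    """Terms appearing in at least ``min_df`` documents, sorted
    lexicographically (deterministic)."""
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    df: dict[str, int] = {}
    for doc in token_docs:
        for t in set(doc):
            df[t] = df.get(t, 0) + 1
    terms = [t for t, n in df.items() if n >= min_df]
    if not terms:
        raise ValueError(
            "vocabulary is empty after document-frequency filtering; "
            "lower min_df")
    return Vocabulary.from_terms(terms)


def vectorize_corpus(corpus: ForumCorpus,
                     stopwords: Iterable[str] = (),
                     min_df: int = 1) -> BagOfWordsCorpus:
    """Tokenize every forum document and encode it against a shared
    vocabulary; out-of-vocabulary tokens are dropped, all other token
    instances are conserved. Documents that empty out keep their position
    with length zero."""
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    stop = set(stopwords)
    token_docs = [tokenize(d.text, stop) for d in corpus]
    vocab = build_vocabulary(token_docs, min_df=min_df)
    docs = tuple(
        tuple(vocab.index[t] for t in doc if t in vocab.index)
        for doc in token_docs
    )
    return BagOfWordsCorpus(vocabulary=vocab, docs=docs,
                            doc_ids=tuple(corpus.forum_ids))
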