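#!/usr/bin/env python
"""Aggregate post/thread popularity per planted forum group (standing in
for a manual categorization) and fit the rank-frequency log-linear line."""

import json
from pathlib import Path

from forumtopics.categories import (aggregate_category_popularity,
                                    rank_frequency_loglin_fit,
                                    write_popularity_csv)
from forumtopics.corpus import read_corpus_json

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    corpus = read_corpus_json(OUT / "corpus.json")
    # the generator records each forum's group in its section field
    assignments = {d.forum_id: d.section for d in corpus}
    rows = aggregate_category_popularity(assignments, corpus)
    write_popularity_csv(rows, OUT / "category_popularity.csv")
    print("category popularity (posts, threads):")
    for r in rows:
        print(f"  {r.category:10s}  {r.n_posts:6d}  {r.n_threads:6d}")

    fit = rank_frequency_loglin_fit([r.n_posts for r in rows])
    print(f"rank-frequency log-linear fit: slope {fit.slope:.3f}, "
          f"R^2 {fit.r_squared:.3f}")
    (OUT / "category_loglin.json").write_text(json.dumps(
        {"slope": fit.slope, "intercept": fit.intercept,
         "r_squared": fit.r_squared}, indent=1))
    print(f"-> {OUT / 'category_popularity.csv'}")


if __name__ == "__main__":
    main()
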