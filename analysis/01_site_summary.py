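#!/usr/bin/env python
"""Summarize the bundled five-site breast-cancer forum summary table:
exact totals and each site's share of all posts."""

import json
from importlib import resources
from pathlib import Path

from forumtopics.corpus import read_site_table, summarize_site_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    with resources.as_file(resources.files("forumtopics")
                           .joinpath("data/breast_cancer_sites.csv")) as p:
        rows = read_site_table(p)
    summary = summarize_site_table(rows)
    OUT.mkdir(exist_ok=True)
    (OUT / "site_summary.json").write_text(json.dumps(summary, indent=1))

    print(f"{len(rows)} sites, {summary['total_forums']} forums, "
          f"{summary['total_threads']:,} threads, "
          f"{summary['total_posts']:,} posts")
    for name, share in sorted(summary["post_share_pct"].items(),
                              key=lambda kv: -kv[1]):
        print(f"  {share:5.1f}%  {name}")
    print(f"-> {OUT / 'site_summary.json'}")


if __name__ == "__main__":
    main()
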