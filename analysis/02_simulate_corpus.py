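#!/usr/bin/env python
"""Simulate the study corpus: 80 forum documents in 4 planted groups from
an 8-topic generative process, with posting volume driven log-linearly by
two designated topics. Writes the corpus JSON and its ground truth."""

import json
from pathlib import Path

from forumtopics.corpus import write_corpus_json
from forumtopics.synthetic import GeneratorConfig, generate_corpus

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    cfg = GeneratorConfig(seed=SEED)   # study-condition defaults
    corpus, truth = generate_corpus(cfg)
    OUT.mkdir(exist_ok=True)
    write_corpus_json(corpus, OUT / "corpus.json")
    (OUT / "ground_truth.json").write_text(json.dumps({
        "config": {"seed": cfg.seed, "V": cfg.V, "K_true": cfg.K_true,
                   "D": cfg.D, "n_groups": cfg.n_groups,
                   "doc_length_mean": cfg.doc_length_mean},
        "topic_word": truth.topic_word.tolist(),
        "doc_topic": truth.doc_topic.tolist(),
        "group_of": truth.group_of,
        "outcome_coefficients": truth.outcome_coefficients,
    }))

    lengths = [len(d.text.split()) for d in corpus]
    posts = [d.post_count for d in corpus]
    print(f"{len(corpus)} forum documents, K_true={cfg.K_true}, "
          f"{cfg.n_groups} groups")
    print(f"tokens/doc: mean {sum(lengths) / len(lengths):.1f} "
          f"(min {min(lengths)}, max {max(lengths)})")
    print(f"posts/forum: min {min(posts)}, max {max(posts)} "
          f"(driven by topics "
          f"{[k for k in truth.outcome_coefficients if k != 'intercept']})")
    print(f"-> {OUT / 'corpus.json'}, {OUT / 'ground_truth.json'}")


if __name__ == "__main__":
    main()
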