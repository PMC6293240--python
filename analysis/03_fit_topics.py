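#!/usr/bin/env python
"""Fit the LDA topic model at the planted topic count and measure topic
recovery against the generator's ground truth."""

import json
from pathlib import Path

import numpy as np

from forumtopics.corpus import read_corpus_json
from forumtopics.lda import (LdaConfig, extract_file_feature_set,
                             extract_topic_keys, fit_lda,
                             write_feature_matrix_csv, write_feature_set_tsv,
                             write_topic_keys_tsv)
from forumtopics.preprocess import vectorize_corpus
from forumtopics.synthetic import align_topic_words, match_topics

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 43
SWEEPS = 500


def main() -> None:
    corpus = read_corpus_json(OUT / "corpus.json")
    truth = json.loads((OUT / "ground_truth.json").read_text())
    K = truth["config"]["K_true"]
    V = truth["config"]["V"]

    bow = vectorize_corpus(corpus)   # synthetic words need no stopword list
    print(f"vocabulary {len(bow.vocabulary)} terms, {bow.n_tokens} tokens")

    state = fit_lda(bow, LdaConfig(K=K, n_iterations=SWEEPS,
                                   optimize_alpha_every=50, burn_in=100,
                                   seed=SEED), log_likelihood_every=100)
    for sweep, ll in state.log_likelihood_history:
        print(f"  sweep {sweep:4d}  log-likelihood {ll:,.0f}")

    kdir = OUT / f"topics_k{K}"
    kdir.mkdir(parents=True, exist_ok=True)
    keys = extract_topic_keys(state, top_words=10)
    write_topic_keys_tsv(keys, kdir / "topic_keys.tsv")
    features = extract_file_feature_set(state)
    write_feature_set_tsv(features, kdir / "feature_set.tsv", n_top=5)
    write_feature_matrix_csv(features, kdir / "feature_matrix.csv")

    phi = align_topic_words(state.topic_word_distributions(),
                            state.vocabulary, V)
    mapping, tv = match_topics(phi, np.array(truth["topic_word"]))
    print(f"feature rows sum to 1 within "
          f"{np.max(np.abs(features.matrix.sum(1) - 1)):.1e}; "
          f"max strength {features.matrix.max():.3f}")
    print(f"matched topic TV distances: mean {tv.mean():.3f}, "
          f"max {tv.max():.3f}")
    print("topic strengths (alpha): "
          + " ".join(f"{k.strength:.3f}" for k in keys))
    (kdir / "recovery.json").write_text(json.dumps({
        "mapping_est_to_true": {str(k): v for k, v in mapping.items()},
        "tv_distances": tv.tolist()}, indent=1))
    print(f"-> {kdir}")


if __name__ == "__main__":
    main()
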