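import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from forumtopics.corpus import ForumCorpus, ForumDocument
from forumtopics.lda import LdaConfig, fit_lda
from forumtopics.preprocess import vectorize_corpus
from forumtopics.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture
def tiny_corpus() -> ForumCorpus:
    return ForumCorpus(documents=[
        ForumDocument(forum_id="F10", forum_name="Chemo",
                      text="chemo chemo side effects nausea",
                      thread_count=2, post_count=10),
        ForumDocument(forum_id="F11", forum_name="Diagnosis",
                      text="biopsy mammogram results waiting biopsy",
                      thread_count=3, post_count=25),
        ForumDocument(forum_id="F12", forum_name="Family",
                      text="husband family support friends support",
                      thread_count=1, post_count=5),
    ], source_label="tiny")


@pytest.fixture(scope="session")
def two_topic_setup():
    """A well-separated 2-topic corpus with a 2-topic fit; shared across
    tests because the sampler dominates test runtime."""
    cfg = GeneratorConfig(seed=7, V=60, K_true=2, D=40, doc_length_mean=60,
                          n_groups=2, predictive_topics=(1,),
                          effect_sizes=(2.0,), noise_sd=0.1)
    corpus, truth = generate_corpus(cfg)
    bow = vectorize_corpus(corpus)
    state = fit_lda(bow, LdaConfig(K=2, n_iterations=500,
                                   optimize_alpha_every=50, burn_in=100,
                                   seed=11))
    return cfg, corpus, truth, bow, state


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
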