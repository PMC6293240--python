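"""End-to-end pipeline: corpus -> bag of words -> LDA (per K in a ladder)
-> similarity matrices -> threshold clusters -> AIC topic ranking.

Every run writes a manifest recording the configuration, the per-stage
seeds, and content hashes of all artifacts, so a rerun with the same
configuration and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .categories import (aggregate_category_popularity, read_assignments_csv,
                         rank_frequency_loglin_fit, write_popularity_csv)
from .corpus import ForumCorpus, read_corpus_json
from .lda import (LdaConfig, extract_file_feature_set, extract_topic_keys,
                  fit_lda, write_feature_matrix_csv, write_feature_set_tsv,
                  write_topic_keys_tsv)
from .preprocess import default_stopwords, load_stopwords, vectorize_corpus
from .regression import (RegressionSpec, default_outcome, forward_stepwise,
                         rank_topics_by_aic, write_ranking_tsv)
from .similarity import (file_similarity_matrix, threshold_clusters,
                         top_pairs, topic_similarity_matrix,
                         write_cluster_json, write_similarity_csv)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "load_config"]

# fixed stage indices for seed fan-out (documented, stable across versions)
_STAGES = ("generate", "preprocess", "fit", "similarity", "regress",
           "categories")


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed = seed + stage index, so stages are individually
    reproducible."""
    return seed + _STAGES.index(stage)


@dataclass(frozen=True)
class PipelineConfig:
    corpus_path: str
    output_dir: str
    stopwords_path: str | None = None
    assignments_path: str | None = None
    topic_labels_path: str | None = None
    k_ladder: tuple[int, ...] = (15, 20, 30)
    n_iterations: int = 1000
    optimize_alpha_every: int = 50
    burn_in: int = 100
    beta: float = 0.01
    min_df: int = 1
    similarity_threshold: float = 0.80
    top_pairs_cutoff: float = 0.80
    regression_mode: str = "single_topic_screen"
    outcome_name: str = "log10(post_count + 1)"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.k_ladder:
            raise ValueError("k_ladder must be nonempty")
        if not 0 <= self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must lie in [0, 1]")
        if self.regression_mode not in ("single_topic_screen",
                                        "forward_stepwise"):
            raise ValueError("unknown regression mode "
                             f"{self.regression_mode!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat TOML config file (keys mirror PipelineConfig fields)."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "k_ladder" in raw:
        raw["k_ladder"] = tuple(int(k) for k in raw["k_ladder"])
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write all artifacts plus a manifest.

    Fails fast on a missing input; on a stage failure the partially
    written output directory is removed.
    """
    corpus_path = Path(config.corpus_path)
    if not corpus_path.exists():
        raise FileNotFoundError(f"corpus not found: {corpus_path}")
    if config.stopwords_path and not Path(config.stopwords_path).exists():
        raise FileNotFoundError(
            f"stopword list not found: {config.stopwords_path}")
    if config.assignments_path and not Path(config.assignments_path).exists():
        raise FileNotFoundError(
            f"assignment file not found: {config.assignments_path}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    timings: dict[str, float] = {}
    warnings_log: list[str] = []

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    shutil.rmtree(out, ignore_errors=True)
                    raise RuntimeError(
                        f"pipeline stage {name!r} failed: {exc}") from exc
                timings[name] = time.perf_counter() - self.t0
        return _Timer()

    corpus = read_corpus_json(corpus_path)
    stopwords = (load_stopwords(config.stopwords_path)
                 if config.stopwords_path else default_stopwords())

    with stage("preprocess"):
        bow = vectorize_corpus(corpus, stopwords, min_df=config.min_df)

    labels: dict[int, str] = {}
    if config.topic_labels_path:
        import csv
        with open(config.topic_labels_path, newline="",
                  encoding="utf-8") as fh:
            labels = {int(r["topic_id"]): r["topic_label"]
                      for r in csv.DictReader(fh)}

    y = default_outcome(corpus)
    for K in config.k_ladder:
        kdir = out / f"k{K}"
        kdir.mkdir(exist_ok=True)
        lda_cfg = LdaConfig(
            K=K, beta=config.beta, n_iterations=config.n_iterations,
            optimize_alpha_every=config.optimize_alpha_every,
            burn_in=config.burn_in,
            seed=stage_seed(config.seed, "fit") + K)
        with stage(f"fit_k{K}"):
            state = fit_lda(bow, lda_cfg)
            keys = extract_topic_keys(state)
            features = extract_file_feature_set(state)
            artifacts.append(write_topic_keys_tsv(
                keys, kdir / "topic_keys.tsv"))
            artifacts.append(write_feature_set_tsv(
                features, kdir / "feature_set.tsv", n_top=5))
            artifacts.append(write_feature_matrix_csv(
                features, kdir / "feature_matrix.csv"))
        with stage(f"similarity_k{K}"):
            fsim = file_similarity_matrix(features)
            tsim = topic_similarity_matrix(features)
            artifacts.append(write_similarity_csv(
                fsim, kdir / "file_similarity.csv"))
            artifacts.append(write_similarity_csv(
                tsim, kdir / "topic_similarity.csv"))
            pairs = top_pairs(fsim, cutoff=config.top_pairs_cutoff)
            pairs_path = kdir / "top_pairs.json"
            pairs_path.write_text(json.dumps(
                {a: [[b, s] for b, s in v] for a, v in pairs.items() if v},
                indent=1), encoding="utf-8")
            artifacts.append(pairs_path)
            artifacts.append(write_cluster_json(
                threshold_clusters(fsim, config.similarity_threshold),
                kdir / "file_clusters.json"))
            artifacts.append(write_cluster_json(
                threshold_clusters(tsim, config.similarity_threshold),
                kdir / "topic_clusters.json"))
        with stage(f"regress_k{K}"):
            spec = RegressionSpec(outcome=y,
                                  outcome_name=config.outcome_name)
            import warnings as _w
            with _w.catch_warnings(record=True) as caught:
                _w.simplefilter("always")
                ranking = rank_topics_by_aic(features, spec)
            for w in caught:
                warnings_log.append(f"k{K}: {w.message}")
            artifacts.append(write_ranking_tsv(
                ranking, kdir / "aic_ranking.tsv", labels=labels))
            if config.regression_mode == "forward_stepwise":
                sw = forward_stepwise(features, spec)
                sw_path = kdir / "stepwise.json"
                sw_path.write_text(json.dumps({
                    "entry_order": list(sw.entry_order),
                    "aic_path": list(sw.aic_path),
                    "final_aic": sw.final_aic,
                    "intercept": sw.intercept,
                    "coefficients": {str(k): v
                                     for k, v in sw.coefficients.items()},
                }, indent=1), encoding="utf-8")
                artifacts.append(sw_path)

    if config.assignments_path:
        with stage("categories"):
            assignments = read_assignments_csv(config.assignments_path)
            rows = aggregate_category_popularity(assignments, corpus)
            artifacts.append(write_popularity_csv(
                rows, out / "category_popularity.csv"))
            counts = [r.n_posts for r in rows if r.n_posts > 0]
            if len(counts) >= 3:
                fit = rank_frequency_loglin_fit(counts)
                p = out / "category_loglin.json"
                p.write_text(json.dumps({
                    "slope": fit.slope, "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "degenerate": fit.degenerate}, indent=1),
                    encoding="utf-8")
                artifacts.append(p)

    manifest = {
        "package_version": __version__,
        "config": {k: getattr(config, k) for k in (
            "corpus_path", "k_ladder", "n_iterations",
            "optimize_alpha_every", "burn_in", "beta", "min_df",
            "similarity_threshold", "top_pairs_cutoff", "regression_mode",
            "outcome_name", "seed")},
        "similarity_transform": "1 - d/sqrt(2)",
        "aic_convention": "n*ln(2*pi*rss/n) + n + 2*(p + 2)",
        "stage_seconds": timings,
        "warnings": warnings_log,
        "artifact_hashes": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(artifacts)},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=list), encoding="utf-8")
    return out
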