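"""Canned study-condition tasks built on the synthetic generator.

These fix the corpus conditions under which the method-level claims are
checked: a three-theme, disjoint-vocabulary corpus for cluster-count
recovery, and the default four-theme overlapping-vocabulary labeled
corpus for GCN label recovery.  Problem sizes (~1000 and ~1500 documents)
keep a full multi-seed experiment within single-CPU desk scale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import cluster, gcn
from .preprocess import ProcessedDoc, preprocess_corpus
from .synth import GeneratorConfig, generate_video_pool

THREE_THEMES = ("product_review", "health_information", "instructional")


def three_theme_config(seed: int, vocab_size_per_theme: int = 120
                       ) -> GeneratorConfig:
    """Generator config with 3 well-separated themes (no shared vocabulary).

    The diffuse catch-all theme is disabled and the shared vocabulary is
    emptied so the three topical vocabularies are disjoint — the regime in
    which the corpus has exactly three planted clusters.
    """
    uniform = {t: 1.0 / 3.0 for t in THREE_THEMES}
    mixtures = {(a, s): dict(uniform)
                for a in (16, 24) for s in ("female", "male")}
    return GeneratorConfig(
        seed=seed,
        themes=THREE_THEMES,
        theme_mixture=mixtures,
        pool_mixture=dict(uniform),
        vocab_size_per_theme=vocab_size_per_theme,
        shared_vocab_size=0,
        shared_word_prob=0.0,
        theme_noise_max=0.0,
    )


def three_theme_corpus(seed: int, n_docs: int = 1000) -> list[ProcessedDoc]:
    cfg = three_theme_config(seed)
    return preprocess_corpus(generate_video_pool(cfg, n_docs))


def elbow_recovery_k(seed: int, n_docs: int = 1000, k_max: int = 8,
                     n_restarts: int = 10,
                     rel_threshold: float = 0.15) -> int:
    """Selected cluster count on one seeded three-theme corpus."""
    corpus = three_theme_corpus(seed, n_docs)
    tfidf = cluster.tfidf_matrix(corpus)
    sse = cluster.sse_curve(tfidf, 1, k_max, n_restarts, seed)
    return cluster.elbow_select_k(sse, rel_threshold)


def labeled_task(seed: int, n_docs: int = 1500
                 ) -> tuple[list[ProcessedDoc], dict[str, str]]:
    """Default 4-theme labeled corpus (overlapping Zipf vocabularies)."""
    cfg = GeneratorConfig(seed=seed)
    pool = generate_video_pool(cfg, n_docs)
    corpus = preprocess_corpus(pool)
    labels = {v.video_id: v.true_theme for v in pool}
    return corpus, labels


def gcn_recovery_accuracy(seed: int, n_docs: int = 1500,
                          config: gcn.GcnConfig | None = None,
                          include_word_word: bool = True) -> float:
    """Held-out test accuracy of the GCN on one seeded labeled corpus."""
    corpus, labels = labeled_task(seed, n_docs)
    graph = gcn.build_text_graph(
        corpus, window=(config or gcn.GcnConfig()).window)
    if not include_word_word:
        graph.word_word = graph.word_word.multiply(0.0).tocsr()
    cfg = replace(config or gcn.GcnConfig(), seed=seed)
    model = gcn.train_gcn(graph, labels, cfg)
    return gcn.evaluate_split(model, graph, labels)["test_accuracy"]


def seeds_from(seed: int, n: int) -> list[int]:
    """Derive *n* independent 31-bit run seeds from a base seed."""
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
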