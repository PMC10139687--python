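"""End-to-end orchestration: synth → preprocess → cluster → GCN → networks.

``run_pipeline`` executes the full audit analysis on generated data and
writes every stage artifact plus a ``summary.json`` into a run directory.
Reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cluster, gcn, metrics, profnet, synth
from .preprocess import preprocess_corpus, write_corpus_jsonl

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    generator: synth.GeneratorConfig = field(
        default_factory=synth.GeneratorConfig)
    gcn: gcn.GcnConfig = field(default_factory=gcn.GcnConfig)
    n_videos: int = 4201
    n_labeled: int = 1000
    rater_error: float = 0.025
    k_min: int = 1
    k_max: int = 8
    n_restarts: int = 10
    elbow_threshold: float = 0.15
    mds_max_points: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.seed != self.generator.seed:
            self.generator = dataclasses.replace(self.generator,
                                                 seed=self.seed)
        if self.seed != self.gcn.seed:
            self.gcn = dataclasses.replace(self.gcn, seed=self.seed)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        gen_kwargs = raw.pop("generator", {}) or {}
        if "theme_mixture" in gen_kwargs:
            mixture = {}
            for key, mix in gen_kwargs["theme_mixture"].items():
                age, sex = key.split("_", 1)
                mixture[(int(age), sex)] = dict(mix)
            gen_kwargs["theme_mixture"] = mixture
        for k in ("terms", "themes", "ages", "sexes"):
            if k in gen_kwargs and gen_kwargs[k] is not None:
                gen_kwargs[k] = tuple(gen_kwargs[k])
        if "races" in gen_kwargs:
            gen_kwargs["races"] = tuple(
                (r, int(n)) for r, n in gen_kwargs["races"])
        if gen_kwargs.get("subpool_frac_by_age") is not None:
            gen_kwargs["subpool_frac_by_age"] = tuple(
                (int(a), float(f))
                for a, f in gen_kwargs["subpool_frac_by_age"])
        gcn_kwargs = raw.pop("gcn", {}) or {}
        cfg = cls(generator=synth.GeneratorConfig(**gen_kwargs),
                  gcn=gcn.GcnConfig(**gcn_kwargs), **raw)
        if seed is not None:
            cfg.seed = seed
            cfg.__post_init__()
        return cfg

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        gen = dataclasses.asdict(self.generator)
        gen["theme_mixture"] = {f"{a}_{s}": dict(mix)
                                for (a, s), mix in gen["theme_mixture"].items()}
        doc = {f.name: getattr(self, f.name)
               for f in dataclasses.fields(self)
               if f.name not in ("generator", "gcn")}
        doc["generator"] = gen
        doc["gcn"] = dataclasses.asdict(self.gcn)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(plain(doc), fh, sort_keys=True)


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small configuration: full cohort, 4 terms, 2 pages, ~600 videos."""
    return PipelineConfig(
        generator=synth.GeneratorConfig(seed=seed, n_terms=4, pages=2),
        gcn=gcn.GcnConfig(seed=seed, hidden_dim=64, epochs=120),
        n_videos=600,
        n_labeled=300,
        k_max=6,
        mds_max_points=200,
        seed=seed,
    )


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage, write artifacts under *out_dir*, return the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    gen = config.generator

    logger.info("stage synth")
    cohort = synth.generate_profile_cohort(gen)
    pool = synth.generate_video_pool(gen, config.n_videos)
    results = synth.simulate_search_results(pool, cohort, gen)
    synth.write_cohort_csv(cohort, out / "cohort.csv")
    synth.write_pool_jsonl(pool, out / "pool.jsonl")
    synth.write_results_csv(results, out / "results.csv")
    unique_ids, n_collected, n_duplicates = synth.deduplicate(results)
    surfaced = [v for v in pool if v.video_id in unique_ids]

    logger.info("stage preprocess")
    corpus = preprocess_corpus(surfaced)
    write_corpus_jsonl(corpus, out / "corpus.jsonl")

    logger.info("stage cluster")
    tfidf = cluster.tfidf_matrix(corpus)
    sse = cluster.sse_curve(tfidf, config.k_min, config.k_max,
                            config.n_restarts, config.seed)
    selected_k = cluster.elbow_select_k(sse, config.elbow_threshold)
    best = cluster.kmeans_cluster(tfidf, selected_k, config.n_restarts,
                                  config.seed)
    with open(out / "sse_by_k.csv", "w", encoding="utf-8") as fh:
        fh.write("k,sse\n")
        for k in sorted(sse):
            fh.write(f"{k},{sse[k]:.6f}\n")
    with open(out / "assignments.csv", "w", encoding="utf-8") as fh:
        fh.write("video_id,cluster\n")
        for vid in sorted(best.assignments):
            fh.write(f"{vid},{best.assignments[vid]}\n")
    n_embed = min(config.mds_max_points, len(corpus))
    sim = cluster.cosine_similarity_matrix(
        cluster.TfidfMatrix(tfidf.matrix[:n_embed], tfidf.vocabulary,
                            tfidf.doc_ids[:n_embed]))
    coords = cluster.mds_embed(1.0 - sim)
    stress = cluster.mds_stress(1.0 - sim, coords)
    with open(out / "mds_coords.csv", "w", encoding="utf-8") as fh:
        fh.write("video_id,x,y\n")
        for vid, (x, y) in zip(tfidf.doc_ids[:n_embed], coords):
            fh.write(f"{vid},{x:.6f},{y:.6f}\n")

    logger.info("stage labeling")
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 505])
    n_labeled = min(config.n_labeled, len(surfaced))
    labeled_idx = rng.choice(len(surfaced), size=n_labeled, replace=False)
    labeled_videos = [surfaced[i] for i in sorted(labeled_idx)]
    truth = [v.true_theme for v in labeled_videos]
    rater_a, rater_b = synth.simulate_raters(
        truth, gen, error_rate=config.rater_error)
    kappa = metrics.cohen_kappa(rater_a, rater_b)
    labels = {v.video_id: lab for v, lab in zip(labeled_videos, rater_a)}

    logger.info("stage gcn")
    graph = gcn.build_text_graph(corpus, window=config.gcn.window)
    model = gcn.train_gcn(graph, labels, config.gcn)
    preds, probs = gcn.classify(model, graph)
    split = gcn.evaluate_split(model, graph, labels)
    held = set(model.train_ids) | set(model.val_ids)
    test_ids = sorted(d for d in labels if d not in held)
    report = metrics.classification_metrics(
        [labels[d] for d in test_ids], [preds[d] for d in test_ids])
    report.kappa = kappa
    report.to_json(out / "metrics.json")
    report.confusion.to_csv(out / "confusion.csv")
    with open(out / "predictions.csv", "w", encoding="utf-8") as fh:
        fh.write("video_id,predicted_theme,"
                 + ",".join(f"p_{c}" for c in model.classes) + "\n")
        for vid in sorted(preds):
            p = ",".join(f"{x:.6f}" for x in probs[vid])
            fh.write(f"{vid},{preds[vid]},{p}\n")

    logger.info("stage profnet")
    shares = metrics.theme_share(preds)
    networks = {}
    for mode in ("single_attribute", "age_by_sex"):
        net = profnet.build_attribute_network(results, mode)
        profnet.write_graphml(net, out / f"network_{mode}.graphml")
        profnet.write_edges_csv(net, out / f"network_{mode}_edges.csv")
        networks[mode] = {
            "edges": {f"{a}|{b}": int(d["weight"])
                      for a, b, d in sorted(net.edges(data=True))},
            "degree_centrality":
                profnet.degree_centrality(net)["weighted_degree"].to_dict(),
        }
    prevalence = profnet.prevalence_by_group(preds, results,
                                             profnet.by_age_sex)
    prevalence.to_csv(out / "prevalence_by_group.csv")

    summary = {
        "n_collected": n_collected,
        "n_duplicates": n_duplicates,
        "n_unique": len(unique_ids),
        "selected_k": selected_k,
        "sse_by_k": {str(k): round(v, 4) for k, v in sse.items()},
        "mds_stress": round(stress, 4),
        "kappa": round(kappa, 4),
        "gcn": {k: (round(v, 4) if isinstance(v, float) else v)
                for k, v in split.items()},
        "metrics": report.to_dict(),
        "theme_share": shares,
        "prevalence_by_group": {g: row.to_dict()
                                for g, row in prevalence.iterrows()},
        "networks": networks,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
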