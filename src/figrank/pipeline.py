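"""End-to-end helpers: corpus -> features -> cross-validated evaluation."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import Article, GoldRanking, check_consistency, read_article_json
from .features import (
    FeatureMatrix,
    VectorSpace,
    build_vector_space,
    extract_all,
    registry_from_rows,
)
from .metrics import MetricReport, evaluate, similarity_metric
from .ranker import FigureRanker, RankingInstance, TrainerConfig
from .topics import ArticleTopics

logger = logging.getLogger(__name__)

SYSTEMS = ("random", "listnet", "figrank")


def load_corpus(
    corpus_dir: str | Path, gold: Mapping[str, GoldRanking]
) -> list[tuple[Article, GoldRanking]]:
    """Read every *.json article in a directory, skipping unreadable files."""
    out = []
    paths = sorted(Path(corpus_dir).glob("*.json"))
    for path in paths:
        if path.name == "manifest.json":
            continue
        try:
            article = read_article_json(path)
            g = gold[article.article_id]
            check_consistency(article, g)
        except Exception as exc:  # noqa: BLE001 - skip-and-warn contract
            logger.warning("skipping %s: %s", path, exc)
            continue
        out.append((article, g))
    if not out:
        raise ValueError(f"no readable articles in {corpus_dir}")
    return out


def extract_corpus_features(
    corpus: Sequence[tuple[Article, GoldRanking]],
    lda_topics: int = 10,
    lda_max_iter: int = 100,
    seed: int = 0,
    with_topics: bool = True,
) -> FeatureMatrix:
    """Shared vector space + per-article topic models -> FeatureMatrix."""
    texts: list[str] = []
    for article, _ in corpus:
        texts.append(article.title)
        texts.append(article.abstract)
        for sec in article.sections:
            texts.extend(sec.paragraphs)
        for fig in article.figures:
            texts.append(fig.caption)
    space = build_vector_space([t for t in texts if t and t.strip()])

    matrix: FeatureMatrix | None = None
    for article, gold in corpus:
        topic_model = None
        if with_topics:
            topic_model = ArticleTopics(
                article, space, k=lda_topics, seed=seed, max_iter=lda_max_iter
            )
        rows = extract_all(article, space, topic_model)
        if matrix is None:
            matrix = FeatureMatrix(registry=registry_from_rows(rows))
        matrix.articles[article.article_id] = rows
        matrix.gold[article.article_id] = gold
    assert matrix is not None
    return matrix


def _dataset_from_matrix(matrix: FeatureMatrix) -> list[RankingInstance]:
    return [
        RankingInstance(aid, X, ranks) for aid, (X, ranks) in matrix.as_arrays().items()
    ]


def random_baseline(
    gold: Mapping[str, GoldRanking], repeats: int = 100, seed: int = 0
) -> MetricReport:
    """Random-permutation baseline: per-article average over `repeats` draws."""
    rng = np.random.default_rng(seed)
    per_article = {}
    metric_fns = {name: similarity_metric(name) for name in ("wer_rk", "ndcg", "wer_fr")}
    for aid, g in gold.items():
        m = len(g.ranks)
        sums = dict.fromkeys(metric_fns, 0.0)
        for _ in range(repeats):
            perm = rng.permutation(m) + 1
            for name, fn in metric_fns.items():
                sums[name] += fn(perm, g.ranks)
        per_article[aid] = {name: s / repeats for name, s in sums.items()}
    return MetricReport(per_article)


def cross_validate(
    dataset: Sequence[RankingInstance],
    systems: Sequence[str] = SYSTEMS,
    n_folds: int = 10,
    seed: int = 0,
    config: TrainerConfig | None = None,
    random_repeats: int = 100,
) -> dict[str, MetricReport]:
    """Article-level k-fold cross-validation of the requested systems.

    ``listnet`` trains with the top-1 loss, ``figrank`` with the top-2 loss;
    ``random`` averages `random_repeats` sampled permutations per article.
    """
    if len(dataset) < n_folds:
        raise ValueError(f"need at least {n_folds} articles for {n_folds}-fold CV")
    base = config or TrainerConfig()
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(dataset))
    folds = np.array_split(idx, n_folds)

    gold_all = {inst.article_id: GoldRanking(inst.article_id, inst.gold_ranks.tolist())
                for inst in dataset}
    reports: dict[str, MetricReport] = {}
    for system in systems:
        if system == "random":
            reports[system] = random_baseline(gold_all, repeats=random_repeats, seed=seed)
            continue
        loss_mode = {"listnet": "top1", "figrank": "top2"}[system]
        predictions: dict[str, np.ndarray] = {}
        from dataclasses import replace

        cfg = replace(base, loss_mode=loss_mode)
        for fold in folds:
            test_ids = set(int(i) for i in fold)
            train_set = [inst for i, inst in enumerate(dataset) if i not in test_ids]
            results = FigureRanker(train_set, config=cfg).fit()
            for i in sorted(test_ids):
                inst = dataset[i]
                predictions[inst.article_id] = results.predict(inst).system_ranks
        reports[system] = evaluate(predictions, gold_all)
    return reports


def format_table(reports: Mapping[str, MetricReport]) -> str:
    """Systems x metrics table with mean±std cells."""
    header = f"{'System':<12s} {'~WER-RK':>14s} {'NDCG':>14s} {'~WER-FR':>14s}"
    lines = [header, "-" * len(header)]
    for system, report in reports.items():
        cells = report.summary()
        lines.append(
            f"{system:<12s} {cells['wer_rk']:>14s} {cells['ndcg']:>14s} "
            f"{cells['wer_fr']:>14s}"
        )
    return "\n".join(lines)
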