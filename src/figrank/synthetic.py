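"""Synthetic fixtures with planted figure-importance structure.

Two generators are provided:

* :func:`generate_ranking_dataset` — numeric ranking lists from a known
  linear model (features i.i.d. standard normal, true score w*.x plus
  Gaussian noise, gold ranks = dense ranks of the true scores with
  probabilistic tie injection).  Used to test the trainer and feature
  selection against a known ground truth.

* :func:`generate_article` / :func:`generate_corpus` — full articles with
  IMRAD sections built from a topic-word sampler.  More important figures
  get (i) more mention sentences in Results/Discussion, (ii) captions
  sharing more vocabulary with the title and abstract, and (iii) more
  sub-figure markers, so centrality, frequency and structural features
  correlate with the gold rank by construction.

The figures-per-article distribution is peaked at 4-6 figures over the
range 2..9, emulating the shape reported for author-annotated corpora
(average ~5 figures, almost all articles with 9 or fewer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import (
    Article,
    Figure,
    GoldRanking,
    Section,
    attach_contexts,
    dense_ranks,
    write_article_json,
    write_gold_rankings,
)
from .ranker import RankingInstance

#: figure-count support and probabilities (peaked at 4-6 figures)
FIGURE_COUNTS = (2, 3, 4, 5, 6, 7, 8, 9)
FIGURE_COUNT_PROBS = (0.05, 0.12, 0.20, 0.22, 0.18, 0.11, 0.07, 0.05)


@dataclass
class SyntheticSpec:
    n_articles: int = 100
    figure_counts: Sequence[int] = FIGURE_COUNTS
    figure_count_probs: Sequence[float] = FIGURE_COUNT_PROBS
    #: probability that two adjacent ranks collapse into a tie (~45% of
    #: 5-figure articles then contain at least one tie)
    tie_probability: float = 0.14
    n_features: int = 10
    noise_sd: float = 0.0
    planted_weights: np.ndarray | None = None
    #: strength of the planted text signal (0 disables the importance
    #: gradient, giving symmetric figures and tie-heavy gold)
    importance_gradient: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tie_probability <= 1.0:
            raise ValueError("tie_probability must lie in [0, 1]")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        probs = np.asarray(self.figure_count_probs, float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("figure_count_probs must sum to 1")


def _inject_ties(strict_ranks: np.ndarray, tie_p: float, rng: np.random.Generator) -> list[int]:
    """Collapse adjacent rank pairs with probability tie_p, re-densifying."""
    order = np.argsort(strict_ranks)
    collapsed = np.array(strict_ranks, dtype=float)
    for a, b in zip(order[:-1], order[1:]):
        if rng.random() < tie_p:
            collapsed[b] = collapsed[a]
    return dense_ranks(collapsed)


def generate_ranking_dataset(
    spec: SyntheticSpec,
) -> tuple[list[RankingInstance], np.ndarray]:
    """Numeric lists from a known linear model; returns (dataset, w*)."""
    rng = np.random.default_rng(spec.seed)
    if spec.planted_weights is not None:
        w_star = np.asarray(spec.planted_weights, float)
        if w_star.shape != (spec.n_features,):
            raise ValueError("planted_weights must match n_features")
    else:
        w_star = rng.normal(size=spec.n_features)
        w_star /= np.linalg.norm(w_star)
    dataset = []
    for i in range(spec.n_articles):
        n = int(rng.choice(spec.figure_counts, p=spec.figure_count_probs))
        X = rng.normal(size=(n, spec.n_features))
        true = X @ w_star + spec.noise_sd * rng.normal(size=n)
        strict = np.empty(n, dtype=int)
        strict[np.argsort(-true)] = np.arange(1, n + 1)
        ranks = _inject_ties(strict, spec.tie_probability, rng)
        dataset.append(RankingInstance(f"synth{i:04d}", X, np.array(ranks)))
    return dataset, w_star


# ---------------------------------------------------------------------------
# Article generator
# ---------------------------------------------------------------------------

_N_TOPICS = 4
_TOPIC_VOCAB = 24
_BACKGROUND_VOCAB = 30


def _vocab() -> tuple[list[list[str]], list[str]]:
    topics = [
        [f"{stem}{t}{i:02d}" for i in range(_TOPIC_VOCAB)]
        for t, stem in enumerate(["kinase", "pathway", "assay", "genome"])
    ]
    background = [f"common{i:02d}" for i in range(_BACKGROUND_VOCAB)]
    return topics, background


def _sentence(rng: np.random.Generator, pool: Sequence[str], n_words: int, prefix: str = "") -> str:
    words = list(rng.choice(pool, size=n_words, replace=True))
    body = " ".join(words)
    text = (prefix + " " + body).strip()
    return text[0].upper() + text[1:] + "."


def generate_article(
    spec: SyntheticSpec, article_id: str = "synthetic-0001", seed: int | None = None
) -> tuple[Article, GoldRanking]:
    """One synthetic article with planted importance structure."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    topics, background = _vocab()
    n_fig = int(rng.choice(spec.figure_counts, p=spec.figure_count_probs))

    if spec.importance_gradient > 0:
        strict = rng.permutation(n_fig) + 1
        ranks = _inject_ties(strict, spec.tie_probability, rng)
    else:
        ranks = [1] * n_fig  # symmetric figures: all tied

    # the article's "central" topic dominates title/abstract
    central = topics[0]
    title_pool = central[:10] + background[:5]
    title = _sentence(rng, title_pool, 7)[:-1]
    abstract = " ".join(_sentence(rng, central + background, 12) for _ in range(3))

    max_rank = max(ranks)
    # importance in [1..m], larger = more important
    importance = [max_rank - r + 1 for r in ranks]

    figures = []
    for pos in range(n_fig):
        label = str(pos + 1)
        imp = importance[pos]
        fig_topic = topics[pos % _N_TOPICS]
        n_central = int(round(spec.importance_gradient * 2 * imp))
        caption_pool = central[:10] * max(1, n_central) + fig_topic + background
        markers = ""
        n_sub = min(6, 1 + int(spec.importance_gradient * (imp - 1)))
        if n_sub > 1:
            letters = "ABCDEF"[:n_sub]
            markers = " ".join(
                f"{ch}. {_sentence(rng, fig_topic, 4)}" for ch in letters
            )
        caption = f"{_sentence(rng, caption_pool, 8)} {markers}".strip()
        figures.append(Figure(position=pos + 1, label=label, caption=caption))

    def mention_paragraph(pos: int, pool: Sequence[str], n_mentions: int) -> str:
        sents = [_sentence(rng, pool + background, 9)]
        for _ in range(n_mentions):
            sents.append(
                _sentence(rng, pool, 8, prefix=f"as shown in Figure {pos + 1},")
            )
            sents.append(_sentence(rng, pool + background, 9))
        return " ".join(sents)

    intro = Section(
        "Introduction",
        "INTRO",
        [_sentence(rng, central + background, 14) for _ in range(2)],
    )
    methods = Section(
        "Methods",
        "METHODS",
        [_sentence(rng, topics[2] + background, 14) for _ in range(2)],
    )
    results_paras = []
    discussion_paras = []
    for pos in range(n_fig):
        imp = importance[pos]
        pool = topics[pos % _N_TOPICS] + central[: 2 * imp]
        n_res = max(1, int(round(spec.importance_gradient * imp)))
        results_paras.append(mention_paragraph(pos, pool, n_res))
        n_disc = max(0, int(round(spec.importance_gradient * (imp - 1))))
        if n_disc or pos == 0:
            discussion_paras.append(mention_paragraph(pos, pool, max(1, n_disc)))
    if not discussion_paras:
        discussion_paras = [_sentence(rng, central + background, 14)]
    results = Section("Results", "RESULTS", results_paras)
    discussion = Section("Discussion", "DISCUSSION", discussion_paras)

    article = Article(
        article_id=article_id,
        title=title,
        abstract=abstract,
        sections=[intro, methods, results, discussion],
        figures=figures,
    )
    attach_contexts(article)
    return article, GoldRanking(article_id, list(ranks))


def generate_corpus(spec: SyntheticSpec) -> list[tuple[Article, GoldRanking]]:
    """A corpus of articles, reproducible from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_articles)
    return [
        generate_article(spec, article_id=f"synthetic-{i:04d}", seed=int(s))
        for i, s in enumerate(seeds)
    ]


def write_corpus(
    corpus: Sequence[tuple[Article, GoldRanking]],
    out_dir: str | Path,
    spec: SyntheticSpec | None = None,
) -> None:
    """Write article JSON files, the gold TSV and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for article, _ in corpus:
        write_article_json(article, out / f"{article.article_id}.json")
    write_gold_rankings([g for _, g in corpus], out / "gold.tsv")
    manifest = {"n_articles": len(corpus)}
    if spec is not None:
        manifest.update(
            seed=spec.seed,
            tie_probability=spec.tie_probability,
            importance_gradient=spec.importance_gradient,
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
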