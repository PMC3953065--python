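"""LDA topic features.

A topic model is fitted per article, treating each paragraph as a document.
Topics are ranked by cosine similarity of their representation to the
article's title+abstract, and the top four are compared with each figure
under two topic representations: the most probable words (WORDS) and the
concatenation of the paragraphs whose argmax topic it is (PARAGRAPHS).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer

from .corpus import Article, Figure
from .features import VectorSpace, tokenize, _figure_texts

logger = logging.getLogger(__name__)

WORDS = "WORDS"
PARAGRAPHS = "PARAGRAPHS"

N_TOP_TOPICS = 4  # features cover the four most title/abstract-relevant topics
N_TOP_WORDS = 20  # WORDS representation size
DEFAULT_K = 10
DEFAULT_MAX_ITER = 500


@dataclass
class TopicRepresentation:
    topic_id: int
    mode: str  # WORDS or PARAGRAPHS
    text: str


class TopicModel:
    """Fitted LDA over a list of paragraphs (rows of both matrices sum to 1)."""

    def __init__(
        self,
        paragraphs: Sequence[str],
        doc_topic: np.ndarray,
        topic_word: np.ndarray,
        vocabulary: list[str],
        seed: int,
    ):
        self.paragraphs = list(paragraphs)
        self.doc_topic = doc_topic
        self.topic_word = topic_word
        self.vocabulary = vocabulary
        self.seed = seed

    @property
    def k(self) -> int:
        return self.topic_word.shape[0]

    def top_words(self, topic_id: int, n: int = N_TOP_WORDS) -> list[str]:
        order = np.argsort(self.topic_word[topic_id])[::-1][:n]
        return [self.vocabulary[i] for i in order]

    def representation(self, topic_id: int, mode: str) -> TopicRepresentation:
        if mode == WORDS:
            text = " ".join(self.top_words(topic_id))
        elif mode == PARAGRAPHS:
            members = np.flatnonzero(self.doc_topic.argmax(axis=1) == topic_id)
            text = " ".join(self.paragraphs[i] for i in members)
        else:
            raise ValueError(f"unknown representation mode {mode!r}")
        return TopicRepresentation(topic_id, mode, text)

    def dump(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "top_words": {t: self.top_words(t) for t in range(self.k)},
            "doc_topic": self.doc_topic.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def fit_lda(
    paragraphs: Sequence[str],
    k: int = DEFAULT_K,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
) -> TopicModel:
    """Fit LDA on paragraphs-as-documents (deterministic given the seed).

    k is clamped to the number of usable paragraphs; priors are symmetric
    (alpha = 1/k, eta = 0.01), batch variational EM.
    """
    paragraphs = [p for p in paragraphs if p and p.strip()]
    if not paragraphs:
        raise ValueError("need at least one non-empty paragraph")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(paragraphs):
        logger.warning(
            "k=%d exceeds paragraph count %d; clamping", k, len(paragraphs)
        )
        k = len(paragraphs)
    vectorizer = CountVectorizer(
        tokenizer=tokenize, preprocessor=lambda t: t, token_pattern=None
    )
    counts = vectorizer.fit_transform(paragraphs)
    lda = LatentDirichletAllocation(
        n_components=k,
        doc_topic_prior=1.0 / k,
        topic_word_prior=0.01,
        max_iter=max_iter,
        learning_method="batch",
        random_state=seed,
    )
    doc_topic = lda.fit_transform(counts)
    doc_topic = doc_topic / doc_topic.sum(axis=1, keepdims=True)
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModel(
        paragraphs, doc_topic, topic_word, vectorizer.get_feature_names_out().tolist(), seed
    )


def rank_topics(
    model: TopicModel, title: str, abstract: str, space: VectorSpace
) -> list[int]:
    """Topic ids sorted by descending cosine(WORDS representation, title+abstract)."""
    anchor = (title + " " + abstract).strip()
    scored = []
    for t in range(model.k):
        rep = model.representation(t, WORDS).text
        score = space.cosine(rep, anchor) if anchor and rep else 0.0
        scored.append((-score, t))
    return [t for _, t in sorted(scored)]


def topic_feature_names() -> list[str]:
    """Registry names for the 26 topic features (24 pairwise + 2 cumulative)."""
    names = []
    for rep in ("caption", "context", "capctx"):
        for rank in range(1, N_TOP_TOPICS + 1):
            for mode in (WORDS, PARAGRAPHS):
                names.append(f"topic_{rep}_top{rank}_{mode.lower()}")
    names.append("topic_cumulative_top2_words")
    names.append("topic_cumulative_top2_paragraphs")
    return names


class ArticleTopics:
    """Topic model of one article plus its relevance-ordered topics.

    Topic order for the 24 pairwise features follows title+abstract
    relevance; the two cumulative features use the abstract-only order.
    """

    def __init__(
        self,
        article: Article,
        space: VectorSpace,
        k: int = DEFAULT_K,
        seed: int = 0,
        max_iter: int = DEFAULT_MAX_ITER,
    ):
        paragraphs = [p for sec in article.sections for p in sec.paragraphs]
        self.model = fit_lda(paragraphs, k=k, seed=seed, max_iter=max_iter)
        self.order_title_abstract = rank_topics(
            self.model, article.title, article.abstract, space
        )
        self.order_abstract = rank_topics(self.model, "", article.abstract, space)
        self._rep_cache: dict[tuple[int, str], str] = {}

    def _rep_text(self, topic_id: int, mode: str) -> str:
        key = (topic_id, mode)
        if key not in self._rep_cache:
            self._rep_cache[key] = self.model.representation(topic_id, mode).text
        return self._rep_cache[key]

    def topic_features(self, figure: Figure, space: VectorSpace) -> dict[str, float]:
        reprs = _figure_texts(figure)
        out: dict[str, float] = {}
        for rep_name in ("caption", "context", "capctx"):
            fig_text = reprs[rep_name]
            for rank in range(1, N_TOP_TOPICS + 1):
                for mode in (WORDS, PARAGRAPHS):
                    name = f"topic_{rep_name}_top{rank}_{mode.lower()}"
                    if rank > self.model.k or not fig_text.strip():
                        out[name] = 0.0
                        continue
                    topic_id = self.order_title_abstract[rank - 1]
                    topic_text = self._rep_text(topic_id, mode)
                    out[name] = (
                        space.cosine(fig_text, topic_text) if topic_text.strip() else 0.0
                    )
        ctx = reprs["context"]
        for mode in (WORDS, PARAGRAPHS):
            name = f"topic_cumulative_top2_{mode.lower()}"
            total = 0.0
            if ctx.strip():
                for topic_id in self.order_abstract[: min(2, self.model.k)]:
                    topic_text = self._rep_text(topic_id, mode)
                    if topic_text.strip():
                        total += space.cosine(ctx, topic_text)
            out[name] = total
        return out
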