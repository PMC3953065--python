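"""Figure feature extraction.

Each figure of an article is turned into a named numeric vector with four
categories: centrality (cosine similarity between figure text and article
parts), frequency (mention counts per IMRAD section), topic (similarity to
LDA topics; see :mod:`figrank.topics`) and structural (position, links
between figures, sub-figure count).  All cosines are computed in a shared
tf-idf space whose idf statistics come from the article collection.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import (
    Article,
    Figure,
    GoldRanking,
    IMRAD_CATEGORIES,
    SchemaError,
    detect_figure_mentions,
    split_sentences,
)

# A compact stopword list; enough to keep function words out of the cosines.
STOPWORDS = frozenset(
    """a an and are as at be been but by for from has have in into is it its of on
    or that the their there these this those to was we were which while with within
    our can may will not no than then also between each during under over both""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")

_SUFFIXES = ("ingly", "edly", "ing", "ed", "ies", "es", "s")


def _light_stem(token: str) -> str:
    for suf in _SUFFIXES:
        if token.endswith(suf) and len(token) - len(suf) >= 3:
            stem = token[: -len(suf)]
            if suf == "ies":
                stem += "y"
            return stem
    return token


def tokenize(text: str, stem: bool = False) -> list[str]:
    toks = [t for t in _TOKEN_RE.findall(text.lower()) if t not in STOPWORDS]
    if stem:
        toks = [_light_stem(t) for t in toks]
    return toks


@dataclass(frozen=True)
class SpaceSpec:
    """Preprocessing choices for the shared vector space."""

    lowercase: bool = True
    stem: bool = False
    use_idf: bool = True  # raw-tf mode when False


class VectorSpace:
    """tf-idf vector space over a text collection (deterministic)."""

    def __init__(self, texts: Sequence[str], spec: SpaceSpec | None = None):
        texts = [t for t in texts if t is not None]
        if not texts or not any(t.strip() for t in texts):
            raise ValueError("cannot build a vector space from an empty corpus")
        self.spec = spec or SpaceSpec()
        self._vectorizer = TfidfVectorizer(
            tokenizer=lambda t: tokenize(t, stem=self.spec.stem),
            preprocessor=lambda t: t,
            token_pattern=None,
            use_idf=self.spec.use_idf,
            norm=None,
            smooth_idf=True,
        )
        self._vectorizer.fit(texts)
        self._cache: dict[str, tuple] = {}

    @property
    def vocabulary(self) -> dict[str, int]:
        return self._vectorizer.vocabulary_

    @property
    def idf(self) -> np.ndarray:
        if not self.spec.use_idf:
            return np.ones(len(self.vocabulary))
        return self._vectorizer.idf_

    def transform(self, text: str) -> np.ndarray:
        return self._sparse(text).toarray().ravel()

    def _sparse(self, text: str):
        # texts repeat heavily across figures (sections, topics, captions);
        # cache the sparse vectors, bounding memory on huge corpora
        hit = self._cache.get(text)
        if hit is None:
            if len(self._cache) > 20000:
                self._cache.clear()
            hit = self._vectorizer.transform([text])
            self._cache[text] = hit
        return hit

    def cosine(self, text_a: str, text_b: str) -> float:
        """Cosine similarity in [0,1]; 0 when either vector is zero."""
        va = self._sparse(text_a)
        vb = self._sparse(text_b)
        na = np.sqrt(va.multiply(va).sum())
        nb = np.sqrt(vb.multiply(vb).sum())
        if na == 0.0 or nb == 0.0:
            return 0.0
        dot = va.multiply(vb).sum()
        return float(np.clip(dot / (na * nb), 0.0, 1.0))


def build_vector_space(texts: Sequence[str], spec: SpaceSpec | None = None) -> VectorSpace:
    return VectorSpace(texts, spec)


def cosine(text_a: str, text_b: str, space: VectorSpace) -> float:
    return space.cosine(text_a, text_b)


# ---------------------------------------------------------------------------
# Feature extractors
# ---------------------------------------------------------------------------

_FIG_REPRS = ("caption", "context", "capctx")


def _figure_texts(figure: Figure) -> dict[str, str]:
    cap = figure.caption or ""
    ctx = figure.associated_context or ""
    return {"caption": cap, "context": ctx, "capctx": (cap + " " + ctx).strip()}


def centrality_features(
    article: Article, figure: Figure, space: VectorSpace
) -> dict[str, float]:
    """15 cosine features: figure text vs IMRAD sections and whole article."""
    reprs = _figure_texts(figure)
    out: dict[str, float] = {}
    for cat in IMRAD_CATEGORIES:
        section_text = article.imrad_text(cat)
        for rep in _FIG_REPRS:
            name = f"cent_{rep}_{cat}"
            if not section_text.strip() or not reprs[rep].strip():
                out[name] = 0.0
            else:
                out[name] = space.cosine(reprs[rep], section_text)
    for scope_name, scope_text in (
        ("title", article.title),
        ("abstract", article.abstract),
        ("fulltext", article.full_text()),
    ):
        name = f"cent_capctx_{scope_name}"
        if not scope_text.strip() or not reprs["capctx"].strip():
            out[name] = 0.0
        else:
            out[name] = space.cosine(reprs["capctx"], scope_text)
    return out


def _section_mentions_by_paragraph(
    article: Article, figure: Figure, category: str
) -> list[tuple[str, int]]:
    """(paragraph, mention count) for every paragraph in an IMRAD category."""
    rows = []
    for sec in article.sections:
        if sec.imrad != category:
            continue
        for para in sec.paragraphs:
            n = sum(
                detect_figure_mentions(sent, figure.label)
                for sent in split_sentences(para)
            )
            rows.append((para, n))
    return rows


def frequency_features(
    article: Article, figure: Figure, space: VectorSpace | None = None
) -> dict[str, float]:
    """12 mention-frequency features.

    Four raw counts (one per IMRAD section), four weighted counts for
    RESULTS/DISCUSSION (paragraph mentions weighted by paragraph-title and
    paragraph-abstract cosine), and four length-normalised counts (raw count
    divided by the section's token count).
    """
    out: dict[str, float] = {}
    per_cat: dict[str, list[tuple[str, int]]] = {
        cat: _section_mentions_by_paragraph(article, figure, cat)
        for cat in IMRAD_CATEGORIES
    }
    for cat in IMRAD_CATEGORIES:
        out[f"freq_{cat}"] = float(sum(n for _, n in per_cat[cat]))
    for cat in ("RESULTS", "DISCUSSION"):
        for anchor_name, anchor_text in (
            ("title", article.title),
            ("abstract", article.abstract),
        ):
            val = 0.0
            if space is not None and anchor_text.strip():
                for para, n in per_cat[cat]:
                    if n:
                        val += n * space.cosine(para, anchor_text)
            out[f"freq_wt_{anchor_name}_{cat}"] = val
    for cat in IMRAD_CATEGORIES:
        n_tokens = len(tokenize(article.imrad_text(cat)))
        out[f"freq_norm_{cat}"] = (
            out[f"freq_{cat}"] / n_tokens if n_tokens else 0.0
        )
    return out


_SUBFIG_RE = re.compile(r"(?<![A-Za-z0-9])([a-fA-F])[.:,]|\(([a-fA-F])\)")


def count_subfigures(caption: str) -> int:
    """Distinct sub-figure markers ("A.", "b:", "c," or "(A)") in a caption."""
    letters = set()
    for m in _SUBFIG_RE.finditer(caption or ""):
        letters.add((m.group(1) or m.group(2)).lower())
    return len(letters)


def structural_features(
    article: Article, figure: Figure, space: VectorSpace
) -> dict[str, float]:
    """Position, figure-figure link statistics and sub-figure count."""
    own = _figure_texts(figure)["capctx"]
    sims = []
    for other in article.figures:
        if other.position == figure.position:
            continue
        other_text = _figure_texts(other)["capctx"]
        if own.strip() and other_text.strip():
            sims.append(space.cosine(own, other_text))
        else:
            sims.append(0.0)
    if sims:
        link_mean = float(np.mean(sims))
        link_std = float(np.std(sims))  # population std
    else:
        link_mean = link_std = 0.0
    return {
        "struct_position": float(figure.position),
        "struct_link_mean": link_mean,
        "struct_link_std": link_std,
        "struct_subfigures": float(count_subfigures(figure.caption)),
    }


# ---------------------------------------------------------------------------
# Registry and matrix assembly
# ---------------------------------------------------------------------------

#: Categories in the order the feature groups are described.
CATEGORY_ORDER = ("centrality", "frequency", "topic", "structural")


def _names_for_category(category: str, sample: dict[str, float]) -> list[str]:
    return sorted(sample)  # lexicographic within category


@dataclass
class FeatureVector:
    article_id: str
    position: int
    values: dict[str, float]


@dataclass
class FeatureMatrix:
    """Per-article feature vectors plus gold rankings under a fixed registry."""

    registry: list[str]
    articles: dict[str, list[FeatureVector]] = field(default_factory=dict)
    gold: dict[str, GoldRanking] = field(default_factory=dict)

    def as_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """article_id -> (X matrix [n_fig, n_feat], dense gold ranks)."""
        out = {}
        for aid, rows in self.articles.items():
            X = np.array(
                [[fv.values[name] for name in self.registry] for fv in rows],
                dtype=float,
            )
            ranks = np.array(self.gold[aid].ranks, dtype=int)
            out[aid] = (X, ranks)
        return out


def extract_all(
    article: Article,
    space: VectorSpace,
    topic_model=None,
    gold: GoldRanking | None = None,
) -> list[FeatureVector]:
    """All feature categories for every figure of one article.

    ``topic_model`` is a fitted :class:`figrank.topics.ArticleTopics`; when
    None the topic category contributes zero-valued features (the registry
    shape never changes).
    """
    from . import topics as topics_mod  # local import to avoid cycle

    rows = []
    for fig in article.figures:
        cent = centrality_features(article, fig, space)
        freq = frequency_features(article, fig, space)
        if topic_model is not None:
            top = topic_model.topic_features(fig, space)
        else:
            top = {name: 0.0 for name in topics_mod.topic_feature_names()}
        struct = structural_features(article, fig, space)
        values: dict[str, float] = {}
        for group in (cent, freq, top, struct):
            for name in _names_for_category("", group):
                v = float(group[name])
                if not math.isfinite(v):
                    raise ValueError(f"non-finite feature {name}={v}")
                values[name] = v
        rows.append(FeatureVector(article.article_id, fig.position, values))
    return rows


def registry_from_rows(rows: Sequence[FeatureVector]) -> list[str]:
    """Stable registry: categories in paper order, lexicographic within."""
    names = set(rows[0].values)
    by_prefix = {
        "centrality": sorted(n for n in names if n.startswith("cent_")),
        "frequency": sorted(n for n in names if n.startswith("freq_")),
        "topic": sorted(n for n in names if n.startswith("topic_")),
        "structural": sorted(n for n in names if n.startswith("struct_")),
    }
    ordered = []
    for cat in CATEGORY_ORDER:
        ordered.extend(by_prefix[cat])
    leftovers = sorted(names - set(ordered))
    ordered.extend(leftovers)
    return ordered


def write_registry_yaml(registry: Sequence[str], path: str | Path) -> None:
    import yaml

    header = (
        "# Figure feature registry: 15 centrality + 12 frequency + 26 topic\n"
        "# + 4 structural = 57 named features. The literature reports an\n"
        "# 89-feature inventory for this feature family without itemising the\n"
        "# per-category composition; this registry enumerates every feature\n"
        "# the text descriptions define exactly once instead of padding to\n"
        "# that total.\n"
    )
    rows = []
    for idx, name in enumerate(registry, start=1):
        prefix = name.split("_", 1)[0]
        category = {
            "cent": "centrality",
            "freq": "frequency",
            "topic": "topic",
            "struct": "structural",
        }.get(prefix, "other")
        rows.append({"index": idx, "name": name, "category": category})
    Path(path).write_text(
        header + yaml.safe_dump(rows, sort_keys=False), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# LETOR / SVM-rank qid format
# ---------------------------------------------------------------------------


def write_letor(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write "rel qid:i 1:v1 2:v2 ... # article_id/position" lines.

    Relevance is the reversed dense gold rank (most important figure gets the
    largest integer), the usual LETOR convention of higher-is-better.
    """
    lines = []
    qids = {aid: i + 1 for i, aid in enumerate(matrix.articles)}
    for aid, rows in matrix.articles.items():
        ranks = matrix.gold[aid].ranks
        max_rank = max(ranks)
        for fv, rank in zip(rows, ranks):
            rel = max_rank - rank  # reversed dense rank
            feats = " ".join(
                f"{i}:{fv.values[name]:.10g}"
                for i, name in enumerate(matrix.registry, start=1)
            )
            lines.append(f"{rel} qid:{qids[aid]} {feats} # {aid}/{fv.position}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_letor(path: str | Path, registry: Sequence[str] | None = None) -> FeatureMatrix:
    """Read a LETOR file back into a FeatureMatrix.

    Feature names default to "f1".."fd" when no registry is supplied.  Dense
    gold ranks are recovered from the relevance column (higher relevance ->
    better rank).
    """
    by_qid: dict[str, list[tuple[int, list[float], str, int]]] = {}
    dim = None
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        body, _, comment = line.partition("#")
        parts = body.split()
        rel = int(parts[0])
        if not parts[1].startswith("qid:"):
            raise SchemaError(f"{path}:{lineno}: missing qid field")
        qid = parts[1][4:]
        values = []
        for tok in parts[2:]:
            idx, _, val = tok.partition(":")
            if int(idx) != len(values) + 1:
                raise SchemaError(f"{path}:{lineno}: non-consecutive feature index")
            values.append(float(val))
        if dim is None:
            dim = len(values)
        elif len(values) != dim:
            raise SchemaError(
                f"{path}:{lineno}: inconsistent feature count "
                f"({len(values)} vs {dim})"
            )
        comment = comment.strip()
        aid, _, pos = comment.partition("/")
        aid = aid or f"q{qid}"
        position = int(pos) if pos.isdigit() else len(by_qid.get(qid, [])) + 1
        by_qid.setdefault(qid, []).append((rel, values, aid, position))
    if registry is None:
        registry = [f"f{i}" for i in range(1, (dim or 0) + 1)]
    elif len(registry) != dim:
        raise SchemaError(f"{path}: registry size {len(registry)} != file dim {dim}")
    matrix = FeatureMatrix(registry=list(registry))
    from .corpus import dense_ranks

    for qid, rows in by_qid.items():
        aid = rows[0][2]
        vectors = [
            FeatureVector(aid, pos, dict(zip(registry, vals)))
            for rel, vals, _, pos in rows
        ]
        ranks = dense_ranks([-rel for rel, *_ in rows])
        matrix.articles[aid] = vectors
        matrix.gold[aid] = GoldRanking(aid, ranks)
    return matrix
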