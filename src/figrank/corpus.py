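"""Articles, figures and gold rankings.

A biomedical article is modelled as a title, an abstract and an ordered list
of sections, each mapped onto the IMRAD rhetoric (Introduction / Methods /
Results / Discussion); figures carry their caption and a derived *associated
context* — the sentences that mention the figure plus the two sentences on
either side.  Corresponding-author importance rankings (with ties) are kept
as dense ranks, one integer per figure position.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

INTRO = "INTRO"
METHODS = "METHODS"
RESULTS = "RESULTS"
DISCUSSION = "DISCUSSION"
OTHER = "OTHER"

IMRAD_CATEGORIES = (INTRO, METHODS, RESULTS, DISCUSSION)

#: Heading synonyms, matched case-insensitively after stripping punctuation.
#: Combined "results and discussion" headings resolve to RESULTS so that the
#: shared text is counted once by frequency and centrality features.
_IMRAD_SYNONYMS = {
    INTRO: {
        "introduction",
        "background",
        "introduction and background",
    },
    METHODS: {
        "methods",
        "method",
        "materials and methods",
        "material and methods",
        "methods and materials",
        "materials & methods",
        "methodology",
        "experimental procedures",
        "experimental section",
        "study design",
        "patients and methods",
        "subjects and methods",
    },
    RESULTS: {
        "results",
        "findings",
        "results and discussion",
        "results & discussion",
        "results and discussions",
    },
    DISCUSSION: {
        "discussion",
        "discussions",
        "discussion and conclusion",
        "discussion and conclusions",
        "conclusions and discussion",
    },
}

_HEADING_CLEAN_RE = re.compile(r"[^a-z&\s]")


class SchemaError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


@dataclass
class Figure:
    position: int  # 1-based order of appearance
    label: str  # display number referenced in text, e.g. "3"
    caption: str
    associated_context: str = ""


@dataclass
class Section:
    heading: str
    imrad: str
    paragraphs: list[str] = field(default_factory=list)


@dataclass
class Article:
    article_id: str
    title: str
    abstract: str
    sections: list[Section]
    figures: list[Figure]

    def imrad_text(self, category: str) -> str:
        """Concatenated paragraph text of every section in an IMRAD category."""
        parts: list[str] = []
        for sec in self.sections:
            if sec.imrad == category:
                parts.extend(sec.paragraphs)
        return " ".join(parts)

    def full_text(self) -> str:
        parts = [self.title, self.abstract]
        for sec in self.sections:
            parts.extend(sec.paragraphs)
        return " ".join(p for p in parts if p)

    def n_figures(self) -> int:
        return len(self.figures)


@dataclass
class GoldRanking:
    """Dense reference ranks (1,2,2,3 style), one per figure position."""

    article_id: str
    ranks: list[int]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise SchemaError(f"empty rank list for article {self.article_id!r}")
        if min(self.ranks) < 1:
            raise SchemaError(
                f"non-positive rank in article {self.article_id!r}: {self.ranks}"
            )


def map_imrad(heading: str) -> str:
    """Map a section heading onto an IMRAD category (OTHER when unknown)."""
    key = _HEADING_CLEAN_RE.sub("", heading.lower()).strip()
    key = re.sub(r"\s+", " ", key)
    for category, synonyms in _IMRAD_SYNONYMS.items():
        if key in synonyms:
            return category
    return OTHER


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

#: Abbreviations whose trailing period must not end a sentence.
_ABBREVIATIONS = [
    "Fig.", "Figs.", "fig.", "figs.", "et al.", "e.g.", "i.e.", "cf.",
    "vs.", "ca.", "approx.", "Dr.", "No.", "no.", "Eq.", "Eqs.",
]

_SENT_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\"'])")


def split_sentences(text: str) -> list[str]:
    """Split text into sentences, guarding common scientific abbreviations."""
    if not text or not text.strip():
        return []
    protected = text
    for i, abbr in enumerate(_ABBREVIATIONS):
        protected = protected.replace(abbr, abbr[:-1] + f"\x00{i}\x00")
    pieces = _SENT_BOUNDARY_RE.split(protected)
    out = []
    for piece in pieces:
        for i, abbr in enumerate(_ABBREVIATIONS):
            piece = piece.replace(abbr[:-1] + f"\x00{i}\x00", abbr)
        piece = piece.strip()
        if piece:
            out.append(piece)
    return out


# ---------------------------------------------------------------------------
# Figure-mention detection
# ---------------------------------------------------------------------------

_MENTION_HEAD = r"(?:figures|figure|figs?\.?)"
# a figure token: number with an optional panel letter, e.g. "2" or "2A"
_FIG_TOKEN = r"\d+[A-Za-z]?"
# a list of tokens joined by commas, "and"/"or", ampersands or range dashes
_MENTION_RE = re.compile(
    rf"\b{_MENTION_HEAD}\s*"
    rf"({_FIG_TOKEN}(?:\s*(?:,|and|or|&|[-‐-―])\s*{_FIG_TOKEN})*)\b",
    re.IGNORECASE,
)
_RANGE_RE = re.compile(rf"({_FIG_TOKEN})\s*[-‐-―]\s*({_FIG_TOKEN})")
_TOKEN_RE = re.compile(_FIG_TOKEN)


def _expand_tokens(token_text: str) -> set[str]:
    """Labels referenced by one mention phrase, with ranges expanded."""
    labels: set[str] = set()
    rest = token_text
    for m in _RANGE_RE.finditer(token_text):
        lo = int(re.match(r"\d+", m.group(1)).group())
        hi = int(re.match(r"\d+", m.group(2)).group())
        if lo <= hi:
            labels.update(str(v) for v in range(lo, hi + 1))
        rest = rest.replace(m.group(0), " ")
    for tok in _TOKEN_RE.findall(rest):
        labels.add(re.match(r"\d+", tok).group())
    return labels


def detect_figure_mentions(sentence: str, label: str) -> int:
    """Count mention phrases in a sentence that reference a figure label.

    Panel suffixes ("Figure 2A") count as mentions of figure "2"; ranges
    ("Figures 2-4") include interior labels; bare numbers without a
    Figure/Fig head are never mentions.
    """
    target = re.match(r"\d+", str(label))
    if target is None:
        return 0
    target = target.group()
    count = 0
    for m in _MENTION_RE.finditer(sentence):
        if target in _expand_tokens(m.group(1)):
            count += 1
    return count


def extract_associated_context(article: Article, figure: Figure) -> str:
    """Sentences mentioning the figure ±2 neighbours, merged without repeats.

    Windows are clipped at paragraph boundaries and only body sections are
    scanned (abstract and title are represented separately by the features).
    """
    chunks: list[str] = []
    for sec in article.sections:
        for para in sec.paragraphs:
            sentences = split_sentences(para)
            hit = [
                i
                for i, sent in enumerate(sentences)
                if detect_figure_mentions(sent, figure.label) > 0
            ]
            if not hit:
                continue
            keep: set[int] = set()
            for i in hit:
                keep.update(range(max(0, i - 2), min(len(sentences), i + 3)))
            chunks.extend(sentences[i] for i in sorted(keep))
    if not chunks:
        logger.debug(
            "figure %s of article %s is never mentioned in the body",
            figure.label,
            article.article_id,
        )
    return " ".join(chunks)


def attach_contexts(article: Article) -> Article:
    """Populate associated_context for every figure (idempotent)."""
    for fig in article.figures:
        fig.associated_context = extract_associated_context(article, fig)
    return article


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _build_article(payload: dict, source: str) -> Article:
    for key in ("article_id", "title", "sections", "figures"):
        if key not in payload:
            raise SchemaError(f"{source}: missing required key {key!r}")
    if not payload["figures"]:
        raise SchemaError(f"{source}: article has no figures")
    if "abstract" not in payload or payload.get("abstract") is None:
        logger.warning("%s: article has no abstract; using empty string", source)
        payload = {**payload, "abstract": ""}
    sections = []
    for sec in payload["sections"]:
        if "heading" not in sec or "paragraphs" not in sec:
            raise SchemaError(f"{source}: section missing 'heading' or 'paragraphs'")
        imrad = sec.get("imrad") or map_imrad(sec["heading"])
        if imrad not in IMRAD_CATEGORIES + (OTHER,):
            raise SchemaError(f"{source}: unknown imrad label {imrad!r}")
        sections.append(Section(sec["heading"], imrad, list(sec["paragraphs"])))
    figures = []
    for pos, fig in enumerate(payload["figures"], start=1):
        if "caption" not in fig:
            raise SchemaError(f"{source}: figure {pos} missing 'caption'")
        figures.append(
            Figure(position=pos, label=str(fig.get("label", pos)), caption=fig["caption"])
        )
    article = Article(
        article_id=str(payload["article_id"]),
        title=payload["title"],
        abstract=payload["abstract"],
        sections=sections,
        figures=figures,
    )
    return attach_contexts(article)


def read_article_json(path: str | Path) -> Article:
    """Read one article from the plain JSON schema."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: top level must be an object")
    return _build_article(payload, str(path))


def article_to_json(article: Article) -> dict:
    """Canonical JSON payload (round-trips through read_article_json)."""
    return {
        "article_id": article.article_id,
        "title": article.title,
        "abstract": article.abstract,
        "sections": [
            {"heading": s.heading, "imrad": s.imrad, "paragraphs": list(s.paragraphs)}
            for s in article.sections
        ],
        "figures": [{"label": f.label, "caption": f.caption} for f in article.figures],
    }


def write_article_json(article: Article, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(article_to_json(article), indent=1, sort_keys=False) + "\n",
        encoding="utf-8",
    )


def read_jats_xml(path: str | Path) -> Article:
    """Read a JATS-like NXML article (front / body / fig elements)."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SchemaError(f"{path}: not well-formed XML ({exc})") from exc
    root = tree.getroot()
    body = root.find(".//body")
    if body is None:
        raise SchemaError(f"{path}: missing <body> element")

    def text_of(elem) -> str:
        if elem is None:
            return ""
        return re.sub(r"\s+", " ", " ".join(elem.itertext())).strip()

    title = text_of(root.find(".//front//article-meta//title-group//article-title"))
    abstract = text_of(root.find(".//front//article-meta//abstract"))
    article_id = text_of(root.find(".//front//article-meta//article-id")) or path.stem

    sections = []
    for sec in body.findall("./sec"):
        heading = text_of(sec.find("./title"))
        paragraphs = [text_of(p) for p in sec.findall(".//p")]
        paragraphs = [p for p in paragraphs if p]
        sections.append(Section(heading, map_imrad(heading), paragraphs))
    if not sections:  # body with bare paragraphs
        paragraphs = [text_of(p) for p in body.findall("./p")]
        sections.append(Section("", OTHER, [p for p in paragraphs if p]))

    figures = []
    for pos, fig in enumerate(body.iter("fig"), start=1):
        caption = text_of(fig.find("./caption"))
        if not caption:
            logger.warning("%s: fig %d has no caption", path, pos)
        label_el = fig.find("./label")
        label = text_of(label_el)
        label_num = re.search(r"\d+", label or "")
        figures.append(
            Figure(
                position=pos,
                label=label_num.group() if label_num else str(pos),
                caption=caption,
            )
        )
    if not figures:
        raise SchemaError(f"{path}: article has no figures")
    article = Article(article_id, title, abstract, sections, figures)
    return attach_contexts(article)


def dense_ranks(raw: Sequence[int | float]) -> list[int]:
    """Normalize raw ranks to dense numbering (1,3,3 -> 1,2,2)."""
    return [int(r) for r in rankdata(raw, method="dense")]


def read_gold_rankings(path: str | Path) -> dict[str, GoldRanking]:
    """Read the gold TSV: article_id <TAB> comma-separated ranks."""
    out: dict[str, GoldRanking] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            article_id, rank_field = line.split("\t")
        except ValueError as exc:
            raise SchemaError(f"{path}:{lineno}: expected two tab-separated fields") from exc
        try:
            raw = [int(tok) for tok in rank_field.split(",")]
        except ValueError as exc:
            raise SchemaError(f"{path}:{lineno}: non-integer rank") from exc
        if any(r <= 0 for r in raw):
            raise SchemaError(f"{path}:{lineno}: non-positive rank")
        out[article_id] = GoldRanking(article_id, dense_ranks(raw))
    return out


def write_gold_rankings(gold: Iterable[GoldRanking], path: str | Path) -> None:
    lines = [f"{g.article_id}\t{','.join(map(str, g.ranks))}" for g in gold]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def check_consistency(article: Article, gold: GoldRanking) -> None:
    if len(gold.ranks) != article.n_figures():
        raise SchemaError(
            f"article {article.article_id!r}: {article.n_figures()} figures but "
            f"{len(gold.ranks)} gold ranks"
        )
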