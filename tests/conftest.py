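import json

import numpy as np
import pytest

from figrank.corpus import Article, Figure, GoldRanking, Section, attach_contexts
from figrank.features import build_vector_space
from figrank.ranker import RankingInstance


@pytest.fixture
def small_article() -> Article:
    """Three-figure article with known mention structure."""
    art = Article(
        article_id="art1",
        title="Kinase signalling controls membrane transport",
        abstract="We study kinase signalling. Membrane transport depends on kinase activity.",
        sections=[
            Section(
                "Introduction",
                "INTRO",
                ["Kinase signalling is central to the cell. Transport matters."],
            ),
            Section(
                "Methods",
                "METHODS",
                ["Cells were cultured. Imaging was performed with a microscope."],
            ),
            Section(
                "Results",
                "RESULTS",
                [
                    "Baseline was recorded. As shown in Figure 1, kinase activity rose."
                    " The effect was strong. Controls stayed flat."
                    " Figure 2 shows membrane transport. Transport increased twofold.",
                    "We then examined localisation. Figure 1 and Figure 3 show"
                    " colocalisation. The overlap was extensive.",
                ],
            ),
            Section(
                "Discussion",
                "DISCUSSION",
                ["As shown in Figure 1, the kinase drives transport. This is new."],
            ),
        ],
        figures=[
            Figure(1, "1", "Kinase activity time course. A. control. B. treated."),
            Figure(2, "2", "Membrane transport quantification."),
            Figure(3, "3", "Colocalisation of kinase and membrane markers."),
        ],
    )
    return attach_contexts(art)


@pytest.fixture
def small_gold() -> GoldRanking:
    return GoldRanking("art1", [1, 2, 2])


@pytest.fixture
def small_space(small_article):
    texts = [small_article.title, small_article.abstract]
    for sec in small_article.sections:
        texts.extend(sec.paragraphs)
    for fig in small_article.figures:
        texts.append(fig.caption)
    return build_vector_space(texts)


@pytest.fixture
def article_json_file(tmp_path, small_article):
    payload = {
        "article_id": small_article.article_id,
        "title": small_article.title,
        "abstract": small_article.abstract,
        "sections": [
            {"heading": s.heading, "imrad": s.imrad, "paragraphs": s.paragraphs}
            for s in small_article.sections
        ],
        "figures": [{"label": f.label, "caption": f.caption} for f in small_article.figures],
    }
    path = tmp_path / "art1.json"
    path.write_text(json.dumps(payload), encoding="utf-8")
    return path


@pytest.fixture
def tiny_dataset() -> list[RankingInstance]:
    """Deterministic 12-list numeric dataset with a planted direction."""
    rng = np.random.default_rng(42)
    w_star = np.array([1.0, -0.5, 0.25])
    out = []
    for i in range(12):
        n = int(rng.integers(2, 6))
        X = rng.normal(size=(n, 3))
        scores = X @ w_star
        ranks = np.empty(n, dtype=int)
        ranks[np.argsort(-scores)] = np.arange(1, n + 1)
        out.append(RankingInstance(f"a{i}", X, ranks))
    return out
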