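"""Vector space, feature extractors and LETOR round trip."""

import math

import numpy as np
import pytest

from figrank.corpus import Article, Figure, GoldRanking, Section, attach_contexts
from figrank.features import (
    FeatureMatrix,
    FeatureVector,
    SchemaError,
    build_vector_space,
    centrality_features,
    cosine,
    count_subfigures,
    extract_all,
    frequency_features,
    read_letor,
    registry_from_rows,
    structural_features,
    write_letor,
)


class TestVectorSpace:
    def test_identical_documents_cosine_one(self):
        space = build_vector_space(["alpha beta gamma", "delta epsilon"])
        assert cosine("alpha beta", "alpha beta", space) == pytest.approx(1.0)

    def test_disjoint_vocabulary_cosine_zero(self):
        space = build_vector_space(["alpha beta", "gamma delta"])
        assert cosine("alpha", "gamma", space) == 0.0

    def test_stopword_only_document_is_zero_vector(self):
        space = build_vector_space(["alpha beta", "the and of"])
        assert cosine("the and of", "alpha beta", space) == 0.0
        assert cosine("the and of", "the and of", space) == 0.0

    def test_hand_computed_tfidf_cosine(self):
        # Two-document corpus; sklearn smooth idf: ln((1+n)/(1+df)) + 1
        space = build_vector_space(["alpha beta", "alpha gamma"])
        idf_shared = math.log(3 / 3) + 1  # df=2
        idf_rare = math.log(3 / 2) + 1  # df=1
        a = np.array([idf_shared, idf_rare, 0.0])
        b = np.array([idf_shared, 0.0, idf_rare])
        expected = (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cosine("alpha beta", "alpha gamma", space) == pytest.approx(
            expected, abs=1e-12
        )

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vector_space(["", "   "])

    def test_determinism(self):
        s1 = build_vector_space(["alpha beta", "gamma delta alpha"])
        s2 = build_vector_space(["alpha beta", "gamma delta alpha"])
        assert s1.vocabulary == s2.vocabulary
        assert np.allclose(s1.idf, s2.idf)


class TestCentrality:
    def test_fifteen_named_values_in_unit_interval(self, small_article, small_space):
        vals = centrality_features(small_article, small_article.figures[0], small_space)
        assert len(vals) == 15
        assert all(0.0 <= v <= 1.0 for v in vals.values())

    def test_missing_section_gives_zero(self, small_space, small_article):
        art = Article(
            "a",
            small_article.title,
            small_article.abstract,
            [s for s in small_article.sections if s.imrad != "METHODS"],
            small_article.figures,
        )
        vals = centrality_features(art, art.figures[0], small_space)
        assert all(v == 0.0 for k, v in vals.items() if k.endswith("_METHODS"))

    def test_caption_verbatim_results_paragraph(self):
        caption = "kinase phosphorylates membrane receptor strongly"
        art = Article(
            "a",
            "title words",
            "abstract words",
            [Section("Results", "RESULTS", [caption])],
            [Figure(1, "1", caption)],
        )
        space = build_vector_space([caption, "title words", "abstract words"])
        vals = centrality_features(art, art.figures[0], space)
        assert vals["cent_caption_RESULTS"] == pytest.approx(1.0)


class TestFrequency:
    def test_counts_and_normalisation(self, small_article, small_space):
        vals = frequency_features(small_article, small_article.figures[0], small_space)
        assert len(vals) == 12
        assert vals["freq_RESULTS"] == 2.0  # two mentioning sentences in RESULTS
        assert vals["freq_DISCUSSION"] == 1.0
        assert vals["freq_INTRO"] == 0.0
        n_tokens = len(
            [
                t
                for t in __import__("figrank.features", fromlist=["tokenize"]).tokenize(
                    small_article.imrad_text("RESULTS")
                )
            ]
        )
        assert vals["freq_norm_RESULTS"] == pytest.approx(2.0 / n_tokens)

    def test_weighted_frequency_hand_value(self):
        # one RESULTS paragraph with 2 mentions; weight = cosine(paragraph, title)
        para = "As shown in Figure 1, kinase rose. Figure 1 again shows kinase."
        art = Article(
            "a",
            "kinase kinase",
            "",
            [Section("Results", "RESULTS", [para])],
            [Figure(1, "1", "cap")],
        )
        space = build_vector_space([para, "kinase kinase", "cap"])
        vals = frequency_features(art, art.figures[0], space)
        expected = 2.0 * space.cosine(para, "kinase kinase")
        assert vals["freq_wt_title_RESULTS"] == pytest.approx(expected)
        assert vals["freq_wt_abstract_RESULTS"] == 0.0  # empty abstract


class TestStructural:
    def test_position_and_links(self, small_article, small_space):
        vals = structural_features(small_article, small_article.figures[0], small_space)
        assert vals["struct_position"] == 1.0
        assert 0.0 <= vals["struct_link_mean"] <= 1.0
        assert vals["struct_link_std"] >= 0.0
        assert vals["struct_subfigures"] == 2.0  # "A. control. B. treated."

    def test_single_figure_article_links_zero(self, small_space):
        art = Article(
            "a",
            "t",
            "",
            [Section("Results", "RESULTS", ["Figure 1 shows stuff."])],
            [Figure(1, "1", "only figure")],
        )
        attach_contexts(art)
        vals = structural_features(art, art.figures[0], small_space)
        assert vals["struct_link_mean"] == 0.0
        assert vals["struct_link_std"] == 0.0

    def test_identical_texts_give_zero_std(self):
        figs = [Figure(i, str(i), "same caption words") for i in (1, 2, 3)]
        art = Article("a", "t", "", [Section("Results", "RESULTS", [])], figs)
        space = build_vector_space(["same caption words", "other text"])
        vals = structural_features(art, figs[0], space)
        assert vals["struct_link_std"] == pytest.approx(0.0)
        assert vals["struct_link_mean"] == pytest.approx(1.0)


class TestSubfigures:
    @pytest.mark.parametrize(
        "caption,expected",
        [
            ("A. control. B. treated. C. merged.", 3),
            ("(A) before (B) after", 2),
            ("Overview of the pathway", 0),
            ("a, first panel; a. repeated letter", 1),
            ("Values of 3.2, 4.5 shown", 0),
            ("word a. mid-sentence B: two", 2),
        ],
    )
    def test_patterns(self, caption, expected):
        assert count_subfigures(caption) == expected


class TestExtractAll:
    def test_registry_shape_and_determinism(self, small_article, small_space):
        rows1 = extract_all(small_article, small_space, None)
        rows2 = extract_all(small_article, small_space, None)
        reg = registry_from_rows(rows1)
        # 15 centrality + 12 frequency + 26 topic + 4 structural
        assert len(reg) == 57
        for r1, r2 in zip(rows1, rows2):
            assert r1.values == r2.values
        # identical ordering for every figure
        assert all(set(r.values) == set(reg) for r in rows1)

    def test_registry_category_order(self, small_article, small_space):
        reg = registry_from_rows(extract_all(small_article, small_space, None))
        prefixes = [n.split("_")[0] for n in reg]
        boundaries = [prefixes.index(p) for p in ("cent", "freq", "topic", "struct")]
        assert boundaries == sorted(boundaries)


class TestLetor:
    def _matrix(self):
        reg = ["f1", "f2", "f3"]
        m = FeatureMatrix(registry=reg)
        m.articles["a1"] = [
            FeatureVector("a1", 1, {"f1": 0.5, "f2": 1.0, "f3": 0.0}),
            FeatureVector("a1", 2, {"f1": 0.25, "f2": 0.0, "f3": 2.0}),
        ]
        m.gold["a1"] = GoldRanking("a1", [1, 2])
        m.articles["a2"] = [
            FeatureVector("a2", 1, {"f1": 1.5, "f2": -1.0, "f3": 3.0}),
            FeatureVector("a2", 2, {"f1": 0.0, "f2": 0.5, "f3": 1.0}),
            FeatureVector("a2", 3, {"f1": 2.0, "f2": 0.125, "f3": 0.0}),
        ]
        m.gold["a2"] = GoldRanking("a2", [2, 1, 2])
        return m

    def test_round_trip(self, tmp_path):
        m = self._matrix()
        path = tmp_path / "data.letor"
        write_letor(m, path)
        m2 = read_letor(path, registry=m.registry)
        for aid in m.articles:
            assert m2.gold[aid].ranks == m.gold[aid].ranks
            for fv1, fv2 in zip(m.articles[aid], m2.articles[aid]):
                assert fv1.values == pytest.approx(fv2.values)

    def test_hand_written_line(self, tmp_path):
        path = tmp_path / "one.letor"
        path.write_text("2 qid:1 1:0.5 2:1.25 # art9/1\n")
        m = read_letor(path)
        (aid,) = m.articles
        assert aid == "art9"
        assert m.articles[aid][0].values == {"f1": 0.5, "f2": 1.25}

    def test_inconsistent_feature_count_rejected(self, tmp_path):
        path = tmp_path / "bad.letor"
        path.write_text("1 qid:1 1:0.5 2:1.0 3:0.0 # a/1\n0 qid:1 1:0.5 2:1.0 # a/2\n")
        with pytest.raises(SchemaError):
            read_letor(path)
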