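"""Text preprocessing pipeline and embedding-mean document vectors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import figword as fw
from figword import _porter
from figword.errors import FigwordError
from figword.text_repr import load_stopwords


class TestPorterStemmer:
    # canonical behavior of the original five-step algorithm, frozen as
    # full-word outputs
    CASES = [
        ("caresses", "caress"),
        ("ponies", "poni"),
        ("ties", "ti"),
        ("caress", "caress"),
        ("cats", "cat"),
        ("feed", "feed"),
        ("agreed", "agre"),
        ("plastered", "plaster"),
        ("bled", "bled"),
        ("motoring", "motor"),
        ("sing", "sing"),
        ("conflated", "conflat"),
        ("sized", "size"),
        ("hopping", "hop"),
        ("tanned", "tan"),
        ("falling", "fall"),
        ("hissing", "hiss"),
        ("fizzed", "fizz"),
        ("failing", "fail"),
        ("filing", "file"),
        ("happy", "happi"),
        ("sky", "sky"),
        ("relational", "relat"),
        ("conditional", "condit"),
        ("rational", "ration"),
        ("expression", "express"),
        ("mouse", "mous"),
        ("embryos", "embryo"),
        ("gene", "gene"),
        ("fluorescence", "fluoresc"),
        ("microscopy", "microscopi"),
        ("probate", "probat"),
        ("rate", "rate"),
        ("controlling", "control"),
        ("roll", "roll"),
        ("generalization", "gener"),
        ("adjustment", "adjust"),
        ("dependent", "depend"),
        ("activate", "activ"),
        ("effective", "effect"),
    ]

    @pytest.mark.parametrize("word,expected", CASES)
    def test_known_stems(self, word, expected):
        assert _porter.stem(word) == expected

    def test_short_words_pass_through(self):
        assert _porter.stem("go") == "go"
        assert _porter.stem("a") == "a"

    @settings(deadline=None, max_examples=200)
    @given(st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=1, max_size=15))
    def test_stemming_never_grows_and_is_deterministic(self, word):
        # full idempotence does not hold for the genuine algorithm
        # (agreed -> agre -> agr), so the contract is: deterministic,
        # never longer than the input, and always lowercase
        once = _porter.stem(word)
        assert once == _porter.stem(word)
        assert len(once) <= len(word)
        assert once == once.lower()


class TestPreprocess:
    def test_full_pipeline_with_ner(self, ner_map):
        td = fw.preprocess("Pax6 expression in mouse embryos", ner_map)
        assert td.tokens == ("gene", "express", "mous", "embryo")
        assert td.distinct_tokens == {"gene", "express", "mous", "embryo"}

    def test_empty_text_gives_empty_doc(self):
        assert fw.preprocess("").tokens == ()

    def test_pure_stopword_text_gives_empty_doc(self):
        assert fw.preprocess("the of and").tokens == ()

    def test_stopwords_removed_even_when_stem_leaves_list(self):
        # "this" stems to "thi"; the surface form is still a stop word
        assert fw.preprocess("this gene").tokens == ("gene",)

    def test_ner_is_longest_match_and_case_insensitive(self):
        ner = fw.NERSubstitutionMap({"mus": "species", "Mus musculus": "species"})
        td = fw.preprocess("Found in MUS MUSCULUS tissue", ner)
        assert td.tokens.count("speci") == 1  # one entity, not two

    def test_ner_rejects_non_generic_values(self):
        with pytest.raises(FigwordError):
            fw.NERSubstitutionMap({"Pax6": "transcription-factor"})

    def test_ner_map_reads_from_tsv(self, tmp_path):
        p = tmp_path / "ner.tsv"
        p.write_text("Pax6\tgene\nBRCA1\tgene\n")
        ner = fw.NERSubstitutionMap.from_tsv(p)
        assert fw.preprocess("BRCA1 binds", ner).tokens == ("gene", "bind")

    def test_stopword_list_is_loaded_from_package_data(self):
        sw = load_stopwords()
        assert {"the", "of", "and", "in"} <= sw
        assert len(sw) > 100


class TestMeanEmbedding:
    def test_single_token_returns_its_vector(self, tiny_table):
        td = fw.TokenizedDoc(tokens=("gene",))
        assert np.allclose(fw.mean_embedding(td, tiny_table), tiny_table["gene"])

    def test_distinct_semantics_ignore_frequency(self, tiny_table):
        """Tokens [a,a,a,b] average as (e_a + e_b)/2: each distinct word
        counts once and n counts distinct in-vocabulary words."""
        td = fw.TokenizedDoc(tokens=("gene", "gene", "gene", "cell"))
        expected = (tiny_table["gene"] + tiny_table["cell"]) / 2
        assert np.allclose(fw.mean_embedding(td, tiny_table), expected)

    def test_token_frequency_mode_weights_by_count(self, tiny_table):
        td = fw.TokenizedDoc(tokens=("gene", "gene", "gene", "cell"))
        expected = (3 * tiny_table["gene"] + tiny_table["cell"]) / 4
        assert np.allclose(
            fw.mean_embedding(td, tiny_table, distinct=False), expected
        )

    def test_fully_oov_doc_maps_to_zero_vector(self, tiny_table):
        td = fw.TokenizedDoc(tokens=("nosuchtoken",))
        vec = fw.mean_embedding(td, tiny_table)
        assert vec.shape == (4,) and np.all(vec == 0)

    def test_oov_tokens_excluded_from_divisor(self, tiny_table):
        td = fw.TokenizedDoc(tokens=("gene", "nosuchtoken"))
        assert np.allclose(fw.mean_embedding(td, tiny_table), tiny_table["gene"])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.sampled_from(["gene", "express", "mous", "embryo", "protein", "cell"]),
            min_size=1,
            max_size=12,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_and_multiplicity_invariance(self, tiny_table, tokens, rnd):
        base = fw.mean_embedding(fw.TokenizedDoc(tokens=tuple(tokens)), tiny_table)
        shuffled = list(tokens)
        rnd.shuffle(shuffled)
        assert np.allclose(
            fw.mean_embedding(fw.TokenizedDoc(tokens=tuple(shuffled)), tiny_table), base
        )
        assert np.allclose(
            fw.mean_embedding(
                fw.TokenizedDoc(tokens=tuple(tokens + [tokens[0]])), tiny_table
            ),
            base,
        )

    @settings(deadline=None, max_examples=50)
    @given(
        st.sets(
            st.sampled_from(["gene", "express", "mous", "embryo", "protein", "cell"]),
            min_size=1,
            max_size=6,
        )
    )
    def test_mean_lies_in_coordinatewise_hull(self, tiny_table, tokens):
        """Convexity: every coordinate of the mean lies between the min
        and max of that coordinate over contributing tokens."""
        vec = fw.mean_embedding(fw.TokenizedDoc(tokens=tuple(tokens)), tiny_table)
        stack = np.vstack([tiny_table[t] for t in tokens])
        assert np.all(vec >= stack.min(axis=0) - 1e-12)
        assert np.all(vec <= stack.max(axis=0) + 1e-12)


class TestDocumentVectors:
    def test_concat_captions_joins_in_figure_order(self):
        doc = fw.DocumentRecord(
            doc_id="d",
            figures=[
                fw.FigureRecord(caption="A panel."),
                fw.FigureRecord(caption="B panel."),
            ],
        )
        assert fw.concat_captions(doc) == "A panel. B panel."

    def test_concat_captions_skips_empty(self):
        doc = fw.DocumentRecord(
            doc_id="d",
            figures=[
                fw.FigureRecord(caption="x"),
                fw.FigureRecord(caption=""),
                fw.FigureRecord(caption="y"),
            ],
        )
        assert fw.concat_captions(doc) == "x y"
        assert fw.concat_captions(fw.DocumentRecord(doc_id="e")) == ""

    def test_caption_equals_ta_when_texts_match(self, tiny_table, ner_map):
        doc = fw.DocumentRecord(
            doc_id="d",
            title_abstract="Pax6 expression in mouse embryos",
            figures=[fw.FigureRecord(caption="Pax6 expression in mouse embryos")],
        )
        cap = fw.caption_vector(doc, tiny_table, ner_map)
        ta = fw.ta_vector(doc, tiny_table, ner_map)
        assert np.allclose(cap, ta)

    def test_captionless_doc_gets_zero_caption_vector(self, tiny_table):
        doc = fw.DocumentRecord(doc_id="d", title_abstract="gene")
        assert np.all(fw.caption_vector(doc, tiny_table) == 0)

    def test_all_vectors_have_embedding_dimension(self, synth_corpus):
        reps = synth_corpus["reps"]
        dim = synth_corpus["table"].dim
        assert reps.X_cap.shape == (80, dim)
        assert reps.X_ta.shape == (80, dim)
        assert np.isfinite(reps.X_cap).all() and np.isfinite(reps.X_ta).all()
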