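import numpy as np
import pytest

import figword as fw


@pytest.fixture(scope="session")
def taxonomy():
    return fw.DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def tiny_table():
    """Deterministic 6-token, 4-dim embedding table."""
    rng = np.random.default_rng(7)
    tokens = ["gene", "express", "mous", "embryo", "protein", "cell"]
    return fw.EmbeddingTable({t: rng.standard_normal(4) for t in tokens})


@pytest.fixture(scope="session")
def ner_map():
    return fw.NERSubstitutionMap({"Pax6": "gene", "Mus musculus": "species"})


@pytest.fixture()
def small_docs():
    """Three hand-built documents covering labels, empty captions and
    figure-less documents."""
    return [
        fw.DocumentRecord(
            doc_id="d1",
            label=fw.RELEVANT,
            title_abstract="Pax6 expression in mouse embryos",
            figures=[
                fw.FigureRecord(
                    caption="Histogram of expression",
                    panel_labels=["Histogram", "Fluorescence microscopy"],
                ),
                fw.FigureRecord(caption="", panel_labels=["Histogram"]),
            ],
        ),
        fw.DocumentRecord(
            doc_id="d2",
            label=fw.IRRELEVANT,
            title_abstract="Protein folding dynamics",
            figures=[fw.FigureRecord(caption="A gel.", panel_labels=["Gel/blot"])],
        ),
        fw.DocumentRecord(doc_id="d3", title_abstract="No figures here", figures=[]),
    ]


@pytest.fixture(scope="session")
def synth_corpus():
    """Small strongly-signalled synthetic corpus with its embedding
    table and precomputed representations (session-scoped: read-only)."""
    cfg = fw.SynthConfig(
        n_docs=80,
        seed=11,
        caption_signal=0.7,
        ta_signal=0.7,
        embedding_dim=32,
        tokens_per_caption=(10, 30),
        tokens_per_ta=(20, 50),
        figures_per_doc=(2, 5),
    )
    docs, manifest = fw.generate_corpus(cfg)
    table = fw.generate_embeddings(cfg)
    reps = fw.build_representations(docs, table)
    return {"cfg": cfg, "docs": docs, "manifest": manifest, "table": table, "reps": reps}
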