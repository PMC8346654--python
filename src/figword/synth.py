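"""Synthetic labeled corpora and embedding tables.

The generator emulates the statistical structure the pipeline's
representations assume: class-conditional panel-type composition of
figures (relevant and irrelevant publications favor different kinds of
images) and class-conditional unigram token distributions for captions
and titles-and-abstracts (each class has a set of topic words mixed into
a shared background vocabulary).  Default sizes mirror a mid-sized
curation corpus: a few hundred balanced documents averaging about eight
figures each, captions of several dozen informative tokens, abstracts a
couple of hundred.

It deliberately does *not* emulate syntax, discourse structure, realistic
word frequency tails, or correlations between text and images beyond the
shared class label — mean-of-embedding representations are insensitive to
the former, and the latter is exactly what the integration schemes are
meant to exploit.

A ``complementary`` mode assigns each document exactly one informative
modality (images, captions, or title-and-abstract, uniformly) and leaves
the other two at their class-independent null distributions.  Corpora
generated this way test whether the integration schemes recover signal
that no single modality carries for the whole corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import FigwordError
from .interchange import (
    DEFAULT_TAXONOMY,
    IRRELEVANT,
    RELEVANT,
    DocumentRecord,
    EmbeddingTable,
    FigureRecord,
    Taxonomy,
)

MODALITIES = ("img", "cap", "ta")


def _default_panel_probs() -> dict[str, list[float]]:
    # relevant publications favor fluorescence microscopy (position 6);
    # all other panel types are equally likely in both classes
    rel = [0.1] * 11
    irr = [0.1] * 11
    rel[5] = 0.6
    irr[5] = 0.05
    return {RELEVANT: rel, IRRELEVANT: irr}


@dataclass
class SynthConfig:
    """Knobs for corpus and embedding generation; the seed fully
    determines the output.

    ``caption_signal`` / ``ta_signal`` give the probability that a
    generated token comes from the document class's topic-word set
    rather than the shared background vocabulary; 0 means the text
    carries no class information.  ``panel_inclusion_probs`` gives, per
    class label, the per-panel-type Bernoulli inclusion probability used
    when composing each figure (empty draws are resampled — a real
    figure contains at least one panel).
    """

    n_docs: int = 400
    class_balance: float = 0.5  # P(relevant)
    figures_per_doc: tuple[int, int] = (5, 12)
    panel_inclusion_probs: dict[str, list[float]] = field(
        default_factory=_default_panel_probs
    )
    vocab_size: int = 2000
    topic_word_count: int = 50
    caption_signal: float = 0.3
    ta_signal: float = 0.3
    tokens_per_caption: tuple[int, int] = (40, 120)
    tokens_per_ta: tuple[int, int] = (100, 250)
    embedding_dim: int = 200
    complementary: bool = False
    seed: int = 0

    def validate(self, taxonomy: Taxonomy) -> None:
        for name, val in (
            ("class_balance", self.class_balance),
            ("caption_signal", self.caption_signal),
            ("ta_signal", self.ta_signal),
        ):
            if not 0.0 <= val <= 1.0:
                raise FigwordError(f"{name} must lie in [0, 1], got {val}")
        for label, probs in self.panel_inclusion_probs.items():
            if len(probs) != len(taxonomy):
                raise FigwordError(
                    f"panel_inclusion_probs[{label!r}] must have "
                    f"{len(taxonomy)} entries"
                )
            if not all(0.0 <= p <= 1.0 for p in probs):
                raise FigwordError("panel inclusion probabilities must lie in [0, 1]")
        if self.vocab_size < 2 * self.topic_word_count + 10:
            raise FigwordError(
                "vocab_size too small for two topic sets plus background"
            )
        if self.n_docs <= 0 or self.embedding_dim <= 0:
            raise FigwordError("n_docs and embedding_dim must be positive")


def _vocab(cfg: SynthConfig) -> tuple[list[str], dict[str, list[str]], list[str]]:
    words = [f"w{i:05d}" for i in range(cfg.vocab_size)]
    t = cfg.topic_word_count
    topics = {RELEVANT: words[:t], IRRELEVANT: words[t : 2 * t]}
    background = words[2 * t :]
    return words, topics, background


def _draw_tokens(
    rng: np.random.Generator,
    n: int,
    signal: float,
    topic: list[str],
    background: list[str],
) -> list[str]:
    out = []
    for _ in range(n):
        pool = topic if (signal > 0 and rng.random() < signal) else background
        out.append(pool[rng.integers(len(pool))])
    return out


def _draw_panels(
    rng: np.random.Generator, probs: Sequence[float], taxonomy: Taxonomy
) -> list[str]:
    # resample until non-empty: a figure always contains >= 1 panel
    while True:
        mask = rng.random(len(probs)) < np.asarray(probs)
        if mask.any():
            return [taxonomy.classes[i] for i in np.nonzero(mask)[0]]


def generate_corpus(
    cfg: SynthConfig, taxonomy: Taxonomy = DEFAULT_TAXONOMY
) -> tuple[list[DocumentRecord], dict]:
    """Generate a labeled corpus plus a ground-truth manifest.

    The manifest records the generating parameters and, in complementary
    mode, each document's informative modality, so tests can assert
    recovery against known structure.
    """
    cfg.validate(taxonomy)
    rng = np.random.default_rng(cfg.seed)
    _, topics, background = _vocab(cfg)
    null_panel = np.mean(
        [cfg.panel_inclusion_probs[RELEVANT], cfg.panel_inclusion_probs[IRRELEVANT]],
        axis=0,
    )
    docs: list[DocumentRecord] = []
    informative: dict[str, str] = {}
    for i in range(cfg.n_docs):
        label = RELEVANT if rng.random() < cfg.class_balance else IRRELEVANT
        mode = MODALITIES[rng.integers(3)] if cfg.complementary else None
        if mode is not None:
            informative[f"doc{i:05d}"] = mode

        panel_probs = cfg.panel_inclusion_probs[label]
        cap_sig, ta_sig = cfg.caption_signal, cfg.ta_signal
        if cfg.complementary:
            if mode != "img":
                panel_probs = null_panel
            cap_sig = cfg.caption_signal if mode == "cap" else 0.0
            ta_sig = cfg.ta_signal if mode == "ta" else 0.0

        n_figs = int(rng.integers(cfg.figures_per_doc[0], cfg.figures_per_doc[1] + 1))
        figures = []
        for _ in range(n_figs):
            labels = _draw_panels(rng, panel_probs, taxonomy)
            n_tok = int(
                rng.integers(cfg.tokens_per_caption[0], cfg.tokens_per_caption[1] + 1)
            )
            caption = " ".join(
                _draw_tokens(rng, n_tok, cap_sig, topics[label], background)
            )
            figures.append(FigureRecord(caption=caption, panel_labels=labels))
        n_ta = int(rng.integers(cfg.tokens_per_ta[0], cfg.tokens_per_ta[1] + 1))
        ta = " ".join(_draw_tokens(rng, n_ta, ta_sig, topics[label], background))
        docs.append(
            DocumentRecord(
                doc_id=f"doc{i:05d}", title_abstract=ta, figures=figures, label=label
            )
        )
    manifest = {
        "config": asdict(cfg),
        "taxonomy": list(taxonomy.classes),
        "topic_words": {k: list(v) for k, v in topics.items()},
        "informative_modality": informative,
    }
    return docs, manifest


def generate_embeddings(cfg: SynthConfig) -> EmbeddingTable:
    """One unit-norm random vector per vocabulary token.

    Independent Gaussian directions in ``embedding_dim`` dimensions are
    nearly orthogonal, so the two classes' topic-word sets are not
    collinear by construction and an embedding-mean classifier can
    separate them exactly when the corpus carries text signal.
    Seed-deterministic (seed offset from the corpus stream so corpus and
    table draws do not interact).
    """
    if cfg.vocab_size < 2 * cfg.topic_word_count + 10:
        raise FigwordError("vocab_size too small for two topic sets plus background")
    if cfg.embedding_dim <= 0:
        raise FigwordError("embedding_dim must be positive")
    rng = np.random.default_rng((cfg.seed + 909091) % (2**31 - 1))
    words, _, _ = _vocab(cfg)
    vecs = {}
    for w in words:
        v = rng.standard_normal(cfg.embedding_dim)
        vecs[w] = v / np.linalg.norm(v)
    return EmbeddingTable(vecs)
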