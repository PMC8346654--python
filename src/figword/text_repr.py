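"""Text preprocessing and embedding-mean document vectors.

Captions (concatenated per document) and titles-and-abstracts go through
the same pipeline: named-entity substitution, lowercasing, tokenization
on non-alphanumeric boundaries, Porter stemming, and stop-word removal.
A document's text vector is the mean of the embedding vectors of its
*distinct* in-vocabulary tokens — each distinct word contributes once
regardless of how often it occurs.

Named-entity recognition is a static substitution map (surface form →
one of six generic concept terms: gene, disease, chemical, species,
mutation, cell-line) rather than a call to a live annotation service;
any external annotator can be adapted by materializing its output as
such a map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from . import _porter
from .errors import FigwordError
from .interchange import DocumentRecord, EmbeddingTable

GENERIC_TERMS = ("gene", "disease", "chemical", "species", "mutation", "cell-line")

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def load_stopwords() -> frozenset[str]:
    """The standard English stop-word list frozen into the package data
    (one word per line)."""
    text = resources.files("figword").joinpath("data/stopwords.txt").read_text("utf-8")
    return frozenset(w for w in text.splitlines() if w)


_STOPWORDS = load_stopwords()


class NERSubstitutionMap:
    """Surface form → generic concept term map.

    Substitution is longest-match first and case-insensitive, so
    overlapping surface forms resolve deterministically and multi-word
    entities win over their substrings.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        mapping = dict(mapping or {})
        for surface, generic in mapping.items():
            if generic not in GENERIC_TERMS:
                raise FigwordError(
                    f"NER map value {generic!r} for {surface!r} is not one of "
                    f"{GENERIC_TERMS}"
                )
        self.mapping = {k.lower(): v for k, v in mapping.items()}
        if self.mapping:
            pattern = "|".join(
                re.escape(s) for s in sorted(self.mapping, key=len, reverse=True)
            )
            self._regex = re.compile(rf"\b(?:{pattern})\b", re.IGNORECASE)
        else:
            self._regex = None

    def substitute(self, text: str) -> str:
        if self._regex is None:
            return text
        return self._regex.sub(lambda m: self.mapping[m.group(0).lower()], text)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NERSubstitutionMap":
        """Read a two-column TSV of (surface_form, generic_term)."""
        mapping = {}
        for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FigwordError(f"{path}:{lineno}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
        return cls(mapping)


EMPTY_NER = NERSubstitutionMap()


@dataclass(frozen=True)
class TokenizedDoc:
    """Preprocessed token stream plus its distinct-token set."""

    tokens: tuple[str, ...]
    distinct_tokens: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "distinct_tokens", frozenset(self.tokens))


def preprocess(text: str, ner: NERSubstitutionMap = EMPTY_NER) -> TokenizedDoc:
    """Run the full preprocessing pipeline on raw text.

    Order: NER substitution → lowercase → tokenize on non-alphanumerics
    → Porter stemming → stop-word removal.  A token is dropped when
    either its surface form or its stem is on the stop list (stemming can
    carry a stop word off the list — "this" stems to "thi" — so the
    surface form is checked too).  Deterministic; empty text yields an
    empty token list.
    """
    lowered = ner.substitute(text).lower()
    out = []
    for raw in _TOKEN_RE.findall(lowered):
        if raw in _STOPWORDS:
            continue
        stemmed = _porter.stem(raw)
        if stemmed in _STOPWORDS:
            continue
        out.append(stemmed)
    return TokenizedDoc(tokens=tuple(out))


def concat_captions(doc: DocumentRecord) -> str:
    """Join a document's figure captions, in figure order, with single
    spaces; empty captions are skipped."""
    return " ".join(fig.caption for fig in doc.figures if fig.caption)


def mean_embedding(
    tdoc: TokenizedDoc, table: EmbeddingTable, distinct: bool = True
) -> np.ndarray:
    """Mean of embedding vectors over a document's tokens.

    With ``distinct=True`` (the default) each distinct in-vocabulary
    token contributes exactly once and the divisor n is the number of
    distinct in-vocabulary tokens.  With ``distinct=False`` the mean is
    taken over the raw token stream instead (the more common pooling
    variant, kept behind this flag).  Out-of-vocabulary tokens are
    skipped and excluded from n; a document with no in-vocabulary tokens
    maps to the zero vector so downstream standardization stays
    well-defined.
    """
    pool = sorted(tdoc.distinct_tokens) if distinct else list(tdoc.tokens)
    vecs = [table[t] for t in pool if t in table]
    if not vecs:
        return np.zeros(table.dim)
    return np.mean(vecs, axis=0)


def caption_vector(
    doc: DocumentRecord,
    table: EmbeddingTable,
    ner: NERSubstitutionMap = EMPTY_NER,
    distinct: bool = True,
) -> np.ndarray:
    """d_CAP: embedding mean of the document's concatenated captions."""
    return mean_embedding(preprocess(concat_captions(doc), ner), table, distinct)


def ta_vector(
    doc: DocumentRecord,
    table: EmbeddingTable,
    ner: NERSubstitutionMap = EMPTY_NER,
    distinct: bool = True,
) -> np.ndarray:
    """d_TA: embedding mean of the document's title-and-abstract."""
    return mean_embedding(preprocess(doc.title_abstract, ner), table, distinct)
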