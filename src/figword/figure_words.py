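"""Figure-word encoding: figures as binary panel-type indicator vectors
and documents as binary Figure-word occurrence vectors.

A *Figure-word* is a K-bit vector (K = taxonomy size, default 11) whose
i-th bit is set when a panel of the taxonomy's i-th class is present in
the figure — presence, not count, so duplicate panels of one class
collapse.  The vocabulary of possible Figure-words therefore has 2**K
members (2048 for the default taxonomy), and a document's image
representation d_IMG is the binary occurrence vector over that
vocabulary.

Bit-order convention: class position 1 maps to the least-significant bit
of the integer index, i.e. index = sum(c_i * 2**(i-1)).  Any fixed
bijection between bit vectors and [0, 2**K) would do; this one is
documented and stable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .errors import DegenerateFigureError
from .interchange import DEFAULT_TAXONOMY, DocumentRecord, Taxonomy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FigureWord:
    """Binary panel-type composition of one figure."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if not all(b in (0, 1) for b in self.bits):
            raise ValueError("Figure-word entries must be 0 or 1")

    def __len__(self) -> int:
        return len(self.bits)

    def as_array(self) -> np.ndarray:
        return np.array(self.bits, dtype=np.uint8)


def encode_figure(panel_labels: Sequence[str], taxonomy: Taxonomy = DEFAULT_TAXONOMY) -> FigureWord:
    """Encode a figure's panel labels as a Figure-word.

    Bit i (1-based taxonomy position) is set iff at least one panel of
    class i is present.  An empty label list is a degenerate figure and
    an error; unknown labels raise TaxonomyError.
    """
    if not panel_labels:
        raise DegenerateFigureError("cannot encode a figure with no panel labels")
    bits = [0] * len(taxonomy)
    for lab in panel_labels:
        bits[taxonomy.position(lab) - 1] = 1
    return FigureWord(bits=tuple(bits))


def figure_word_index(fw: FigureWord) -> int:
    """Integer index of a Figure-word: position 1 is the least-significant
    bit, so index = sum(c_i * 2**(i-1)).  Bijective with bit vectors."""
    return int(sum(b << i for i, b in enumerate(fw.bits)))


def index_to_figure_word(index: int, taxonomy: Taxonomy = DEFAULT_TAXONOMY) -> FigureWord:
    """Inverse of :func:`figure_word_index` for the given taxonomy size."""
    k = len(taxonomy)
    if not 0 <= index < 2**k:
        raise ValueError(f"index {index} out of range [0, {2**k})")
    return FigureWord(bits=tuple((index >> i) & 1 for i in range(k)))


@dataclass(frozen=True)
class ImageDocVector:
    """Document image representation d_IMG: binary occurrence indicator
    over the 2**K Figure-word vocabulary, stored sparsely as the set of
    observed Figure-word indices."""

    indices: frozenset[int]
    size: int

    def to_dense(self) -> np.ndarray:
        vec = np.zeros(self.size, dtype=np.uint8)
        if self.indices:
            vec[sorted(self.indices)] = 1
        return vec


def document_image_vector(
    doc: DocumentRecord, taxonomy: Taxonomy = DEFAULT_TAXONOMY
) -> ImageDocVector:
    """Build d_IMG for one document.

    Figures whose panels were never classified (empty label list) are
    skipped with a logged warning; a document with no encodable figures
    yields the all-zero vector rather than being dropped, so documents
    missing the image modality stay classifiable from text.
    """
    indices: set[int] = set()
    for pos, fig in enumerate(doc.figures):
        if not fig.panel_labels:
            logger.warning(
                "document %r: figure %d has no panel labels; skipped from d_IMG",
                doc.doc_id,
                pos,
            )
            continue
        indices.add(figure_word_index(encode_figure(fig.panel_labels, taxonomy)))
    return ImageDocVector(indices=frozenset(indices), size=taxonomy.vocabulary_size)


def image_matrix(
    docs: Iterable[DocumentRecord], taxonomy: Taxonomy = DEFAULT_TAXONOMY
) -> sparse.csr_matrix:
    """Stack d_IMG vectors for a corpus into a sparse (n_docs x 2**K)
    binary matrix, in document order."""
    rows, cols = [], []
    n = 0
    for i, doc in enumerate(docs):
        n = i + 1
        for idx in sorted(document_image_vector(doc, taxonomy).indices):
            rows.append(i)
            cols.append(idx)
    return sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.float64), (rows, cols)),
        shape=(n, taxonomy.vocabulary_size),
    )
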