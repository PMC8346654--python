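"""Distinguishing Figure-words via the two-proportion z-score test.

Each figure in a labeled corpus contributes one occurrence of its
Figure-word to the counts of its document's class (figure-level
counting: a Figure-word occurring in three figures of one document
counts three).  For every Figure-word the occurrence *proportion* among
relevant-class figures is compared against the proportion among
irrelevant-class figures with the standard pooled two-proportion
z statistic,

    z = (p1 - p2) / sqrt(p (1 - p) (1/n1 + 1/n2)),   p = (k1 + k2) / (n1 + n2),

and Figure-words are ranked by |z|; the sign records the direction of
enrichment (positive = enriched among relevant documents' figures).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EvaluationError, FigwordError
from .figure_words import encode_figure, figure_word_index, index_to_figure_word
from .interchange import DEFAULT_TAXONOMY, RELEVANT, DocumentRecord, Taxonomy


@dataclass
class FigureWordCounts:
    """Occurrence counts per Figure-word index, split by document class.

    ``n_rel`` / ``n_irr`` are the total numbers of counted figures in
    relevant / irrelevant documents, so counts conserve totals:
    sum(k_rel) == n_rel and sum(k_irr) == n_irr.
    """

    k_rel: np.ndarray
    k_irr: np.ndarray
    n_rel: int
    n_irr: int


def count_figure_words(
    docs: Sequence[DocumentRecord], taxonomy: Taxonomy = DEFAULT_TAXONOMY
) -> FigureWordCounts:
    """Count Figure-word occurrences per class over a labeled corpus.

    Unlabeled documents are rejected; figures with no panel labels are
    not counted (they have no Figure-word).
    """
    size = taxonomy.vocabulary_size
    k_rel = np.zeros(size, dtype=int)
    k_irr = np.zeros(size, dtype=int)
    for doc in docs:
        if doc.label is None:
            raise FigwordError(
                f"document {doc.doc_id!r} is unlabeled; counting requires labels"
            )
        bucket = k_rel if doc.label == RELEVANT else k_irr
        for fig in doc.figures:
            if fig.panel_labels:
                bucket[figure_word_index(encode_figure(fig.panel_labels, taxonomy))] += 1
    return FigureWordCounts(
        k_rel=k_rel, k_irr=k_irr, n_rel=int(k_rel.sum()), n_irr=int(k_irr.sum())
    )


def zscore(k1: int, n1: int, k2: int, n2: int) -> float:
    """Pooled two-proportion z statistic for k1/n1 versus k2/n2.

    Positive when the first proportion is larger.  When the pooled
    proportion is 0 or 1 the statistic is undefined; 0 is returned with
    a warning (such words occur in every figure or none and cannot
    distinguish the classes).
    """
    if n1 <= 0 or n2 <= 0:
        raise EvaluationError("both sample sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("pooled proportion is degenerate (0 or 1); z undefined, returning 0")
        return 0.0
    return (p1 - p2) / math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))


def rank_distinguishing(
    counts: FigureWordCounts,
    top: int = 5,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
) -> pd.DataFrame:
    """Top distinguishing Figure-words ranked by |z|, descending.

    Only observed Figure-words (nonzero total count) are ranked.  Ties
    on |z| break by total count (descending) then index (ascending).
    Columns: index, bits (as a "<c1,...,cK>" string), classes (the
    panel-type names present), k_rel, k_irr, z.
    """
    if top <= 0:
        raise ValueError("top must be a positive integer")
    observed = np.nonzero(counts.k_rel + counts.k_irr)[0]
    rows = []
    for idx in observed:
        z = zscore(
            int(counts.k_rel[idx]), counts.n_rel, int(counts.k_irr[idx]), counts.n_irr
        )
        fw = index_to_figure_word(int(idx), taxonomy)
        rows.append(
            {
                "index": int(idx),
                "bits": "<" + ",".join(str(b) for b in fw.bits) + ">",
                "classes": "+".join(
                    taxonomy.class_at(i + 1) for i, b in enumerate(fw.bits) if b
                ),
                "k_rel": int(counts.k_rel[idx]),
                "k_irr": int(counts.k_irr[idx]),
                "z": z,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["index", "bits", "classes", "k_rel", "k_irr", "z"]
    )
    if frame.empty:
        return frame
    frame["_absz"] = frame["z"].abs()
    frame["_total"] = frame["k_rel"] + frame["k_irr"]
    frame = frame.sort_values(
        ["_absz", "_total", "index"], ascending=[False, False, True]
    ).drop(columns=["_absz", "_total"])
    return frame.head(top).reset_index(drop=True)
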