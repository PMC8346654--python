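"""Corpus and embedding interchange formats.

A corpus is a single JSON file holding pre-decomposed documents: each
document carries its title-and-abstract text and a list of figures, and
each figure carries its caption text plus the list of panel-type labels
assigned to its constituent panels.  Panel labels replace raw images as
the interchange unit: figure extraction from PDFs and panel
classification happen upstream and are out of scope here.

Schema::

    {
      "taxonomy": ["Histogram", ...],
      "documents": [
        {
          "doc_id": "...",
          "label": "relevant" | "irrelevant",   # optional (unlabeled)
          "title_abstract": "...",
          "figures": [
            {"caption": "...", "panel_labels": ["Histogram", ...]},
            ...
          ]
        },
        ...
      ]
    }

Word embeddings are read from the word2vec plain-text format: a header
line ``"<count> <dim>"`` followed by one ``token v1 ... v_dim`` row per
vocabulary word.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import CorpusSchemaError, EmbeddingFormatError, TaxonomyError

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"
_VALID_LABELS = (RELEVANT, IRRELEVANT)

#: Panel-type classes of the default image taxonomy, in their fixed
#: ordinal (bit-position) order.  Eleven classes: three kinds of graphic,
#: two kinds of molecular-structure rendering, five kinds of experimental
#: image, a catch-all, and the "separation residual" class for
#: non-informative fragments produced when compound-figure segmentation
#: over-splits a figure.
DEFAULT_CLASSES = (
    "Histogram",
    "Line chart",
    "Other diagram",
    "Macromolecule sequence",
    "3D structure",
    "Fluorescence microscopy",
    "Gel/blot",
    "Plate",
    "Light microscopy",
    "Other",
    "Separation residual",
)


@dataclass(frozen=True)
class Taxonomy:
    """Closed, ordered set of panel-type classes.

    The 1-based ordinal of each class is the bit position used when
    encoding figures as Figure-words, so the order is part of the
    contract and must be stable across runs.
    """

    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        if not self.classes:
            raise TaxonomyError("taxonomy must contain at least one class")
        if any(not c for c in self.classes):
            raise TaxonomyError("taxonomy class names must be non-empty")
        if len(set(self.classes)) != len(self.classes):
            raise TaxonomyError("taxonomy class names must be unique")
        object.__setattr__(
            self, "_positions", {c: i + 1 for i, c in enumerate(self.classes)}
        )

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, name: str) -> bool:
        return name in self._positions

    def position(self, name: str) -> int:
        """1-based ordinal of ``name``; raises TaxonomyError if unknown."""
        try:
            return self._positions[name]
        except KeyError:
            raise TaxonomyError(f"unknown panel class {name!r}") from None

    def class_at(self, position: int) -> str:
        """Inverse of :meth:`position` (1-based)."""
        if not 1 <= position <= len(self.classes):
            raise TaxonomyError(f"position {position} out of range 1..{len(self)}")
        return self.classes[position - 1]

    @property
    def vocabulary_size(self) -> int:
        """Number of possible Figure-words, ``2 ** len(self)``."""
        return 2 ** len(self.classes)


DEFAULT_TAXONOMY = Taxonomy()


@dataclass
class FigureRecord:
    """One (possibly compound) figure: its caption text and the panel-type
    labels of its constituent panels.

    The caption may be empty — page layouts sometimes yield figures with
    no associated caption.  ``panel_labels`` may be empty only when the
    figure was never segmented and classified upstream.
    """

    caption: str = ""
    panel_labels: list[str] = field(default_factory=list)


@dataclass
class DocumentRecord:
    """One publication in the corpus."""

    doc_id: str
    title_abstract: str = ""
    figures: list[FigureRecord] = field(default_factory=list)
    label: str | None = None  # "relevant" / "irrelevant" / None (unlabeled)


class EmbeddingTable:
    """Token -> fixed-dimension real vector map.

    All vectors share the same dimensionality ``dim`` (the default
    biomedical word2vec tables used downstream are 200-dimensional).
    """

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise EmbeddingFormatError("embedding table must not be empty")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise EmbeddingFormatError(
                f"inconsistent vector lengths in embedding table: {sorted(dims)}"
            )
        self.dim = dims.pop()
        self.vectors = {t: np.asarray(v, dtype=float) for t, v in vectors.items()}

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def get(self, token: str) -> np.ndarray | None:
        return self.vectors.get(token)


# ---------------------------------------------------------------------------
# corpus I/O


def _figure_from_json(obj, doc_id: str, taxonomy: Taxonomy) -> FigureRecord:
    if not isinstance(obj, dict):
        raise CorpusSchemaError(f"document {doc_id!r}: figure entry is not an object")
    labels = obj.get("panel_labels", [])
    for lab in labels:
        if lab not in taxonomy:
            raise CorpusSchemaError(
                f"document {doc_id!r}: unknown panel class {lab!r} "
                f"(not in taxonomy {list(taxonomy.classes)})"
            )
    return FigureRecord(caption=obj.get("caption", ""), panel_labels=list(labels))


def read_corpus(path: str | Path, taxonomy: Taxonomy = DEFAULT_TAXONOMY) -> list[DocumentRecord]:
    """Read a corpus JSON file, validating panel labels against ``taxonomy``.

    Raises CorpusSchemaError naming the offending document and label when
    a panel class outside the taxonomy is encountered.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CorpusSchemaError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(payload, dict) or "documents" not in payload:
        raise CorpusSchemaError(f"{path}: corpus object must contain 'documents'")

    docs: list[DocumentRecord] = []
    seen: set[str] = set()
    for entry in payload["documents"]:
        if not isinstance(entry, dict) or "doc_id" not in entry:
            raise CorpusSchemaError(f"{path}: document entry missing 'doc_id'")
        doc_id = str(entry["doc_id"])
        if doc_id in seen:
            raise CorpusSchemaError(f"{path}: duplicate doc_id {doc_id!r}")
        seen.add(doc_id)
        label = entry.get("label")
        if label is not None and label not in _VALID_LABELS:
            raise CorpusSchemaError(
                f"document {doc_id!r}: label must be one of {_VALID_LABELS}, got {label!r}"
            )
        figures = [
            _figure_from_json(f, doc_id, taxonomy) for f in entry.get("figures", [])
        ]
        docs.append(
            DocumentRecord(
                doc_id=doc_id,
                title_abstract=entry.get("title_abstract", ""),
                figures=figures,
                label=label,
            )
        )
    return docs


def write_corpus(
    docs: Iterable[DocumentRecord],
    path: str | Path,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
) -> None:
    """Write documents as a corpus JSON file readable by :func:`read_corpus`.

    Output is deterministic (fixed key order, 2-space indent, UTF-8) so
    identical document lists produce byte-identical files.
    """
    entries = []
    for doc in docs:
        for fig in doc.figures:
            for lab in fig.panel_labels:
                if lab not in taxonomy:
                    raise TaxonomyError(
                        f"document {doc.doc_id!r}: unknown panel class {lab!r}"
                    )
        entry: dict = {"doc_id": doc.doc_id}
        if doc.label is not None:
            entry["label"] = doc.label
        entry["title_abstract"] = doc.title_abstract
        entry["figures"] = [
            {"caption": f.caption, "panel_labels": list(f.panel_labels)}
            for f in doc.figures
        ]
        entries.append(entry)
    payload = {"taxonomy": list(taxonomy.classes), "documents": entries}
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# embedding I/O (word2vec plain-text format)


def read_embeddings(path: str | Path) -> EmbeddingTable:
    """Read a word2vec text-format embedding file.

    Format: header line ``"<count> <dim>"``; then ``count`` lines of
    ``token v1 ... v_dim``.  Ragged rows, duplicate tokens, and count
    mismatches are format errors.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingFormatError(f"{path}: malformed header line")
        try:
            count, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise EmbeddingFormatError(f"{path}: malformed header line") from exc
        if count <= 0 or dim <= 0:
            raise EmbeddingFormatError(f"{path}: header counts must be positive")
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            token, values = parts[0], parts[1:]
            if len(values) != dim:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: expected {dim} values for token "
                    f"{token!r}, got {len(values)}"
                )
            if token in vectors:
                raise EmbeddingFormatError(f"{path}:{lineno}: duplicate token {token!r}")
            try:
                vectors[token] = np.array(values, dtype=float)
            except ValueError as exc:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: non-numeric value for token {token!r}"
                ) from exc
    if len(vectors) != count:
        raise EmbeddingFormatError(
            f"{path}: header promises {count} tokens, found {len(vectors)}"
        )
    return EmbeddingTable(vectors)


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Write an embedding table in word2vec text format (round-trips with
    :func:`read_embeddings` up to float formatting)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dim}\n")
        for token, vec in table.vectors.items():
            fh.write(token + " " + " ".join(repr(float(x)) for x in vec) + "\n")
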