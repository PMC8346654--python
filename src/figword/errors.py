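"""Exception hierarchy shared across the package."""


class FigwordError(Exception):
    """Base class for all errors raised by this package."""


class CorpusSchemaError(FigwordError):
    """A corpus file violates the documented JSON schema."""


class TaxonomyError(FigwordError):
    """A panel label is not a member of the active taxonomy, or the
    taxonomy itself is malformed."""


class DegenerateFigureError(FigwordError):
    """A figure with no panel labels was passed where an encodable
    figure is required."""


class EmbeddingFormatError(FigwordError):
    """A word-embedding file violates the word2vec text format."""


class TrainingError(FigwordError):
    """A classifier or standardizer cannot be fit on the given data
    (e.g. a single-class label vector, or too few rows)."""


class EvaluationError(FigwordError):
    """Cross-validation planning or system comparison is impossible on
    the given inputs (corpus too small to stratify, misaligned
    predictions, unequal evaluation counts)."""
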