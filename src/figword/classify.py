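"""Base classifiers and the two information-integration schemes.

Three per-modality document representations feed the classifiers:

* d_IMG — binary Figure-word occurrence vector (width 2**K, default 2048)
* d_CAP — embedding mean of the concatenated captions (width dim, default 200)
* d_TA  — embedding mean of the title-and-abstract (width dim, default 200)

``CombV`` concatenates the three blocks into d_ALL, standardizes every
feature to mean 0 / sd 1 (binary indicator entries and unbounded
embedding means live on very different scales), and trains one
maximum-margin classifier on the result.

``CombC`` is a stacking scheme: base classifiers C_IMG, C_CAP, C_TA are
trained separately per block; each document is then summarized by the
6-tuple <L_IMG, P_IMG, L_CAP, P_CAP, L_TA, P_TA> of base labels and
relevant-class probabilities, on which a meta-classifier is trained.
Meta-features for the *training* documents come from internal
out-of-fold prediction — a base classifier's in-sample outputs are
optimistically biased, and training the meta-classifier on them is a
known leakage bug.

All classifiers are SVMs with calibrated probability outputs; labels
follow the probability via the fixed threshold L = [P >= 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC

from .errors import TrainingError
from .figure_words import image_matrix
from .interchange import (
    DEFAULT_TAXONOMY,
    RELEVANT,
    DocumentRecord,
    EmbeddingTable,
    Taxonomy,
)
from .text_repr import EMPTY_NER, NERSubstitutionMap, caption_vector, ta_vector

#: Order of the modality blocks in d_ALL and of the meta-feature pairs.
BLOCKS = ("IMG", "CAP", "TA")

#: Callback signature for fit instrumentation: (component name, doc_ids
#: the fit saw).  Used by the evaluation layer to prove that no model
#: component is ever fit on test-fold documents.
FitListener = Callable[[str, Sequence[str]], None]


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters for every SVM in the system.

    kernel/C/calibration defaults (linear, C=1, Platt-style sigmoid
    calibration) are deliberately plain; stacking_folds controls the
    internal out-of-fold split used to build training meta-features.
    """

    kernel: str = "linear"
    C: float = 1.0
    calibration: str = "sigmoid"
    stacking_folds: int = 5
    seed: int = 0
    distinct_mean: bool = True  # distinct-word vs token-frequency embedding mean

    def with_seed(self, seed: int) -> "ClassifierConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class BaseClassifierOutput:
    """One base-classifier verdict: hard label (1 = relevant) and
    calibrated relevant-class probability."""

    label: int
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if self.label != int(self.probability >= 0.5):
            raise ValueError("label must equal [probability >= 0.5]")


# ---------------------------------------------------------------------------
# feature standardization


class StandardizationModel:
    """Per-column mean/sd learned from a training matrix; constant
    columns get sd clamped to 1 so they transform to exact zeros."""

    def __init__(self, mean: np.ndarray, scale: np.ndarray):
        self.mean = mean
        self.scale = scale


def fit_standardizer(train: np.ndarray) -> StandardizationModel:
    """Learn per-column mean and standard deviation (population sd) from
    training rows only; requires at least 2 rows."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise TrainingError("standardizer needs a 2-D matrix with >= 2 rows")
    mean = train.mean(axis=0)
    scale = train.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return StandardizationModel(mean, scale)


def apply_standardizer(model: StandardizationModel, matrix: np.ndarray) -> np.ndarray:
    """Apply stored training means/sds; never refits, so applying to a
    test matrix leaks nothing."""
    return (np.asarray(matrix, dtype=float) - model.mean) / model.scale


# ---------------------------------------------------------------------------
# representation assembly


@dataclass
class DocumentRepresentations:
    """Per-corpus feature blocks, row-aligned with ``doc_ids``.

    Building these involves no fitting (the taxonomy and embedding table
    are fixed external inputs), so representations may be computed once
    for a corpus and sliced freely into training/test folds.
    """

    doc_ids: list[str]
    X_img: np.ndarray
    X_cap: np.ndarray
    X_ta: np.ndarray
    y: np.ndarray | None = None  # 1 = relevant, 0 = irrelevant; None if unlabeled

    def block(self, name: str) -> np.ndarray:
        return {"IMG": self.X_img, "CAP": self.X_cap, "TA": self.X_ta}[name]

    @property
    def X_all(self) -> np.ndarray:
        """d_ALL: [IMG | CAP | TA] concatenation, width 2**K + 2*dim."""
        return np.hstack([self.X_img, self.X_cap, self.X_ta])

    def subset(self, idx: np.ndarray) -> "DocumentRepresentations":
        return DocumentRepresentations(
            doc_ids=[self.doc_ids[i] for i in idx],
            X_img=self.X_img[idx],
            X_cap=self.X_cap[idx],
            X_ta=self.X_ta[idx],
            y=None if self.y is None else self.y[idx],
        )


def build_representations(
    docs: Sequence[DocumentRecord],
    table: EmbeddingTable,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
    ner: NERSubstitutionMap = EMPTY_NER,
    distinct_mean: bool = True,
) -> DocumentRepresentations:
    """Compute d_IMG, d_CAP and d_TA for every document in order."""
    X_img = image_matrix(docs, taxonomy)
    if sparse.issparse(X_img):
        X_img = np.asarray(X_img.todense())
    X_cap = np.vstack([caption_vector(d, table, ner, distinct_mean) for d in docs])
    X_ta = np.vstack([ta_vector(d, table, ner, distinct_mean) for d in docs])
    labels = [d.label for d in docs]
    y = None
    if all(lab is not None for lab in labels):
        y = np.array([1 if lab == RELEVANT else 0 for lab in labels], dtype=int)
    return DocumentRepresentations(
        doc_ids=[d.doc_id for d in docs], X_img=X_img, X_cap=X_cap, X_ta=X_ta, y=y
    )


# ---------------------------------------------------------------------------
# base classifier


def _make_estimator(config: ClassifierConfig, y: np.ndarray):
    if config.kernel == "linear":
        base = LinearSVC(C=config.C, random_state=config.seed, max_iter=20000)
        # calibration folds capped by the rarest class so tiny corpora fit
        cv = int(min(5, np.bincount(np.asarray(y, dtype=int)).min()))
        return CalibratedClassifierCV(base, method=config.calibration, cv=max(2, cv))
    return SVC(
        kernel=config.kernel,
        C=config.C,
        probability=True,
        random_state=config.seed,
    )


class BaseClassifier:
    """One modality classifier: per-block standardizer + calibrated SVM."""

    def __init__(self, config: ClassifierConfig, name: str = "base"):
        self.config = config
        self.name = name
        self._scaler: StandardizationModel | None = None
        self._clf = None
        self._classes: np.ndarray | None = None

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        doc_ids: Sequence[str] | None = None,
        fit_listener: FitListener | None = None,
    ) -> "BaseClassifier":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise TrainingError(
                f"{self.name}: training labels contain a single class"
            )
        if fit_listener is not None and doc_ids is not None:
            fit_listener(self.name, list(doc_ids))
        self._scaler = fit_standardizer(X)
        Xs = apply_standardizer(self._scaler, X)
        self._clf = _make_estimator(self.config, y)
        self._clf.fit(Xs, y)
        self._classes = np.asarray(self._clf.classes_)
        return self

    def predict_proba_relevant(self, X: np.ndarray) -> np.ndarray:
        Xs = apply_standardizer(self._scaler, X)
        proba = self._clf.predict_proba(Xs)
        col = int(np.where(self._classes == 1)[0][0])
        return proba[:, col]

    def predict(self, X: np.ndarray) -> list[BaseClassifierOutput]:
        probs = self.predict_proba_relevant(X)
        return [
            BaseClassifierOutput(label=int(p >= 0.5), probability=float(p))
            for p in probs
        ]


def train_base(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    name: str = "base",
    doc_ids: Sequence[str] | None = None,
    fit_listener: FitListener | None = None,
) -> BaseClassifier:
    """Fit a calibrated maximum-margin classifier on one feature block."""
    return BaseClassifier(config, name).fit(X, y, doc_ids, fit_listener)


def predict_base(clf: BaseClassifier, X: np.ndarray) -> list[BaseClassifierOutput]:
    """Apply a base classifier; labels satisfy L = [P >= 0.5]."""
    return clf.predict(X)


# ---------------------------------------------------------------------------
# integration scheme 1: concatenated vectors (CombV)


class CombVModel:
    """Concatenate the three blocks into d_ALL, standardize (train-fit),
    and classify with a single SVM."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        self._clf = BaseClassifier(config, name="combv")

    def fit(
        self,
        reps: DocumentRepresentations,
        fit_listener: FitListener | None = None,
    ) -> "CombVModel":
        widths = {reps.X_img.shape[0], reps.X_cap.shape[0], reps.X_ta.shape[0]}
        if len(widths) != 1:
            raise TrainingError("representation blocks have mismatched row counts")
        if reps.y is None:
            raise TrainingError("CombV requires a fully labeled training corpus")
        self._clf.fit(reps.X_all, reps.y, reps.doc_ids, fit_listener)
        return self

    def predict(self, reps: DocumentRepresentations) -> list[BaseClassifierOutput]:
        return self._clf.predict(reps.X_all)


def train_combv(
    reps: DocumentRepresentations,
    config: ClassifierConfig = ClassifierConfig(),
    fit_listener: FitListener | None = None,
) -> CombVModel:
    return CombVModel(config).fit(reps, fit_listener)


def predict_combv(model: CombVModel, reps: DocumentRepresentations):
    return model.predict(reps)


# ---------------------------------------------------------------------------
# integration scheme 2: meta-classification (CombC)


def meta_features(outputs_by_block: dict[str, list[BaseClassifierOutput]]) -> np.ndarray:
    """Assemble the 6-column meta-feature matrix
    <L_IMG, P_IMG, L_CAP, P_CAP, L_TA, P_TA> in fixed block order."""
    cols = []
    for block in BLOCKS:
        outs = outputs_by_block[block]
        cols.append([o.label for o in outs])
        cols.append([o.probability for o in outs])
    return np.column_stack(cols).astype(float)


class CombCModel:
    """Stacked meta-classification over the three base classifiers."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        self._bases: dict[str, BaseClassifier] = {}
        self._meta = BaseClassifier(config, name="combc-meta")

    def fit(
        self,
        reps: DocumentRepresentations,
        fit_listener: FitListener | None = None,
    ) -> "CombCModel":
        if reps.y is None:
            raise TrainingError("CombC requires a fully labeled training corpus")
        y = reps.y
        n = len(y)
        # out-of-fold base predictions give unbiased training meta-features
        oof = {b: np.empty(n) for b in BLOCKS}
        skf = StratifiedKFold(
            n_splits=self.config.stacking_folds,
            shuffle=True,
            random_state=self.config.seed,
        )
        for inner_train, inner_hold in skf.split(np.zeros(n), y):
            for block in BLOCKS:
                clf = BaseClassifier(self.config, name=f"combc-inner-{block}")
                clf.fit(
                    reps.block(block)[inner_train],
                    y[inner_train],
                    [reps.doc_ids[i] for i in inner_train],
                    fit_listener,
                )
                oof[block][inner_hold] = clf.predict_proba_relevant(
                    reps.block(block)[inner_hold]
                )
        meta_X = meta_features(
            {
                b: [
                    BaseClassifierOutput(label=int(p >= 0.5), probability=float(p))
                    for p in oof[b]
                ]
                for b in BLOCKS
            }
        )
        self._meta.fit(meta_X, y, reps.doc_ids, fit_listener)
        # refit bases on the full training data for use at predict time
        for block in BLOCKS:
            clf = BaseClassifier(self.config, name=f"combc-{block}")
            clf.fit(reps.block(block), y, reps.doc_ids, fit_listener)
            self._bases[block] = clf
        return self

    def base_outputs(
        self, reps: DocumentRepresentations
    ) -> dict[str, list[BaseClassifierOutput]]:
        return {b: self._bases[b].predict(reps.block(b)) for b in BLOCKS}

    def predict(self, reps: DocumentRepresentations) -> list[BaseClassifierOutput]:
        meta_X = meta_features(self.base_outputs(reps))
        return self._meta.predict(meta_X)


def train_combc(
    reps: DocumentRepresentations,
    config: ClassifierConfig = ClassifierConfig(),
    fit_listener: FitListener | None = None,
) -> CombCModel:
    return CombCModel(config).fit(reps, fit_listener)


def predict_combc(model: CombCModel, reps: DocumentRepresentations):
    return model.predict(reps)


# ---------------------------------------------------------------------------
# uniform scheme interface used by the evaluation layer


SCHEMES = ("img", "cap", "ta", "combv", "combc")


class SchemeModel:
    """A fitted classification scheme with a uniform predict surface."""

    def __init__(self, scheme: str, inner):
        self.scheme = scheme
        self._inner = inner

    def predict(self, reps: DocumentRepresentations) -> list[BaseClassifierOutput]:
        if self.scheme in ("combv", "combc"):
            return self._inner.predict(reps)
        block = self.scheme.upper()
        return self._inner.predict(reps.block(block))


def train_scheme(
    scheme: str,
    reps: DocumentRepresentations,
    config: ClassifierConfig = ClassifierConfig(),
    fit_listener: FitListener | None = None,
) -> SchemeModel:
    """Train one of the five schemes (img / cap / ta / combv / combc)."""
    if scheme not in SCHEMES:
        raise TrainingError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if reps.y is None:
        raise TrainingError("training requires a fully labeled corpus")
    if scheme == "combv":
        return SchemeModel(scheme, train_combv(reps, config, fit_listener))
    if scheme == "combc":
        return SchemeModel(scheme, train_combc(reps, config, fit_listener))
    block = scheme.upper()
    clf = train_base(
        reps.block(block),
        reps.y,
        config,
        name=f"c_{scheme}",
        doc_ids=reps.doc_ids,
        fit_listener=fit_listener,
    )
    return SchemeModel(scheme, clf)
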