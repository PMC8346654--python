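"""Cross-validation orchestration, metrics, significance testing and
complementarity (Venn-style) analysis.

The evaluation protocol is repeated stratified cross-validation: several
complete rounds of k-fold CV, each round using a distinct k-way
partition of the corpus.  All fitting — standardizers, base classifiers,
stacking — is confined to training folds; document representations
themselves involve no fitting and are computed once per corpus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .classify import (
    ClassifierConfig,
    DocumentRepresentations,
    FitListener,
    train_scheme,
)
from .errors import EvaluationError


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table for the relevant-vs-irrelevant decision."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0


def confusion(gold: Sequence[int], pred: Sequence[int]) -> ConfusionCounts:
    gold = np.asarray(gold, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if gold.shape != pred.shape:
        raise EvaluationError("gold and prediction vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum((gold == 1) & (pred == 1))),
        fp=int(np.sum((gold == 0) & (pred == 1))),
        fn=int(np.sum((gold == 1) & (pred == 0))),
        tn=int(np.sum((gold == 0) & (pred == 0))),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F-score of the relevant class.

    Zero-denominator cases (no predicted positives / no gold positives)
    are mapped to 0 with a warning rather than raising.
    """
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        warnings.warn("precision undefined (no predicted positives); returning 0")
        precision = 0.0
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        warnings.warn("recall undefined (no gold positives); returning 0")
        recall = 0.0
    f_score = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f_score


@dataclass(frozen=True)
class CVPlan:
    """Repeated stratified k-fold plan: ``rounds`` complete rounds of
    ``folds``-fold CV, each round partitioning the corpus differently
    (one derived seed per round)."""

    rounds: int = 5
    folds: int = 5
    seed: int = 0

    def round_seeds(self) -> list[int]:
        # distinct, reproducible, and kept well below 2**31
        return [(self.seed * 1000 + 7 * r + 1) % (2**31 - 1) for r in range(self.rounds)]


class ScoreTable:
    """Per-(system, round, fold) scores plus per-document predictions.

    ``frame`` holds one row per evaluation with precision / recall /
    f_score / accuracy; ``predictions`` maps round -> (doc_id -> label)
    for the out-of-fold predictions of that round's partition.
    """

    def __init__(self, system: str, frame: pd.DataFrame, predictions: dict[int, dict[str, int]]):
        self.system = system
        self.frame = frame
        self.predictions = predictions

    def scores(self, measure: str = "f_score") -> np.ndarray:
        return self.frame[measure].to_numpy()

    def round_means(self, measure: str = "f_score") -> np.ndarray:
        return self.frame.groupby("round")[measure].mean().to_numpy()

    def aggregate(self) -> pd.DataFrame:
        """Mean and sd per measure across all (round, fold) evaluations."""
        measures = ["precision", "recall", "f_score", "accuracy"]
        return pd.DataFrame(
            {
                "mean": self.frame[measures].mean(),
                "sd": self.frame[measures].std(ddof=1),
            }
        )

    def pooled_accuracy(self, gold: dict[str, int]) -> float:
        """Accuracy of the out-of-fold predictions pooled over rounds
        (every document is predicted once per round)."""
        hits = total = 0
        for preds in self.predictions.values():
            for doc_id, label in preds.items():
                hits += int(label == gold[doc_id])
                total += 1
        return hits / total

    def formatted(self) -> str:
        """Table 3-style one-line summary: mean with sd in parentheses."""
        agg = self.aggregate()
        cells = [
            f"{m}={agg.loc[m, 'mean']:.3f} ({agg.loc[m, 'sd']:.3f})"
            for m in ("precision", "recall", "f_score")
        ]
        return f"{self.system}: " + "  ".join(cells)


def run_cv(
    reps: DocumentRepresentations,
    scheme: str,
    plan: CVPlan = CVPlan(),
    config: ClassifierConfig = ClassifierConfig(),
    fit_listener: FitListener | None = None,
) -> ScoreTable:
    """Evaluate one scheme under repeated stratified k-fold CV.

    Yields rounds*folds evaluations.  Stratification keeps both classes
    in every training fold; a corpus too small for that is a planning
    error.  Identical plan/config seeds reproduce identical tables.
    """
    if reps.y is None:
        raise EvaluationError("cross-validation requires a fully labeled corpus")
    y = reps.y
    if np.bincount(y, minlength=2).min() < plan.folds:
        raise EvaluationError(
            f"corpus too small to stratify {plan.folds}-fold: class counts "
            f"{np.bincount(y, minlength=2).tolist()}"
        )
    rows = []
    predictions: dict[int, dict[str, int]] = {}
    for rnd, rseed in enumerate(plan.round_seeds()):
        skf = StratifiedKFold(n_splits=plan.folds, shuffle=True, random_state=rseed)
        round_preds: dict[str, int] = {}
        for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            if fit_listener is not None:
                # announce the held-out fold so instrumentation can prove
                # that every subsequent fit excluded it
                fit_listener("cv-test-fold", [reps.doc_ids[i] for i in test_idx])
            model = train_scheme(
                scheme,
                reps.subset(train_idx),
                config.with_seed(rseed),
                fit_listener,
            )
            outs = model.predict(reps.subset(test_idx))
            pred = np.array([o.label for o in outs], dtype=int)
            for i, o in zip(test_idx, outs):
                round_preds[reps.doc_ids[i]] = int(o.label)
            c = confusion(y[test_idx], pred)
            precision, recall, f_score = metrics(c)
            rows.append(
                {
                    "system": scheme,
                    "round": rnd,
                    "fold": fold,
                    "precision": precision,
                    "recall": recall,
                    "f_score": f_score,
                    "accuracy": c.accuracy,
                }
            )
        predictions[rnd] = round_preds
    return ScoreTable(scheme, pd.DataFrame(rows), predictions)


def compare_systems(
    a: ScoreTable,
    b: ScoreTable,
    measure: str = "f_score",
    level: str = "fold",
) -> tuple[float, float]:
    """Welch two-sample t-test between two systems' per-fold scores.

    ``level='round'`` pools each round's folds into a round mean first.
    Positive t means system ``a`` scored higher.  Degenerate cases
    (identical score lists; zero variance on both sides) are mapped to
    (0, 1) and (+/-inf, 0) respectively.
    """
    xa = a.scores(measure) if level == "fold" else a.round_means(measure)
    xb = b.scores(measure) if level == "fold" else b.round_means(measure)
    if len(xa) != len(xb):
        raise EvaluationError(
            f"unequal evaluation counts: {len(xa)} vs {len(xb)} "
            "(systems must share one CV plan)"
        )
    if np.array_equal(xa, xb):
        return 0.0, 1.0
    if np.var(xa) == 0.0 and np.var(xb) == 0.0:
        return (np.inf if xa.mean() > xb.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# complementarity analysis


@dataclass(frozen=True)
class ComplementarityReport:
    """Pairwise comparison of which gold-relevant documents each system
    correctly identified."""

    a_only: frozenset[str]
    b_only: frozenset[str]
    both: frozenset[str]
    neither: frozenset[str]


def _correct_relevant(preds: dict[str, int], gold: dict[str, int]) -> set[str]:
    return {d for d, g in gold.items() if g == 1 and preds[d] == 1}


def _check_alignment(gold: dict[str, int], *pred_maps: dict[str, int]) -> None:
    for preds in pred_maps:
        if set(preds) != set(gold):
            raise EvaluationError("prediction and gold document ids are misaligned")


def complementarity(
    preds_a: dict[str, int], preds_b: dict[str, int], gold: dict[str, int]
) -> ComplementarityReport:
    """Which gold-relevant documents does each system alone recover?

    All three maps must cover the same doc_ids.  Sets are over the
    gold-relevant documents only, mirroring how complementary value of
    two classifiers is usually illustrated.
    """
    _check_alignment(gold, preds_a, preds_b)
    relevant = {d for d, g in gold.items() if g == 1}
    ca = _correct_relevant(preds_a, gold)
    cb = _correct_relevant(preds_b, gold)
    return ComplementarityReport(
        a_only=frozenset(ca - cb),
        b_only=frozenset(cb - ca),
        both=frozenset(ca & cb),
        neither=frozenset(relevant - ca - cb),
    )


def complementarity3(
    preds: dict[str, dict[str, int]], gold: dict[str, int]
) -> dict[str, frozenset[str]]:
    """Three-system Venn regions over correctly-identified relevant docs.

    ``preds`` maps system name -> per-document labels.  Returns the 7
    Venn regions keyed like "a_only", "a_b", "a_b_c", plus "none".
    """
    names = sorted(preds)
    if len(names) != 3:
        raise EvaluationError("complementarity3 needs exactly 3 systems")
    _check_alignment(gold, *preds.values())
    correct = {n: _correct_relevant(preds[n], gold) for n in names}
    relevant = {d for d, g in gold.items() if g == 1}
    regions: dict[str, frozenset[str]] = {}
    for mask in range(1, 8):
        members = [names[i] for i in range(3) if mask & (1 << i)]
        inside = set(relevant)
        for n in names:
            if n in members:
                inside &= correct[n]
            else:
                inside -= correct[n]
        key = "_".join(members) if len(members) > 1 else f"{members[0]}_only"
        regions[key] = frozenset(inside)
    regions["none"] = frozenset(
        relevant - set().union(*(correct[n] for n in names))
    )
    return regions
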