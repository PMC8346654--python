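"""Canned end-to-end experiments on synthetic corpora.

These are the package's standard self-checks, runnable from tests or
scripts: a null-calibration experiment (no signal anywhere — every
scheme should perform at chance), a complementary-signal experiment
(each modality informative on a disjoint third of the documents — the
integration schemes should beat every single modality), and a
ranking-recovery experiment (a planted panel-composition signal should
surface as the top-|z| Figure-word).

Problem sizes (400/600 documents, 5x5 CV, 20 ranking replicates) are
chosen so each experiment finishes in minutes on one CPU while leaving
comfortable statistical margins.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .classify import ClassifierConfig, build_representations
from .evaluate import CVPlan, ScoreTable, compare_systems, run_cv
from .interchange import IRRELEVANT, RELEVANT
from .rank_figwords import count_figure_words, rank_distinguishing
from .synth import SynthConfig, generate_corpus, generate_embeddings

#: index of the "fluorescence microscopy only" Figure-word (bit 6 alone)
FLUORESCENCE_ONLY_INDEX = 1 << 5


def null_config(n_docs: int = 400, seed: int = 0) -> SynthConfig:
    """Zero-signal corpus: identical panel composition in both classes,
    no topic words in captions or titles-and-abstracts."""
    probs = {RELEVANT: [0.1] * 11, IRRELEVANT: [0.1] * 11}
    return SynthConfig(
        n_docs=n_docs,
        caption_signal=0.0,
        ta_signal=0.0,
        panel_inclusion_probs=probs,
        seed=seed,
    )


def complementary_config(n_docs: int = 600, seed: int = 0) -> SynthConfig:
    """Each document informative in exactly one modality, with strong
    within-modality signal (fluorescence-dominated figures for image
    documents; 80% topic tokens for text documents)."""
    probs = {RELEVANT: [0.1] * 11, IRRELEVANT: [0.1] * 11}
    probs[RELEVANT][5] = 0.7
    probs[IRRELEVANT][5] = 0.05
    return SynthConfig(
        n_docs=n_docs,
        caption_signal=0.8,
        ta_signal=0.8,
        panel_inclusion_probs=probs,
        complementary=True,
        seed=seed,
    )


def ranking_config(n_docs: int = 400, seed: int = 0) -> SynthConfig:
    """Panel-composition signal only: fluorescence panels included with
    probability 0.6 in relevant vs 0.05 in irrelevant documents (the
    magnitude of contrast seen in real curation corpora), all other
    panel types equal across classes."""
    probs = {RELEVANT: [0.1] * 11, IRRELEVANT: [0.1] * 11}
    probs[RELEVANT][5] = 0.6
    probs[IRRELEVANT][5] = 0.05
    return SynthConfig(
        n_docs=n_docs,
        caption_signal=0.0,
        ta_signal=0.0,
        panel_inclusion_probs=probs,
        seed=seed,
    )


def binomial_band(n: int, p: float = 0.5, alpha: float = 0.05) -> tuple[float, float]:
    """Central 1-alpha band of Binomial(n, p)/n.

    For calibration checks n is the corpus size, not corpus size times
    CV rounds: repeated rounds re-predict the same documents and are not
    independent draws, so the corpus-size band is the conservative one.
    """
    lo = stats.binom.ppf(alpha / 2, n, p) / n
    hi = stats.binom.ppf(1 - alpha / 2, n, p) / n
    return float(lo), float(hi)


def run_all_schemes(
    cfg: SynthConfig,
    plan: CVPlan,
    clf_config: ClassifierConfig | None = None,
    schemes=("img", "cap", "ta", "combv", "combc"),
) -> dict[str, ScoreTable]:
    """Generate a corpus+embeddings from cfg and cross-validate every
    scheme under one shared plan."""
    docs, _ = generate_corpus(cfg)
    table = generate_embeddings(cfg)
    reps = build_representations(docs, table)
    if clf_config is None:
        clf_config = ClassifierConfig(seed=cfg.seed)
    return {s: run_cv(reps, s, plan, clf_config) for s in schemes}


def null_calibration(n_docs: int = 400, seed: int = 0) -> dict:
    """5x5 CV of every scheme on a zero-signal corpus.

    Returns per-scheme pooled accuracies (mean over rounds of each
    round's out-of-fold accuracy over the whole corpus) plus the
    binomial 95% band they are expected to fall in.
    """
    cfg = null_config(n_docs, seed)
    docs, _ = generate_corpus(cfg)
    gold = {d.doc_id: 1 if d.label == RELEVANT else 0 for d in docs}
    tables = run_all_schemes(cfg, CVPlan(rounds=5, folds=5, seed=seed))
    lo, hi = binomial_band(n_docs)
    return {
        "accuracy": {s: t.pooled_accuracy(gold) for s, t in tables.items()},
        "band": (lo, hi),
        "tables": tables,
    }


def signal_recovery(n_docs: int = 600, seed: int = 0) -> dict:
    """5x5 CV of every scheme on a complementary-signal corpus.

    Reports mean F-scores per scheme and Welch t statistics comparing
    each integration scheme against each single-modality scheme over the
    25 fold scores (positive t = integration scored higher).
    """
    cfg = complementary_config(n_docs, seed)
    tables = run_all_schemes(cfg, CVPlan(rounds=5, folds=5, seed=seed))
    mean_f = {s: float(np.mean(t.scores("f_score"))) for s, t in tables.items()}
    welch = {}
    for combined in ("combv", "combc"):
        for single in ("img", "cap", "ta"):
            t, p = compare_systems(tables[combined], tables[single], "f_score")
            welch[f"{combined}_vs_{single}"] = {"t": t, "p": p}
    return {"mean_f": mean_f, "welch": welch, "tables": tables}


def ranking_recovery(
    n_docs: int = 400, n_runs: int = 20, seed: int = 0
) -> dict:
    """How often is the planted fluorescence-only Figure-word the
    top-|z| word across seeded replicates?"""
    hits = 0
    for r in range(n_runs):
        cfg = ranking_config(n_docs, seed=(seed * 1000 + r) % (2**31 - 1))
        docs, _ = generate_corpus(cfg)
        counts = count_figure_words(docs)
        ranked = rank_distinguishing(counts, top=1)
        hits += int(ranked.loc[0, "index"] == FLUORESCENCE_ONLY_INDEX)
    return {"hit_rate": hits / n_runs, "runs": n_runs}
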