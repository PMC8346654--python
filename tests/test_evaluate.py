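"""Metrics, cross-validation orchestration, significance testing and
complementarity analysis."""

import math

import numpy as np
import pytest

import figword as fw
from figword.errors import EvaluationError


class TestMetrics:
    def test_balanced_example(self):
        p, r, f = fw.metrics(fw.ConfusionCounts(tp=8, fp=2, fn=2, tn=8))
        assert (p, r, f) == pytest.approx((0.8, 0.8, 0.8))

    def test_zero_denominators_map_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            p, r, f = fw.metrics(fw.ConfusionCounts(tp=0, fp=0, fn=5, tn=0))
        assert (p, r, f) == (0.0, 0.0, 0.0)

    def test_f_is_harmonic_mean_on_random_counts(self):
        """Brute-force oracle: recompute P, R and the harmonic mean from
        raw prediction/gold vectors for random confusion tables."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            gold = rng.integers(0, 2, 40)
            pred = rng.integers(0, 2, 40)
            c = fw.confusion(gold, pred)
            p, r, f = fw.metrics(c)
            tp = int(np.sum((gold == 1) & (pred == 1)))
            exp_p = tp / max(1, pred.sum()) if pred.sum() else 0.0
            exp_r = tp / max(1, gold.sum()) if gold.sum() else 0.0
            assert abs(p - exp_p) < 1e-12 and abs(r - exp_r) < 1e-12
            if p + r > 0:
                assert abs(f - 2 * p * r / (p + r)) < 1e-12
            assert c.total == 40

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(EvaluationError):
            fw.confusion([1, 0], [1])


@pytest.fixture(scope="module")
def cv_corpus():
    """200-document synthetic corpus with image-only signal, with
    representations built once for all CV tests in this module."""
    probs = {fw.RELEVANT: [0.1] * 11, fw.IRRELEVANT: [0.1] * 11}
    probs[fw.RELEVANT][5] = 0.7
    probs[fw.IRRELEVANT][5] = 0.05
    cfg = fw.SynthConfig(
        n_docs=200,
        seed=21,
        caption_signal=0.0,
        ta_signal=0.0,
        panel_inclusion_probs=probs,
        embedding_dim=16,
        tokens_per_caption=(5, 15),
        tokens_per_ta=(10, 25),
        figures_per_doc=(3, 8),
    )
    docs, _ = fw.generate_corpus(cfg)
    reps = fw.build_representations(docs, fw.generate_embeddings(cfg))
    return reps


class TestRunCV:
    def test_five_by_five_yields_25_rows(self, cv_corpus):
        table = fw.run_cv(cv_corpus, "img", fw.CVPlan(rounds=5, folds=5, seed=1))
        assert len(table.frame) == 25
        assert set(table.frame["round"]) == set(range(5))
        assert set(table.frame["fold"]) == set(range(5))
        assert table.frame[["precision", "recall", "f_score", "accuracy"]].min().min() >= 0
        assert table.frame[["precision", "recall", "f_score", "accuracy"]].max().max() <= 1

    def test_each_document_tested_once_per_round(self, cv_corpus):
        table = fw.run_cv(cv_corpus, "img", fw.CVPlan(rounds=2, folds=5, seed=2))
        for rnd_preds in table.predictions.values():
            assert set(rnd_preds) == set(cv_corpus.doc_ids)

    def test_rounds_use_distinct_partitions(self, cv_corpus):
        plan = fw.CVPlan(rounds=2, folds=5, seed=3)
        assert len(set(plan.round_seeds())) == 2

    def test_identical_seeds_reproduce_identical_tables(self, cv_corpus):
        plan = fw.CVPlan(rounds=2, folds=3, seed=4)
        t1 = fw.run_cv(cv_corpus, "img", plan)
        t2 = fw.run_cv(cv_corpus, "img", plan)
        assert t1.frame.equals(t2.frame)
        assert t1.predictions == t2.predictions

    def test_no_component_ever_fits_on_test_fold_documents(self, cv_corpus):
        """Instrumented leakage guard over a full repeated-CV run of the
        stacking scheme: every fit call's document set must be disjoint
        from the fold it is evaluated on."""
        events: list[tuple[str, frozenset]] = []

        def listener(name, doc_ids):
            events.append((name, frozenset(doc_ids)))

        fw.run_cv(
            cv_corpus,
            "combc",
            fw.CVPlan(rounds=1, folds=3, seed=5),
            fit_listener=listener,
        )
        held_out: frozenset = frozenset()
        fit_names = set()
        for name, ids in events:
            if name == "cv-test-fold":
                held_out = ids
            else:
                fit_names.add(name)
                assert not (ids & held_out)
        # standardizers live inside every base/meta fit; stacking logged
        # its inner fits too
        assert any(n.startswith("combc-inner") for n in fit_names)
        assert "combc-meta" in fit_names

    def test_corpus_too_small_to_stratify_is_planning_error(self, tiny_table):
        docs = [
            fw.DocumentRecord(doc_id=f"d{i}", label=fw.RELEVANT, title_abstract="gene")
            for i in range(4)
        ] + [
            fw.DocumentRecord(doc_id="x", label=fw.IRRELEVANT, title_abstract="cell")
        ]
        reps = fw.build_representations(docs, tiny_table)
        with pytest.raises(EvaluationError):
            fw.run_cv(reps, "ta", fw.CVPlan(rounds=1, folds=3, seed=0))


def _table_from_scores(scores, system="x"):
    import pandas as pd

    frame = pd.DataFrame(
        {
            "system": system,
            "round": 0,
            "fold": range(len(scores)),
            "precision": scores,
            "recall": scores,
            "f_score": scores,
            "accuracy": scores,
        }
    )
    return fw.ScoreTable(system, frame, {})


class TestCompareSystems:
    def test_identical_scores_give_t0_p1(self):
        a = _table_from_scores([0.8] * 25)
        assert fw.compare_systems(a, _table_from_scores([0.8] * 25)) == (0.0, 1.0)

    def test_degenerate_separation_gives_extreme_significance(self):
        a = _table_from_scores([0.9] * 25)
        b = _table_from_scores([0.5] * 25)
        t, p = fw.compare_systems(a, b)
        assert t == math.inf and p == 0.0

    def test_matches_textbook_welch_formula(self):
        """Closed-form oracle: recompute Welch's t from the definition
        on simulated Gaussian score sets; agreement to 1e-10."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            xa = rng.normal(0.8, 0.05, 25)
            xb = rng.normal(0.75, 0.08, 25)
            t, p = fw.compare_systems(_table_from_scores(xa), _table_from_scores(xb))
            va, vb = xa.var(ddof=1) / 25, xb.var(ddof=1) / 25
            expected = (xa.mean() - xb.mean()) / math.sqrt(va + vb)
            assert abs(t - expected) < 1e-10
            assert 0.0 <= p <= 1.0

    def test_symmetric_up_to_sign(self):
        rng = np.random.default_rng(9)
        xa, xb = rng.normal(0.8, 0.1, 25), rng.normal(0.7, 0.1, 25)
        ta, _ = fw.compare_systems(_table_from_scores(xa), _table_from_scores(xb))
        tb, _ = fw.compare_systems(_table_from_scores(xb), _table_from_scores(xa))
        assert abs(ta + tb) < 1e-12

    def test_unequal_counts_rejected(self):
        with pytest.raises(EvaluationError):
            fw.compare_systems(
                _table_from_scores([0.5] * 25), _table_from_scores([0.5] * 24)
            )


class TestComplementarity:
    def test_identical_predictions_have_empty_exclusive_sets(self):
        gold = {"a": 1, "b": 1, "c": 0}
        preds = {"a": 1, "b": 0, "c": 0}
        rep = fw.complementarity(preds, dict(preds), gold)
        assert rep.a_only == rep.b_only == frozenset()
        assert rep.both == {"a"} and rep.neither == {"b"}

    def test_exclusive_sets(self):
        gold = {"1": 1, "2": 1, "3": 1}
        pa = {"1": 1, "2": 1, "3": 0}
        pb = {"1": 0, "2": 1, "3": 1}
        rep = fw.complementarity(pa, pb, gold)
        assert rep.a_only == {"1"} and rep.b_only == {"3"} and rep.both == {"2"}

    def test_misaligned_ids_rejected(self):
        with pytest.raises(EvaluationError):
            fw.complementarity({"a": 1}, {"b": 1}, {"a": 1})

    def test_three_way_regions_partition_recovered_relevant(self):
        """Enumeration oracle: over random predictions the 7 Venn regions
        are disjoint and their union is the set of relevant documents
        correctly identified by at least one system."""
        rng = np.random.default_rng(10)
        ids = [f"d{i}" for i in range(60)]
        for _ in range(20):
            gold = {d: int(rng.random() < 0.5) for d in ids}
            preds = {
                s: {d: int(rng.random() < 0.6) for d in ids} for s in ("img", "cap", "ta")
            }
            regions = fw.complementarity3(preds, gold)
            venn = [v for k, v in regions.items() if k != "none"]
            union = set().union(*venn)
            assert sum(len(v) for v in venn) == len(union)
            expected = {
                d
                for d in ids
                if gold[d] == 1 and any(preds[s][d] == 1 for s in preds)
            }
            assert union == expected
            assert regions["none"] == {
                d
                for d in ids
                if gold[d] == 1 and all(preds[s][d] == 0 for s in preds)
            }
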