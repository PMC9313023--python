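"""Metric computation, the bootstrap protocol and the meta-predictor."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import f1_score, matthews_corrcoef, roc_auc_score

from idrbias import (
    IDPClass,
    MetaRouting,
    PredictionTrack,
    assemble_meta,
    auc_score,
    bootstrap_compare,
    evaluate,
    evaluate_by_class,
)
from idrbias.evaluation import (
    SignificanceTest,
    _binary_metrics,
    anderson_darling_pvalue,
    normalize_min_max,
)

from .conftest import make_protein


def track_for(pid: str, scores, calls=None, name="t") -> PredictionTrack:
    t = PredictionTrack(name)
    t.add(pid, np.asarray(scores, dtype=float),
          None if calls is None else np.asarray(calls))
    return t


def pair_count_auc(scores, labels) -> float:
    """Exhaustive positive x negative pair counting, ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_separation(self):
        assert auc_score(np.array([0.9, 0.8, 0.7, 0.1]), np.array([1, 1, 0, 0])) == 1.0

    def test_mann_whitney_example(self):
        # positives {0.9, 0.3}, negatives {0.5, 0.1}: 3 of 4 pairs ordered
        scores = np.array([0.9, 0.3, 0.5, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auc_score(scores, labels) == pytest.approx(0.75)

    def test_matches_pair_counting_and_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(10, 60))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            ours = auc_score(scores, labels)
            assert ours == pytest.approx(pair_count_auc(scores, labels))
            assert ours == pytest.approx(roc_auc_score(labels, scores))

    def test_confusion_formulas(self):
        # TP=2, FP=1, FN=1, TN=6
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        calls = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0])
        mcc, f1 = _binary_metrics(calls, labels)
        assert mcc == pytest.approx(11 / 21)
        assert f1 == pytest.approx(2 / 3)
        assert mcc == pytest.approx(matthews_corrcoef(labels, calls))
        assert f1 == pytest.approx(f1_score(labels, calls))

    def test_auc_invariances(self):
        rng = np.random.default_rng(1)
        scores = rng.standard_normal(200)
        labels = rng.integers(0, 2, size=200)
        base = auc_score(scores, labels)
        assert auc_score(np.exp(scores), labels) == pytest.approx(base)
        assert auc_score(-scores, labels) == pytest.approx(1 - base)


class TestEvaluate:
    def test_pooled_result(self):
        p = make_protein("P", "1100")
        t = track_for("P", [0.9, 0.8, 0.7, 0.1], [1, 1, 1, 0])
        r = evaluate(t, [p])
        assert r.auc == 1.0 and r.n_residues == 4 and r.n_positive == 2
        assert r.f1 == pytest.approx(2 * 2 / (2 * 2 + 1 + 0))

    def test_unannotated_residues_excluded(self):
        p = make_protein("P", "11--00")
        t = track_for("P", [0.9, 0.8, 0.5, 0.5, 0.2, 0.1])
        r = evaluate(t, [p])
        assert r.n_residues == 4

    def test_single_class_subset_errors(self):
        p = make_protein("P", "1111")
        with pytest.raises(ValueError, match="single class"):
            evaluate(track_for("P", [0.5, 0.5, 0.5, 0.5]), [p], subset_name="only-pos")

    def test_by_class_identity_when_one_class(self):
        p1 = make_protein("P1", "11000")
        p2 = make_protein("P2", "10100")
        t = PredictionTrack("t")
        rng = np.random.default_rng(2)
        for pid in ("P1", "P2"):
            t.add(pid, rng.random(5), None)
        classes = {"P1": IDPClass.C2_LOW_SHORT, "P2": IDPClass.C2_LOW_SHORT}
        df = evaluate_by_class([t], [p1, p2], classes).set_index("subset")
        assert df.loc["low_short"].auc == df.loc["all"].auc

    def test_class_specialist_profile(self, specialists_dataset):
        proteins, truth, tracks = specialists_dataset
        df = evaluate_by_class(tracks, proteins, truth.classes)
        for cls in (IDPClass.C1_FULLY_DISORDERED, IDPClass.C6_HIGH_NONBINDING):
            rows = df[df.subset == cls.value].set_index("predictor").auc
            assert rows.idxmax() == f"specialist_{cls.value}"
            assert rows.max() > 0.9
            assert rows.drop(rows.idxmax()).max() < 0.75

    def test_residue_partition_across_classes(self, caid_like_dataset):
        proteins, truth, tracks = caid_like_dataset
        df = evaluate_by_class(tracks[:1], proteins, truth.classes)
        total = df[df.subset == "all"].n_residues.iloc[0]
        assert df[df.subset != "all"].n_residues.sum() == total


class TestBootstrap:
    def make_dataset(self, n=40, length=50, seed=0):
        rng = np.random.default_rng(seed)
        proteins = [
            make_protein(f"P{i}", "".join(rng.choice(["0", "1"], size=length)))
            for i in range(n)
        ]
        return proteins, rng

    def tracks_with_auc(self, proteins, aucs, rng):
        out = []
        for name, auc in aucs:
            delta = np.sqrt(2) * norm.ppf(auc)
            t = PredictionTrack(name)
            for p in proteins:
                z = rng.standard_normal(len(p))
                z[p.disorder_track == 1] += delta
                t.add(p.id, z, None)
            out.append(t)
        return out

    def test_identical_tracks_never_significant(self):
        proteins, rng = self.make_dataset()
        (a,) = self.tracks_with_auc(proteins, [("a", 0.8)], rng)
        b = PredictionTrack("b", dict(a.scores), dict(a.calls))
        cmp = bootstrap_compare(a, b, proteins, n_iter=30, seed=1)
        assert cmp.p_value == 1.0
        assert not cmp.significant()
        assert np.all(cmp.differences == 0)

    def test_reproducible_and_symmetric(self):
        proteins, rng = self.make_dataset(seed=3)
        a, b = self.tracks_with_auc(proteins, [("a", 0.85), ("b", 0.7)], rng)
        r1 = bootstrap_compare(a, b, proteins, n_iter=25, seed=9)
        r2 = bootstrap_compare(a, b, proteins, n_iter=25, seed=9)
        assert np.array_equal(r1.values_a, r2.values_a)
        assert r1.p_value == r2.p_value
        rev = bootstrap_compare(b, a, proteins, n_iter=25, seed=9)
        assert rev.p_value == pytest.approx(r1.p_value)

    def test_detects_large_gap(self):
        proteins, rng = self.make_dataset(n=100, seed=4)
        a, b = self.tracks_with_auc(proteins, [("a", 0.9), ("b", 0.6)], rng)
        cmp = bootstrap_compare(a, b, proteins, n_iter=50, seed=2)
        assert cmp.values_a.mean() > cmp.values_b.mean()
        assert cmp.significant()

    def test_test_choice_follows_normality(self):
        proteins, rng = self.make_dataset(seed=5)
        a, b = self.tracks_with_auc(proteins, [("a", 0.8), ("b", 0.75)], rng)
        cmp = bootstrap_compare(a, b, proteins, n_iter=60, seed=3)
        expected = SignificanceTest.T_TEST if cmp.normality_p >= 0.05 else SignificanceTest.WILCOXON
        assert cmp.test_used is expected

    def test_anderson_darling_detects_non_normal(self):
        rng = np.random.default_rng(6)
        assert anderson_darling_pvalue(rng.standard_normal(200)) > 0.05
        assert anderson_darling_pvalue(rng.exponential(size=200)) < 1e-6

    def test_parameter_validation(self):
        proteins, rng = self.make_dataset()
        a, b = self.tracks_with_auc(proteins, [("a", 0.8), ("b", 0.8)], rng)
        with pytest.raises(ValueError):
            bootstrap_compare(a, b, proteins, n_iter=1)
        with pytest.raises(ValueError):
            bootstrap_compare(a, b, proteins, fraction=1.5)


class TestMeta:
    def test_min_max_formula(self):
        p = make_protein("P", "110")
        t = track_for("P", [2.0, 4.0, 6.0])
        normed = normalize_min_max(t, [p])
        assert normed.scores["P"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_scores_error(self):
        p = make_protein("P", "110")
        with pytest.raises(ValueError, match="constant"):
            normalize_min_max(track_for("P", [0.5, 0.5, 0.5]), [p])

    def test_identity_routing_reproduces_metrics(self, specialists_dataset):
        proteins, truth, tracks = specialists_dataset
        target = tracks[0]
        routing = MetaRouting(
            {c: target.name for c in IDPClass if c is not IDPClass.UNASSIGNED},
            target.name,
        )
        meta = assemble_meta(tracks, routing, truth.classes, proteins)
        r_meta = evaluate(meta, proteins)
        r_orig = evaluate(target, proteins)
        assert r_meta.auc == pytest.approx(r_orig.auc, abs=1e-12)
        assert r_meta.aupr == pytest.approx(r_orig.aupr, abs=1e-12)
        assert r_meta.mcc == r_orig.mcc
        assert r_meta.f1 == r_orig.f1

    def test_unknown_predictor_rejected(self, specialists_dataset):
        proteins, truth, tracks = specialists_dataset
        routing = MetaRouting(
            {c: "nope" for c in IDPClass if c is not IDPClass.UNASSIGNED}, "nope"
        )
        with pytest.raises(ValueError, match="unknown predictors"):
            assemble_meta(tracks, routing, truth.classes, proteins)
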