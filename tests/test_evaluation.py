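import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import oracle_auroc
from seqppi.evaluation import ConfusionTally, metrics, pair_classes, roc_pr

tally_cells = st.integers(0, 200)


class TestMetrics:
    def test_perfect_classifier(self):
        rep = metrics(ConfusionTally(TP=50, FP=0, TN=50, FN=0))
        for name in ("ACC", "SN", "Spec", "PPV", "NPV", "F_score", "MCC"):
            assert getattr(rep, name) == pytest.approx(1.0)
        assert not rep.undefined

    def test_hand_worked_tally(self):
        # TP=3 FN=2 FP=1 TN=4 evaluated by independent arithmetic
        rep = metrics(ConfusionTally(TP=3, FP=1, TN=4, FN=2))
        assert rep.ACC == pytest.approx(0.7)
        assert rep.SN == pytest.approx(0.6)
        assert rep.Spec == pytest.approx(0.8)
        assert rep.PPV == pytest.approx(0.75)
        assert rep.NPV == pytest.approx(4 / 6)
        assert rep.F_score == pytest.approx(2 * 0.6 * 0.75 / (0.6 + 0.75))
        assert rep.MCC == pytest.approx(10 / math.sqrt(600))

    def test_no_positive_predictions_flags_ppv(self):
        rep = metrics(ConfusionTally(TP=0, FP=0, TN=5, FN=5))
        assert math.isnan(rep.PPV)
        assert "PPV" in rep.undefined
        assert "F_score" in rep.undefined
        assert rep.ACC == pytest.approx(0.5)  # still defined

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTally(0, 0, 0, 0)
        with pytest.raises(ValueError):
            ConfusionTally(-1, 1, 1, 1)

    @given(tally_cells, tally_cells, tally_cells, tally_cells, st.integers(2, 9))
    def test_scale_invariance(self, tp, fp, tn, fn, s):
        if tp + fp + tn + fn == 0:
            tp = 1
        a = metrics(ConfusionTally(tp, fp, tn, fn))
        b = metrics(ConfusionTally(s * tp, s * fp, s * tn, s * fn))
        for name in ("ACC", "SN", "Spec", "PPV", "NPV", "F_score", "MCC"):
            x, y = getattr(a, name), getattr(b, name)
            assert (math.isnan(x) and math.isnan(y)) or x == pytest.approx(y)

    @given(tally_cells, tally_cells, tally_cells, tally_cells)
    def test_mcc_class_swap_symmetry(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            tp = 1
        m1 = metrics(ConfusionTally(tp, fp, tn, fn)).MCC
        m2 = metrics(ConfusionTally(tn, fn, tp, fp)).MCC
        assert (math.isnan(m1) and math.isnan(m2)) or m1 == pytest.approx(m2)

    @given(st.integers(1, 200), tally_cells, tally_cells, st.integers(1, 200))
    def test_f_is_harmonic_mean_of_sn_and_ppv(self, tp, fp, tn, fn):
        # tp >= 1 and fn >= 1 keep SN and PPV defined and positive
        rep = metrics(ConfusionTally(tp, fp, tn, fn))
        assert rep.F_score == pytest.approx(2 / (1 / rep.SN + 1 / rep.PPV))

    def test_from_labels(self):
        y = [1, 1, 1, 1, 1, -1, -1, -1, -1, -1]
        p = [1, 1, 1, -1, -1, 1, -1, -1, -1, -1]
        t = ConfusionTally.from_labels(y, p)
        assert (t.TP, t.FN, t.FP, t.TN) == (3, 2, 1, 4)


class TestRocPr:
    def test_perfect_separation(self):
        auroc, auprc = roc_pr([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1])
        assert auroc == 1.0
        assert auprc == 1.0

    def test_null_scores_near_half(self, rng):
        labels = np.where(rng.random(1000) < 0.5, 1, -1)
        if len(set(labels.tolist())) < 2:  # pragma: no cover
            labels[0] = -labels[0]
        scores = rng.random(1000)
        auroc, _ = roc_pr(scores, labels)
        assert auroc == pytest.approx(0.5, abs=0.05)

    def test_tied_scores_match_pairwise_oracle(self):
        scores = [0.9, 0.7, 0.7, 0.5, 0.3, 0.1]
        labels = [1, 1, -1, 1, -1, -1]
        auroc, _ = roc_pr(scores, labels)
        assert auroc == pytest.approx(oracle_auroc(scores, labels), abs=1e-12)

    def test_reversed_scores_complement(self, rng):
        scores = rng.random(50)  # continuous, ties a.s. absent
        labels = np.where(rng.random(50) < 0.5, 1, -1)
        labels[:2] = [1, -1]
        a1, _ = roc_pr(scores, labels)
        a2, _ = roc_pr(-scores, labels)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_pr([0.1, 0.9], [1, 1])


class TestPairClasses:
    def test_definitions(self):
        train = [("p1", "p2"), ("p3", "p4")]
        assert pair_classes(train, [("p1", "p2")]) == ["C1"]
        assert pair_classes(train, [("p1", "p4")]) == ["C1"]
        assert pair_classes(train, [("p1", "p9")]) == ["C2"]
        assert pair_classes(train, [("p8", "p9")]) == ["C3"]

    def test_partition_property(self, rng):
        ids = [f"q{i}" for i in range(30)]
        train = [(ids[i], ids[i + 1]) for i in range(0, 20, 2)]
        test = [tuple(rng.choice(ids, 2, replace=False)) for _ in range(50)]
        classes = pair_classes(train, test)
        assert len(classes) == 50
        assert set(classes) <= {"C1", "C2", "C3"}

    def test_disjoint_protein_sets_are_all_c3(self):
        assert pair_classes([("a", "b")], [("x", "y"), ("u", "v")]) == ["C3", "C3"]
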