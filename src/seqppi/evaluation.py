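"""Binary-classification evaluation: confusion-tally metrics, ranking
curves, and pair-input test classes.

Metrics are the standard seven — ACC, SN (sensitivity/recall), Spec
(specificity), PPV (precision), NPV, F-score and Matthews correlation
coefficient — computed literally from the TP/FP/TN/FN tally.  A ratio
with a zero denominator is *flagged undefined* (NaN plus a flag), never
silently reported as 0, because an imputed 0 corrupts averages across
folds.

Pair-input evaluation classes partition test pairs by how many of their
two proteins also occur somewhere in the training pairs: C1 = both,
C2 = exactly one, C3 = neither.  Ranking performance (AUROC, AUPRC)
typically degrades from C1 to C3 because shared proteins let a model
exploit protein-level representation bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["ConfusionTally", "MetricsReport", "metrics", "roc_pr", "pair_classes"]

METRIC_NAMES = ("ACC", "SN", "Spec", "PPV", "NPV", "F_score", "MCC")


@dataclass(frozen=True)
class ConfusionTally:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.TP + self.FP + self.TN + self.FN == 0:
            raise ValueError("empty confusion tally")

    @classmethod
    def from_labels(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionTally":
        t = np.asarray(y_true)
        p = np.asarray(y_pred)
        if t.shape != p.shape:
            raise ValueError("label arrays differ in length")
        return cls(
            TP=int(((t == 1) & (p == 1)).sum()),
            FP=int(((t == -1) & (p == 1)).sum()),
            TN=int(((t == -1) & (p == -1)).sum()),
            FN=int(((t == 1) & (p == -1)).sum()),
        )


@dataclass
class MetricsReport:
    """The seven tally metrics plus optional ranking areas.

    ``undefined`` lists the metrics whose defining ratio had a zero
    denominator; their values are NaN.
    """

    ACC: float
    SN: float
    Spec: float
    PPV: float
    NPV: float
    F_score: float
    MCC: float
    AUROC: float | None = None
    AUPRC: float | None = None
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        if self.AUROC is not None:
            d["AUROC"] = self.AUROC
        if self.AUPRC is not None:
            d["AUPRC"] = self.AUPRC
        return d


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return math.nan, True
    return num / den, False


def metrics(tally: ConfusionTally) -> MetricsReport:
    """Evaluate the seven tally metrics.

    ACC=(TP+TN)/total, SN=TP/(TP+FN), Spec=TN/(TN+FP), PPV=TP/(TP+FP),
    NPV=TN/(TN+FN), F = 2*SN*PPV/(SN+PPV),
    MCC=(TP*TN - FP*FN)/sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
    """
    TP, FP, TN, FN = tally.TP, tally.FP, tally.TN, tally.FN
    undefined: set[str] = set()

    acc, bad = _ratio(TP + TN, TP + FP + TN + FN)
    sn, bad_sn = _ratio(TP, TP + FN)
    spec, bad_spec = _ratio(TN, TN + FP)
    ppv, bad_ppv = _ratio(TP, TP + FP)
    npv, bad_npv = _ratio(TN, TN + FN)
    for name, b in (("SN", bad_sn), ("Spec", bad_spec), ("PPV", bad_ppv), ("NPV", bad_npv)):
        if b:
            undefined.add(name)
    if bad_sn or bad_ppv or (not math.isnan(sn) and not math.isnan(ppv) and sn + ppv == 0):
        f = math.nan
        undefined.add("F_score")
    else:
        f = 2 * sn * ppv / (sn + ppv)
    mcc_den = math.sqrt(
        float(TP + FN) * float(TN + FP) * float(TP + FP) * float(TN + FN)
    )
    if mcc_den == 0:
        mcc = math.nan
        undefined.add("MCC")
    else:
        mcc = (TP * TN - FP * FN) / mcc_den
    return MetricsReport(
        ACC=acc, SN=sn, Spec=spec, PPV=ppv, NPV=npv, F_score=f, MCC=mcc,
        undefined=frozenset(undefined),
    )


def roc_pr(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """AUROC and AUPRC of real-valued scores against labels in {+1, -1}.

    AUROC is the rank statistic (probability a positive outranks a
    negative, ties counted half); AUPRC uses step-wise precision
    interpolation (average precision).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    classes = set(np.unique(y).tolist())
    if not classes <= {-1, 1}:
        raise ValueError(f"labels must be +1/-1, got {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("both classes must be present to rank")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def pair_classes(
    train_pairs: Iterable[tuple[str, str]],
    test_pairs: Iterable[tuple[str, str]],
) -> list[str]:
    """Assign each test pair its pair-input class relative to training.

    ``C1``: both proteins of the test pair occur in some training pair;
    ``C2``: exactly one does; ``C3``: neither does.
    """
    seen: set[str] = set()
    for a, b in train_pairs:
        seen.add(a)
        seen.add(b)
    out = []
    for a, b in test_pairs:
        hits = (a in seen) + (b in seen)
        out.append(("C3", "C2", "C1")[hits])
    return out
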