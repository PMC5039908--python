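"""Pair vectorization, the Random Forest classifier, cross-validation,
the lag sweep, and the feature-mode ablations.

A protein pair (A, B) is represented by concatenating per-protein
descriptors of both partners: 238 MMI values, 400 NMBAC values, or the
combined 638-value vector (MMI block first).  The ``order`` switch
("AB"/"BA") builds the forward or the backward vector of a pair, which
the ablation analysis uses to probe order sensitivity.

Classification is a Random Forest of unpruned trees grown on bootstrap
resamples, with a fixed number of candidate features drawn at each
split (default 500 trees, 25 candidates); prediction is a majority vote
across trees, the vote fraction doubling as a ranking score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .evaluation import ConfusionTally, MetricsReport, metrics, roc_pr
from .io_formats import PairRecord
from .mmi_features import mmi_feature_names, mmi_vector
from .nmbac_features import nmbac, nmbac_feature_names

__all__ = [
    "MODES",
    "build_pair_vector",
    "pair_feature_names",
    "PairVectorizer",
    "PPIForestClassifier",
    "train",
    "predict",
    "CVResult",
    "cross_validate",
    "cross_validate_pairs",
    "build_feature_matrix",
    "lag_sweep",
    "format_cv_table",
]

MODES = ("mmi", "nmbac", "combined")

DEFAULT_N_TREES = 500
DEFAULT_MTRY = 25


def _protein_vector(seq: str, mode: str, lg: int, role_mode: str, on_nonstandard: str) -> np.ndarray:
    if mode == "mmi":
        return mmi_vector(seq, role_mode=role_mode, on_nonstandard=on_nonstandard)
    if mode == "nmbac":
        return nmbac(seq, lg=lg, on_nonstandard=on_nonstandard)
    if mode == "combined":
        return np.concatenate(
            [
                mmi_vector(seq, role_mode=role_mode, on_nonstandard=on_nonstandard),
                nmbac(seq, lg=lg, on_nonstandard=on_nonstandard),
            ]
        )
    raise ValueError(f"unknown feature mode {mode!r}; expected one of {MODES}")


def build_pair_vector(
    seqA: str,
    seqB: str,
    mode: str = "combined",
    order: str = "AB",
    lg: int = 30,
    role_mode: str = "canonical",
    on_nonstandard: str = "error",
) -> np.ndarray:
    """Feature vector of one ordered protein pair.

    Combined mode concatenates the 238 MMI-pair values and then the 400
    NMBAC-pair values (at lg=30), i.e. [MMI(A)|MMI(B)|NMBAC(A)|NMBAC(B)],
    638 values.  ``order="BA"`` swaps the two proteins before encoding.
    """
    if order == "BA":
        seqA, seqB = seqB, seqA
    elif order != "AB":
        raise ValueError(f"order must be 'AB' or 'BA', got {order!r}")
    va = _protein_vector(seqA, mode, lg, role_mode, on_nonstandard)
    vb = _protein_vector(seqB, mode, lg, role_mode, on_nonstandard)
    if mode == "combined":
        n_mmi = 119
        return np.concatenate([va[:n_mmi], vb[:n_mmi], va[n_mmi:], vb[n_mmi:]])
    return np.concatenate([va, vb])


def pair_feature_names(mode: str = "combined", lg: int = 30) -> list[str]:
    """Column names of the pair vector, A_/B_-prefixed per partner."""
    if mode == "mmi":
        per = mmi_feature_names()
        return [f"A_{n}" for n in per] + [f"B_{n}" for n in per]
    if mode == "nmbac":
        per = nmbac_feature_names(lg)
        return [f"A_{n}" for n in per] + [f"B_{n}" for n in per]
    if mode == "combined":
        m = mmi_feature_names()
        a = nmbac_feature_names(lg)
        return (
            [f"A_{n}" for n in m]
            + [f"B_{n}" for n in m]
            + [f"A_{n}" for n in a]
            + [f"B_{n}" for n in a]
        )
    raise ValueError(f"unknown feature mode {mode!r}; expected one of {MODES}")


class PairVectorizer(BaseEstimator, TransformerMixin):
    """Transformer: (seqA, seqB) tuples -> pair feature matrix.

    Parameters
    ----------
    mode : {"combined", "mmi", "nmbac"}
        Which descriptor families to use (638, 238 or 400 columns at
        the default lag ceiling).
    order : {"AB", "BA"}
        Forward or backward pair vector.
    lg : int
        NMBAC lag ceiling.
    role_mode : {"canonical", "average"}
        Role assignment inside the three-way MMI term.
    """

    def __init__(
        self,
        mode: str = "combined",
        order: str = "AB",
        lg: int = 30,
        role_mode: str = "canonical",
        on_nonstandard: str = "error",
    ):
        self.mode = mode
        self.order = order
        self.lg = lg
        self.role_mode = role_mode
        self.on_nonstandard = on_nonstandard

    def fit(self, X: Iterable[tuple[str, str]], y=None):
        self.n_features_in_ = 2
        return self

    def transform(self, X: Iterable[tuple[str, str]]) -> np.ndarray:
        return np.array(
            [
                build_pair_vector(
                    a, b,
                    mode=self.mode, order=self.order, lg=self.lg,
                    role_mode=self.role_mode, on_nonstandard=self.on_nonstandard,
                )
                for a, b in X
            ]
        )

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(pair_feature_names(self.mode, self.lg), dtype=object)


class PPIForestClassifier(BaseEstimator, ClassifierMixin):
    """Random Forest over pair vectors with +1/-1 labels.

    An ensemble of ``n_trees`` unpruned CART trees, each grown on a
    bootstrap resample of the training set; at every node ``mtry``
    candidate features are drawn at random and the best split among
    them is used.  Prediction is the majority vote; the fraction of
    trees voting +1 is exposed as a ranking score, and an exact 0.5 tie
    resolves to +1.

    Parameters
    ----------
    n_trees : int, default 500
    mtry : int, default 25
        Candidate features per split (clipped to the feature count).
    seed : int or None
        Reproducibility seed for bootstrap and split sampling.
    """

    def __init__(self, n_trees: int = DEFAULT_N_TREES, mtry: int = DEFAULT_MTRY,
                 seed: int | None = None):
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training examples")
        classes = set(np.unique(y).tolist())
        if not classes <= {-1, 1}:
            raise ValueError(f"labels must be +1/-1, got {sorted(classes)}")
        if len(classes) < 2:
            raise ValueError("training set contains a single class")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=min(self.mtry, X.shape[1]),
            bootstrap=True,
            oob_score=True,
            random_state=self.seed,
            n_jobs=1,
        )
        self.forest_.fit(X, y)
        self.classes_ = np.array([-1, 1])
        self.n_features_in_ = X.shape[1]
        self.oob_score_ = float(self.forest_.oob_score_)
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1 and X.size == 0:
            return X.reshape(0, self.n_features_in_)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            got = X.shape[1] if X.ndim == 2 else X.shape
            raise ValueError(
                f"feature dimension mismatch: expected {self.n_features_in_}, got {got}"
            )
        return X

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of trees voting +1, in [0, 1]; the ranking score."""
        X = self._check_X(X)
        if X.shape[0] == 0:
            return np.empty(0)
        pos = int(np.flatnonzero(self.forest_.classes_ == 1)[0])
        return self.forest_.predict_proba(X)[:, pos]

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_X(X)
        if X.shape[0] == 0:
            return np.empty((0, 2))
        frac = self.vote_fraction(X)
        return np.column_stack([1 - frac, frac])

    def predict(self, X) -> np.ndarray:
        X = self._check_X(X)
        if X.shape[0] == 0:
            return np.empty(0, dtype=int)
        # tie at exactly 0.5 resolves to +1
        return np.where(self.vote_fraction(X) >= 0.5, 1, -1)


def train(X, y, n_trees: int = DEFAULT_N_TREES, mtry: int = DEFAULT_MTRY,
          seed: int | None = None) -> PPIForestClassifier:
    """Fit a :class:`PPIForestClassifier` (thin functional wrapper)."""
    return PPIForestClassifier(n_trees=n_trees, mtry=mtry, seed=seed).fit(X, y)


def predict(model: PPIForestClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels (+1/-1) and vote fractions for a feature matrix."""
    return model.predict(X), model.vote_fraction(X)


@dataclass
class CVResult:
    """Per-fold and aggregate cross-validation metrics."""

    fold_reports: list[MetricsReport]
    fold_assignment: np.ndarray  # fold index per example
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        keys = self.fold_reports[0].as_dict().keys()
        table = {k: np.array([r.as_dict()[k] for r in self.fold_reports]) for k in keys}
        self.mean = {k: float(np.nanmean(v)) for k, v in table.items()}
        self.sd = {k: float(np.nanstd(v, ddof=1)) if len(v) > 1 else 0.0
                   for k, v in table.items()}


def cross_validate(
    X,
    y,
    k: int = 5,
    n_trees: int = DEFAULT_N_TREES,
    mtry: int = DEFAULT_MTRY,
    seed: int | None = None,
) -> CVResult:
    """Seeded stratified k-fold cross-validation of the forest.

    Each fold is held out once; metrics (including AUROC/AUPRC from the
    vote fractions) are reported per fold and as mean +/- SD.  The same
    seed reproduces the same fold assignment, forests and metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of examples {X.shape[0]}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.full(X.shape[0], -1, dtype=int)
    reports: list[MetricsReport] = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        assignment[te] = fold
        fold_seed = None if seed is None else (seed + 1000003 * (fold + 1)) % (2**31 - 1)
        model = train(X[tr], y[tr], n_trees=n_trees, mtry=mtry, seed=fold_seed)
        labels, scores = predict(model, X[te])
        rep = metrics(ConfusionTally.from_labels(y[te], labels))
        try:
            rep.AUROC, rep.AUPRC = roc_pr(scores, y[te])
        except ValueError:
            pass  # single-class fold: areas undefined
        reports.append(rep)
    return CVResult(fold_reports=reports, fold_assignment=assignment)


def build_feature_matrix(
    sequences: dict[str, str],
    pairs: Sequence[PairRecord],
    mode: str = "combined",
    order: str = "AB",
    lg: int = 30,
    role_mode: str = "canonical",
    on_nonstandard: str = "error",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Vectorize a pair list against a sequence store.

    Returns (X, y, row ids); missing sequence ids raise with a listing.
    Per-protein descriptors are cached so each protein is encoded once.
    """
    missing = sorted(
        {p.idA for p in pairs if p.idA not in sequences}
        | {p.idB for p in pairs if p.idB not in sequences}
    )
    if missing:
        raise KeyError(f"pair list references unknown sequence ids: {missing}")
    cache: dict[str, np.ndarray] = {}

    def vec(pid: str) -> np.ndarray:
        if pid not in cache:
            cache[pid] = _protein_vector(
                sequences[pid], mode, lg, role_mode, on_nonstandard
            )
        return cache[pid]

    rows, ids = [], []
    n_mmi = 119
    for p in pairs:
        a, b = (p.idA, p.idB) if order == "AB" else (p.idB, p.idA)
        va, vb = vec(a), vec(b)
        if mode == "combined":
            rows.append(np.concatenate([va[:n_mmi], vb[:n_mmi], va[n_mmi:], vb[n_mmi:]]))
        else:
            rows.append(np.concatenate([va, vb]))
        ids.append(f"{p.idA}|{p.idB}")
    y = np.array([p.label for p in pairs])
    return np.array(rows), y, ids


def cross_validate_pairs(
    sequences: dict[str, str],
    pairs: Sequence[PairRecord],
    mode: str = "combined",
    k: int = 5,
    lg: int = 30,
    n_trees: int = DEFAULT_N_TREES,
    mtry: int = DEFAULT_MTRY,
    seed: int | None = None,
    order: str = "AB",
) -> CVResult:
    """End-to-end CV: vectorize a labeled pair list, then cross-validate."""
    X, y, _ = build_feature_matrix(sequences, pairs, mode=mode, order=order, lg=lg)
    return cross_validate(X, y, k=k, n_trees=n_trees, mtry=mtry, seed=seed)


DEFAULT_LG_VALUES = (5, 10, 15, 20, 25, 30, 35, 40, 45)


def lag_sweep(
    sequences: dict[str, str],
    pairs: Sequence[PairRecord],
    lg_values: Sequence[int] = DEFAULT_LG_VALUES,
    k: int = 5,
    n_trees: int = DEFAULT_N_TREES,
    mtry: int = DEFAULT_MTRY,
    seed: int | None = None,
) -> pd.DataFrame:
    """Accuracy of NMBAC-only features across lag ceilings.

    Runs cross-validation with NMBAC-only pair vectors at each requested
    lag ceiling; returns a table with one row per lg (mean accuracy +/-
    SD across folds).  Every sequence must be longer than max(lg_values).
    """
    max_lg = max(lg_values)
    used = sorted({p.idA for p in pairs} | {p.idB for p in pairs})
    offenders = [pid for pid in used if len(sequences.get(pid, "")) <= max_lg]
    if offenders:
        raise ValueError(
            f"sequences not longer than max lg={max_lg}: {offenders[:10]}"
            + ("..." if len(offenders) > 10 else "")
        )
    rows = []
    for lg in lg_values:
        res = cross_validate_pairs(
            sequences, pairs, mode="nmbac", k=k, lg=lg,
            n_trees=n_trees, mtry=mtry, seed=seed,
        )
        rows.append({"lg": lg, "mean_ACC": res.mean["ACC"], "sd_ACC": res.sd["ACC"]})
    return pd.DataFrame(rows)


def format_cv_table(result: CVResult) -> str:
    """Pretty per-fold metrics table with an 'Average x.xx +/- y.yy' row."""
    keys = list(result.fold_reports[0].as_dict().keys())
    lines = ["\t".join(["fold"] + keys)]
    for i, rep in enumerate(result.fold_reports, start=1):
        d = rep.as_dict()
        lines.append("\t".join([str(i)] + [f"{d[k]:.4f}" for k in keys]))
    lines.append(
        "\t".join(
            ["Average"]
            + [f"{result.mean[k]:.4f} ±{result.sd[k]:.4f}" for k in keys]
        )
    )
    return "\n".join(lines)
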