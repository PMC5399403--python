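"""Classifier training, bag aggregation, repeated nested cross-validation
and candidate ranking.

Two branches score a gene-drug pair:

* forest branch — a random forest on the one-hot instance matrix; the
  per-instance probabilities of a pair's bag are aggregated by a signed
  weighted mean: p_i = (sum_j a_j p_ij) / n_i with a_j = +1 when instance
  j is classified positive and -1 when negative, so p_i in [-1, 1]. A bag
  mixing confident positives and confident negatives lands near 0 instead
  of being dragged up as a max or plain mean would.
* kernel branch — a soft-margin C-SVC on a precomputed substructure-count
  kernel, with C selected by inner cross-validation and probabilities
  obtained from a sigmoid fit on inner-fold decision values.

Evaluation uses stratified 10-fold cross-validation repeated 10 times
with per-repeat seeds; folds are assigned at the pair level so the
instances of one bag can never straddle a fold boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .corpus import GeneDrugPair
from .features import NA, Bag, FeatureMatrix, InstanceRow, bags_to_frame, filter_features
from .labels import Label

# -- Eq.-style bag aggregation ----------------------------------------


def aggregate_bag(instances: Sequence[Tuple[float, int]]) -> float:
    """Signed weighted mean of instance probabilities.

    ``instances`` holds (p_ij, Class_ij) pairs with p_ij in [0, 1] and
    Class_ij in {0, 1}; the result lies in [-1, 1]. An empty bag is an
    error — a pair with no instances must not be silently scored.
    """
    if not len(instances):
        raise ValueError("cannot aggregate an empty bag")
    total = 0.0
    for p, klass in instances:
        a = 1.0 if klass == 1 else -1.0
        total += a * p
    return total / len(instances)


@dataclass
class BagScore:
    pair_id: Tuple[str, str]
    score: float  # p_i in [-1,1] (forest) or p in [0,1] (kernel)
    instances: List[Tuple[float, int]] = field(default_factory=list)


@dataclass
class RankedCandidate:
    rank: int
    gene: str
    drug: str
    p_rf: float
    p_gk: float


# -- metrics -----------------------------------------------------------


def evaluate_metrics(y_true: np.ndarray, prob_pos: np.ndarray, decision: np.ndarray) -> Dict:
    """Per-class precision/recall/F, prevalence-weighted and macro F,
    AUC-ROC (absent for single-class truth) and RMSE of the positive-class
    probability against 0/1 truth."""
    y_true = np.asarray(y_true, dtype=int)
    decision = np.asarray(decision, dtype=int)
    prob_pos = np.asarray(prob_pos, dtype=float)
    p, r, f, support = precision_recall_fscore_support(
        y_true, decision, labels=[1, 0], zero_division=0
    )
    weights = support / support.sum()
    out = {
        "per_class": {
            "1": {"precision": p[0], "recall": r[0], "f": f[0]},
            "0": {"precision": p[1], "recall": r[1], "f": f[1]},
        },
        "weighted_f": float(np.dot(weights, f)),
        "macro_f": float(f.mean()),
        "rmse": float(np.sqrt(np.mean((prob_pos - y_true) ** 2))),
    }
    out["auc_roc"] = float(roc_auc_score(y_true, prob_pos)) if len(set(y_true)) == 2 else None
    return out


@dataclass
class CVReport:
    folds: int
    repeats: int
    seeds: List[int]
    per_repeat: List[Dict]

    def _mean(self, key: str) -> float:
        vals = [r[key] for r in self.per_repeat if r[key] is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def _std(self, key: str) -> float:
        vals = [r[key] for r in self.per_repeat if r[key] is not None]
        return float(np.std(vals)) if vals else float("nan")

    @property
    def weighted_f(self) -> float:
        return self._mean("weighted_f")

    @property
    def macro_f(self) -> float:
        return self._mean("macro_f")

    @property
    def auc_roc(self) -> float:
        return self._mean("auc_roc")

    @property
    def rmse(self) -> float:
        return self._mean("rmse")

    @property
    def weighted_f_std(self) -> float:
        return self._std("weighted_f")

    def per_class_mean(self, klass: str, metric: str) -> float:
        return float(np.mean([r["per_class"][klass][metric] for r in self.per_repeat]))

    def to_dict(self) -> Dict:
        return {
            "folds": self.folds,
            "repeats": self.repeats,
            "seeds": self.seeds,
            "weighted_f": self.weighted_f,
            "weighted_f_std": self.weighted_f_std,
            "macro_f": self.macro_f,
            "auc_roc": self.auc_roc,
            "rmse": self.rmse,
            "per_repeat": self.per_repeat,
        }


# -- learners ----------------------------------------------------------


class ForestBagLearner:
    """Random forest on instance rows, scored at the bag level.

    Training freezes the one-hot vocabulary of the training rows; test
    rows re-use it, with unseen values falling back to NA columns.
    """

    def __init__(
        self,
        bags: Sequence[Bag],
        y: Sequence[int],
        seed: int = 0,
        n_estimators: int = 100,
        ig_threshold: float = 0.0,
    ):
        if len(bags) != len(y):
            raise ValueError("one label per bag required")
        self.bags = list(bags)
        self.y = np.asarray(y, dtype=int)
        self.seed = seed
        self.n_estimators = n_estimators
        self.ig_threshold = ig_threshold
        self._matrix: Optional[FeatureMatrix] = None
        self._model: Optional[RandomForestClassifier] = None

    def fit(self, train_idx: Sequence[int]) -> "ForestBagLearner":
        y_train = self.y[np.asarray(train_idx, dtype=int)]
        if len(set(y_train.tolist())) < 2:
            raise ValueError("training data contains a single class")
        train_bags = [self.bags[i] for i in train_idx]
        matrix = FeatureMatrix.from_bags(train_bags)
        if self.ig_threshold > 0:
            matrix = filter_features(matrix, self.ig_threshold)
        X = matrix.encode()
        y_rows = matrix.frame["class"].astype(int).to_numpy()
        model = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed, n_jobs=1
        )
        model.fit(X, y_rows)
        self._matrix, self._model = matrix, model
        return self

    def _score_bag(self, bag: Bag) -> BagScore:
        return self.score_bags([bag])[0]

    def score_bags(self, bags: Sequence[Bag]) -> List[BagScore]:
        if self._model is None:
            raise RuntimeError("fit() before score_bags()")
        if not bags:
            return []
        frame = bags_to_frame(bags)
        X = self._matrix.encode(frame)
        proba = self._model.predict_proba(X)
        p_pos = proba[:, list(self._model.classes_).index(1)]
        out = []
        start = 0
        for bag in bags:
            chunk = p_pos[start : start + bag.n_i]
            start += bag.n_i
            instances = [(float(p if p >= 0.5 else 1.0 - p), int(p >= 0.5)) for p in chunk]
            out.append(BagScore(bag.pair_id, aggregate_bag(instances), instances))
        return out

    def predict(self, test_idx: Sequence[int]) -> Tuple[np.ndarray, np.ndarray]:
        scores = self.score_bags([self.bags[i] for i in test_idx])
        p_i = np.array([s.score for s in scores])
        return (p_i + 1.0) / 2.0, (p_i > 0).astype(int)


class KernelSVMLearner:
    """C-SVC on a precomputed kernel with inner-fold C selection and
    sigmoid probability calibration on inner-fold decision values."""

    def __init__(
        self,
        K: np.ndarray,
        y: Sequence[int],
        C_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0),
        inner_folds: int = 10,
        seed: int = 0,
        psd_tol: float = 1e-9,
    ):
        K = np.asarray(K, dtype=float)
        if K.shape[0] != K.shape[1] or K.shape[0] != len(y):
            raise ValueError("kernel matrix must be square and match the labels")
        w_min = np.linalg.eigvalsh((K + K.T) / 2)[0]
        if w_min < -psd_tol:
            raise ValueError(f"kernel is not PSD (min eigenvalue {w_min:.3e})")
        self.K = K
        self.y = np.asarray(y, dtype=int)
        self.C_grid = tuple(C_grid)
        self.inner_folds = inner_folds
        self.seed = seed
        self._svc: Optional[SVC] = None
        self._cal: Optional[LogisticRegression] = None
        self._train_idx: Optional[np.ndarray] = None
        self.best_C: Optional[float] = None

    def fit(self, train_idx: Sequence[int]) -> "KernelSVMLearner":
        tr = np.asarray(train_idx, dtype=int)
        y = self.y[tr]
        if len(set(y.tolist())) < 2:
            raise ValueError("training data contains a single class")
        K_tr = self.K[np.ix_(tr, tr)]
        n_splits = min(self.inner_folds, np.bincount(y).min())
        n_splits = max(2, n_splits)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=self.seed)
        scores = {C: 0.0 for C in self.C_grid}
        dvals = {C: (np.zeros(len(tr)), []) for C in self.C_grid}
        for sub, val in skf.split(np.zeros(len(tr)), y):
            for C in self.C_grid:
                svc = SVC(C=C, kernel="precomputed")
                svc.fit(K_tr[np.ix_(sub, sub)], y[sub])
                df = svc.decision_function(K_tr[np.ix_(val, sub)])
                # model selection on the headline metric: weighted F
                scores[C] += f1_score(y[val], (df > 0).astype(int), average="weighted", zero_division=0)
                dvals[C][0][val] = df
        self.best_C = max(self.C_grid, key=lambda C: (scores[C], -C))
        self._svc = SVC(C=self.best_C, kernel="precomputed").fit(K_tr, y)
        # Platt-style calibration on cross-validated decision values
        df = dvals[self.best_C][0]
        self._cal = LogisticRegression()
        self._cal.fit(df.reshape(-1, 1), y)
        self._train_idx = tr
        return self

    def predict(self, test_idx: Sequence[int]) -> Tuple[np.ndarray, np.ndarray]:
        if self._svc is None:
            raise RuntimeError("fit() before predict()")
        te = np.asarray(test_idx, dtype=int)
        df = self._svc.decision_function(self.K[np.ix_(te, self._train_idx)])
        p = self._cal.predict_proba(df.reshape(-1, 1))[:, list(self._cal.classes_).index(1)]
        return p, (df > 0).astype(int)

    def score_pairs(self, pair_ids: Sequence[Tuple[str, str]], test_idx: Sequence[int]) -> List[BagScore]:
        p, _ = self.predict(test_idx)
        return [BagScore(pair_ids[i], float(pi)) for i, pi in zip(test_idx, p)]


class NestedKernelSVMLearner:
    """C-SVC over a *grid* of precomputed kernels.

    The inner cross-validation jointly selects the kernel setting and C
    on the outer-training fold (scored by weighted F), then refits and
    calibrates on the winning combination — the nested protocol used for
    final evaluation, where kernel settings are hyperparameters too.
    """

    def __init__(
        self,
        kernels: Dict[str, np.ndarray],
        y: Sequence[int],
        C_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0),
        inner_folds: int = 10,
        seed: int = 0,
        psd_tol: float = 1e-9,
    ):
        if not kernels:
            raise ValueError("need at least one kernel")
        self.names = sorted(kernels)
        self.kernels = {}
        self.y = np.asarray(y, dtype=int)
        for name in self.names:
            K = np.asarray(kernels[name], dtype=float)
            if K.shape[0] != K.shape[1] or K.shape[0] != len(self.y):
                raise ValueError(f"kernel {name!r} must be square and match the labels")
            w_min = np.linalg.eigvalsh((K + K.T) / 2)[0]
            if w_min < -psd_tol:
                raise ValueError(f"kernel {name!r} is not PSD (min eigenvalue {w_min:.3e})")
            self.kernels[name] = K
        self.C_grid = tuple(C_grid)
        self.inner_folds = inner_folds
        self.seed = seed
        self._svc: Optional[SVC] = None
        self._cal: Optional[LogisticRegression] = None
        self._train_idx: Optional[np.ndarray] = None
        self.best_setting: Optional[Tuple[str, float]] = None

    def fit(self, train_idx: Sequence[int]) -> "NestedKernelSVMLearner":
        tr = np.asarray(train_idx, dtype=int)
        y = self.y[tr]
        if len(set(y.tolist())) < 2:
            raise ValueError("training data contains a single class")
        n_splits = max(2, min(self.inner_folds, np.bincount(y).min()))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=self.seed)
        combos = [(name, C) for name in self.names for C in self.C_grid]
        scores = {c: 0.0 for c in combos}
        dvals = {c: np.zeros(len(tr)) for c in combos}
        for sub, val in skf.split(np.zeros(len(tr)), y):
            for name in self.names:
                K_tr = self.kernels[name][np.ix_(tr, tr)]
                K_ss = K_tr[np.ix_(sub, sub)]
                K_vs = K_tr[np.ix_(val, sub)]
                for C in self.C_grid:
                    svc = SVC(C=C, kernel="precomputed").fit(K_ss, y[sub])
                    df = svc.decision_function(K_vs)
                    scores[(name, C)] += f1_score(
                        y[val], (df > 0).astype(int), average="weighted", zero_division=0
                    )
                    dvals[(name, C)][val] = df
        self.best_setting = max(combos, key=lambda c: (scores[c], self.names.index(c[0]) * -1, -c[1]))
        name, C = self.best_setting
        K_tr = self.kernels[name][np.ix_(tr, tr)]
        self._svc = SVC(C=C, kernel="precomputed").fit(K_tr, y)
        self._cal = LogisticRegression()
        self._cal.fit(dvals[self.best_setting].reshape(-1, 1), y)
        self._train_idx = tr
        return self

    def predict(self, test_idx: Sequence[int]) -> Tuple[np.ndarray, np.ndarray]:
        if self._svc is None:
            raise RuntimeError("fit() before predict()")
        te = np.asarray(test_idx, dtype=int)
        K = self.kernels[self.best_setting[0]]
        df = self._svc.decision_function(K[np.ix_(te, self._train_idx)])
        p = self._cal.predict_proba(df.reshape(-1, 1))[:, list(self._cal.classes_).index(1)]
        return p, (df > 0).astype(int)


class ConstantLearner:
    """Predicts one class for everything (baseline / closed-form checks)."""

    def __init__(self, y: Sequence[int], klass: int = 1):
        self.y = np.asarray(y, dtype=int)
        self.klass = klass

    def fit(self, train_idx):
        return self

    def predict(self, test_idx):
        n = len(test_idx)
        return np.full(n, float(self.klass)), np.full(n, self.klass, dtype=int)


# -- cross-validation protocol ----------------------------------------


def crossvalidate(
    y: Sequence[int],
    learner,
    folds: int = 10,
    repeats: int = 10,
    base_seed: int = 0,
    pair_ids: Optional[Sequence[Tuple[str, str]]] = None,
    seeds: Optional[Sequence[int]] = None,
) -> CVReport:
    """Stratified k-fold CV at the pair level, repeated with per-repeat
    randomization seeds: ``seeds`` if given (one per repeat), otherwise
    repeat index XOR base seed. Any inner hyperparameter search happens
    inside ``learner.fit`` on the outer-training fold only.

    Pairs sharing an identity in ``pair_ids`` are forced into the same
    fold; a bag split across folds raises."""
    y = np.asarray(y, dtype=int)
    n = len(y)
    ids = list(pair_ids) if pair_ids is not None else [(str(i), "") for i in range(n)]
    groups: Dict[Tuple[str, str], List[int]] = {}
    for i, pid in enumerate(ids):
        groups.setdefault(pid, []).append(i)
    uniq = sorted(groups)
    uniq_y = np.array([y[groups[pid][0]] for pid in uniq])
    if seeds is not None:
        if len(seeds) != repeats:
            raise ValueError("need one randomization seed per repeat")
        seeds = [int(s) & 0x7FFFFFFF for s in seeds]
    else:
        seeds = [(r ^ base_seed) & 0x7FFFFFFF for r in range(repeats)]
    per_repeat = []
    for seed in seeds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        prob = np.zeros(n)
        decision = np.zeros(n, dtype=int)
        fold_of = np.full(n, -1, dtype=int)
        for k, (tr_u, te_u) in enumerate(skf.split(np.zeros(len(uniq)), uniq_y)):
            tr = [i for u in tr_u for i in groups[uniq[u]]]
            te = [i for u in te_u for i in groups[uniq[u]]]
            fold_of[te] = k
            learner.fit(tr)
            p, d = learner.predict(te)
            prob[te], decision[te] = p, d
        for pid, idx in groups.items():
            if len({int(fold_of[i]) for i in idx}) != 1:
                raise RuntimeError(f"leakage: bag {pid} split across folds")
        if (fold_of < 0).any():
            raise RuntimeError("some pairs were never assigned to a test fold")
        per_repeat.append(evaluate_metrics(y, prob, decision))
    return CVReport(folds=folds, repeats=repeats, seeds=seeds, per_repeat=per_repeat)


# -- ranking -----------------------------------------------------------


def combine_rankings(
    rf: Sequence[BagScore], gk: Sequence[BagScore], k: int = 20
) -> List[RankedCandidate]:
    """Intersect the top-k of both branches and sort by descending forest
    score (ties: descending kernel score, then pair id)."""

    def top(scores: Sequence[BagScore], name: str) -> Dict[Tuple[str, str], float]:
        if k > len(scores):
            warnings.warn(f"k={k} exceeds the {name} list ({len(scores)}); using the whole list")
        ordered = sorted(scores, key=lambda s: (-s.score, s.pair_id))
        return {s.pair_id: s.score for s in ordered[:k]}

    rf_top = top(rf, "forest")
    gk_top = top(gk, "kernel")
    common = sorted(
        set(rf_top) & set(gk_top),
        key=lambda pid: (-rf_top[pid], -gk_top[pid], pid),
    )
    return [
        RankedCandidate(rank=i + 1, gene=pid[0], drug=pid[1], p_rf=rf_top[pid], p_gk=gk_top[pid])
        for i, pid in enumerate(common)
    ]


def rankings_to_frame(ranked: Sequence[RankedCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"rank": r.rank, "gene": r.gene, "drug": r.drug, "p_RF": r.p_rf, "p_GK": r.p_gk}
            for r in ranked
        ],
        columns=["rank", "gene", "drug", "p_RF", "p_GK"],
    )


# -- scoring unseen candidates ----------------------------------------


def score_test_bags(learner: ForestBagLearner, bags: Sequence[Bag]) -> List[BagScore]:
    """Score unknown pairs with a fitted forest learner. A pair whose bag
    is degenerate (absent from the graph) gets an all-NA single row and a
    warning rather than a silent drop."""
    out = []
    for bag in bags:
        if not bag.rows:
            warnings.warn(f"pair {bag.pair_id} has no instances; scoring an all-NA row")
            bag = Bag(bag.pair_id, [
                InstanceRow(bag.pair_id, NA, NA, NA, NA, NA, NA, "unknown")
            ])
        out.append(learner._score_bag(bag))
    return out
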