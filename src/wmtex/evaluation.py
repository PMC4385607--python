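"""Nested cross-validation with wrapper feature selection.

The evaluation protocol estimates the generalization of the *whole*
procedure — rebalancing, feature selection and classification — not of a
single fitted model:

* **Outer loop**: stratified 10-fold CV.  Each outer training partition is
  (optionally) SMOTE-balanced, a feature subset is chosen on it, a 10-tree
  random forest is trained on the selected features, and the untouched outer
  test fold is predicted.  No test instance ever influences selection or
  training.
* **Inner loop**: best-first forward wrapper search.  Starting from the
  empty set, candidate subsets grow by single-feature additions; each
  candidate is scored by the mean macro F-measure of the 10-tree ensemble
  under stratified 10-fold CV *within the outer training partition*.  The
  search stops after five consecutive node expansions fail to improve the
  best score found.

Per-class precision ``P_k = TP_k / (TP_k + FP_k)`` and recall
``R_k = TP_k / (TP_k + FN_k)`` plus the total accuracy ``T`` are recorded per
outer fold and summarized as mean and sample standard deviation over folds,
reported in "m(s)" form.  A class never predicted in a fold has undefined
precision; such folds are excluded from that metric's average by default
(an ``undefined_as_zero`` switch scores them 0 instead, which reproduces the
"0.00 (0.00)" convention some toolkits print).
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .imbalance import CohortTable, smote_balance

__all__ = [
    "NestedCVConfig",
    "SelectionResult",
    "EvaluationReport",
    "stratified_folds",
    "macro_f_measure",
    "best_first_forward_selection",
    "run_nested_cv",
    "metrics_from_confusion",
    "summarize_folds",
    "apply_task",
]

logger = logging.getLogger(__name__)

_IMPROVE_EPS = 1e-10


@dataclass(frozen=True)
class NestedCVConfig:
    """Protocol parameters of the nested CV and the wrapper search."""

    outer_folds: int = 10
    inner_folds: int = 10
    n_trees: int = 10
    stale_limit: int = 5  # stop after this many non-improving node expansions
    stratified: bool = True
    seed: int = 0
    undefined_as_zero: bool = False

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.n_trees < 1 or self.stale_limit < 1:
            raise ValueError("n_trees and stale_limit must be >= 1")


def stratified_folds(labels: Sequence, k: int, seed: Optional[int] = None) -> List[np.ndarray]:
    """Disjoint stratified test-fold index sets covering all instances."""
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        warnings.warn(
            f"classes smaller than k={k} folds: {dict(small)}; "
            "some folds will lack these classes",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros((len(y), 1)), y)]


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def macro_f_measure(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> float:
    """Macro-averaged F1 over ``n_classes`` classes (absent classes score 0)."""
    cm = _confusion(np.asarray(y_true), np.asarray(y_pred), n_classes)
    tp = np.diag(cm).astype(float)
    denom = 2 * tp + (cm.sum(axis=0) - tp) + (cm.sum(axis=1) - tp)
    f1 = np.divide(2 * tp, denom, out=np.zeros(n_classes), where=denom > 0)
    return float(f1.mean())


class _BaggedTrees:
    """10-tree Breiman forest as a thin bagging loop over sklearn trees.

    Bootstrap resampling, sqrt(d) feature sampling per split and majority
    vote — functionally the same estimator as
    :class:`sklearn.ensemble.RandomForestClassifier`, assembled by hand so
    the wrapper search's thousands of tiny fits avoid the ensemble object's
    per-fit overhead.  Ties in the vote go to the lowest class index.
    """

    def __init__(self, n_trees: int, rng: np.random.Generator):
        self.n_trees = n_trees
        self.rng = rng
        self._trees: List[DecisionTreeClassifier] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaggedTrees":
        n = len(y)
        boot = self.rng.integers(0, n, size=(self.n_trees, n))
        seeds = self.rng.integers(0, 2**31 - 1, size=self.n_trees)
        self._trees = []
        for b, s in zip(boot, seeds):
            t = DecisionTreeClassifier(max_features="sqrt", random_state=int(s))
            t.fit(X[b], y[b], check_input=False)
            self._trees.append(t)
        return self

    def predict(self, X: np.ndarray, n_classes: int) -> np.ndarray:
        votes = np.zeros((len(X), n_classes), dtype=np.int32)
        rows = np.arange(len(X))
        for t in self._trees:
            pred = t.predict(X, check_input=False).astype(np.int64)
            votes[rows, pred] += 1
        return votes.argmax(axis=1)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one best-first forward wrapper search."""

    feature_names: Tuple[str, ...]
    feature_indices: Tuple[int, ...]
    merit: float
    n_expansions: int
    n_evaluated: int


def _encode_labels(labels: pd.Series, classes: Sequence[str]) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    return np.array([lookup[v] for v in labels], dtype=np.int64)


def best_first_forward_selection(
    table: CohortTable,
    config: NestedCVConfig = NestedCVConfig(),
    seed: Optional[int] = None,
) -> SelectionResult:
    """Best-first forward search over feature subsets.

    The search starts from the empty set (merit 0), expands the
    best-scoring open node by all single-feature additions, and terminates
    after ``config.stale_limit`` consecutive expansions that produce no new
    best subset.  Candidate merit is the mean macro F-measure of the
    10-tree ensemble under stratified ``inner_folds``-fold CV on ``table``;
    every subset is evaluated at most once, with its own deterministic
    random stream, so results do not depend on evaluation order.
    """
    classes = table.classes
    if len(classes) < 2:
        raise ValueError("feature selection needs at least 2 classes")
    seed = config.seed if seed is None else seed
    X = np.ascontiguousarray(table.X(), dtype=np.float32)
    y = _encode_labels(table.labels, classes)
    n_classes = len(classes)
    d = X.shape[1]
    names = list(table.features.columns)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fold_pairs = [
            (np.setdiff1d(np.arange(len(y)), test), test)
            for test in stratified_folds(y, config.inner_folds, seed=seed)
        ]

    cache: Dict[Tuple[int, ...], float] = {}

    def merit(subset: Tuple[int, ...]) -> float:
        got = cache.get(subset)
        if got is not None:
            return got
        Xs = np.ascontiguousarray(X[:, subset])
        # common random numbers: every subset sees the same bootstrap/seed
        # stream, so merit comparisons are paired and data-identical subsets
        # score identically (no spurious "improvements" from seed noise)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        scores = []
        for tr, te in fold_pairs:
            forest = _BaggedTrees(config.n_trees, rng).fit(Xs[tr], y[tr])
            pred = forest.predict(Xs[te], n_classes)
            scores.append(macro_f_measure(y[te], pred, n_classes))
        m = float(np.mean(scores))
        cache[subset] = m
        return m

    best_subset: Tuple[int, ...] = ()
    best_merit = 0.0
    open_heap: List[Tuple[float, Tuple[int, ...]]] = [(0.0, ())]
    expanded = set()
    stale = 0
    n_expansions = 0
    while open_heap:
        _, node = heapq.heappop(open_heap)
        if node in expanded:
            continue
        expanded.add(node)
        improved = False
        for j in range(d):
            if j in node:
                continue
            child = tuple(sorted(node + (j,)))
            if child in cache:
                continue
            m = merit(child)
            heapq.heappush(open_heap, (-m, child))
            if m > best_merit + _IMPROVE_EPS:
                best_merit, best_subset = m, child
                improved = True
        n_expansions += 1
        if improved:
            stale = 0
        else:
            stale += 1
            if stale >= config.stale_limit:
                break
    return SelectionResult(
        feature_names=tuple(names[j] for j in best_subset),
        feature_indices=best_subset,
        merit=best_merit,
        n_expansions=n_expansions,
        n_evaluated=len(cache),
    )


def metrics_from_confusion(cm: np.ndarray):
    """Total accuracy and per-class precision/recall of one confusion matrix.

    ``cm[i, j]`` counts class-``i`` instances predicted as class ``j``.
    Precision of a never-predicted class is undefined and returned as NaN
    (logged); recall of a class absent from the fold is likewise NaN.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    total = cm.sum()
    T = float(np.trace(cm) / total)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(col > 0, np.diag(cm) / np.where(col > 0, col, 1), np.nan)
        R = np.where(row > 0, np.diag(cm) / np.where(row > 0, row, 1), np.nan)
    for k in np.nonzero(col == 0)[0]:
        logger.info("class %d never predicted in this fold; precision undefined", k)
    return T, P, R


def summarize_folds(values: Sequence[float]) -> Tuple[float, float]:
    """Mean and sample SD (divisor n-1) over folds, NaN entries excluded.

    Undefined per-fold metrics (NaN markers from
    :func:`metrics_from_confusion`) do not enter the average; the SD is NaN
    when fewer than two defined values remain.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return float("nan"), float("nan")
    m = float(x.mean())
    s = float(x.std(ddof=1)) if x.size >= 2 else float("nan")
    return m, s


@dataclass
class EvaluationReport:
    """Per-fold confusion matrices, selections and the m(s) summary."""

    classes: Tuple[str, ...]
    confusions: List[np.ndarray]
    selected: List[Tuple[str, ...]]
    config: NestedCVConfig
    smote_mode: str

    def fold_metrics(self) -> pd.DataFrame:
        rows = []
        for cm in self.confusions:
            T, P, R = metrics_from_confusion(cm)
            row = {"T": T}
            for i, c in enumerate(self.classes):
                row[f"P_{c}"] = P[i]
                row[f"R_{c}"] = R[i]
            rows.append(row)
        return pd.DataFrame(rows, index=[f"fold{i}" for i in range(len(rows))])

    def summary(self, undefined_as_zero: Optional[bool] = None) -> pd.DataFrame:
        if undefined_as_zero is None:
            undefined_as_zero = self.config.undefined_as_zero
        fm = self.fold_metrics()
        if undefined_as_zero:
            fm = fm.fillna(0.0)
        out = {}
        for col in fm.columns:
            m, s = summarize_folds(fm[col].to_numpy())
            out[col] = {"m": m, "s": s}
        return pd.DataFrame(out).T

    def mean_total_accuracy(self) -> float:
        return float(self.summary().loc["T", "m"])

    def pooled_confusion(self) -> np.ndarray:
        return np.sum(self.confusions, axis=0)

    def to_text(self) -> str:
        s = self.summary()
        lines = [f"classes: {', '.join(self.classes)}  (smote={self.smote_mode})"]
        for name, row in s.iterrows():
            lines.append(f"  {name:>10s}  {row['m']:.2f} ({row['s']:.2f})")
        return "\n".join(lines)


def run_nested_cv(
    table: CohortTable,
    config: NestedCVConfig = NestedCVConfig(),
    smote_mode: str = "within-folds",
    smote_k: int = 5,
) -> EvaluationReport:
    """Run the full nested CV protocol on a cohort table.

    ``smote_mode`` is one of ``within-folds`` (balance each outer training
    partition only; the default, leakage-free placement), ``pre-split``
    (balance the whole table first) or ``off``.
    """
    if smote_mode not in ("within-folds", "pre-split", "off"):
        raise ValueError(f"unknown smote_mode {smote_mode!r}")
    classes = table.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if smote_mode == "pre-split":
        table = smote_balance(table, k=smote_k, seed=config.seed)

    y_all = _encode_labels(table.labels, classes)
    n_classes = len(classes)
    fold_seeds = np.random.SeedSequence(config.seed).generate_state(
        config.outer_folds + 1
    ) % (2**31 - 1)
    outer = stratified_folds(
        y_all, config.outer_folds, seed=int(fold_seeds[-1])
    )

    confusions, selections = [], []
    all_idx = np.arange(table.n_subjects)
    for f, test_idx in enumerate(outer):
        fold_seed = int(fold_seeds[f])
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_tab = table.subset(train_idx)
        if smote_mode == "within-folds":
            train_tab = smote_balance(train_tab, k=smote_k, seed=fold_seed)
        sel = best_first_forward_selection(train_tab, config, seed=fold_seed)
        cols = list(sel.feature_names)
        if not cols:  # degenerate: no subset ever improved on the empty set
            cols = list(table.features.columns)
        clf = RandomForestClassifier(
            n_estimators=config.n_trees, random_state=fold_seed, n_jobs=1
        )
        clf.fit(train_tab.features[cols].to_numpy(float),
                _encode_labels(train_tab.labels, classes))
        pred = clf.predict(table.features.iloc[test_idx][cols].to_numpy(float))
        confusions.append(_confusion(y_all[test_idx], pred.astype(np.int64), n_classes))
        selections.append(sel.feature_names)
        logger.debug("fold %d: selected %s", f, sel.feature_names)
    return EvaluationReport(
        classes=classes,
        confusions=confusions,
        selected=selections,
        config=config,
        smote_mode=smote_mode,
    )


def apply_task(table: CohortTable, task: str) -> CohortTable:
    """Map a NC/AD/LBD cohort onto one of the three classification tasks.

    ``three-class`` keeps the labels; ``nc-vs-dem`` merges AD and LBD into a
    single DEM class; ``ad-vs-lbd`` drops the NC rows.
    """
    if task == "three-class":
        return table
    if task == "nc-vs-dem":
        labels = table.labels.replace({"AD": "DEM", "LBD": "DEM"})
        return CohortTable(features=table.features, labels=labels,
                           provenance=table.provenance)
    if task == "ad-vs-lbd":
        keep = np.nonzero((table.labels != "NC").to_numpy())[0]
        return table.subset(keep)
    raise ValueError(f"unknown task {task!r}")
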