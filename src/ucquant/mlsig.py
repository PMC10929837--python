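"""Classifier benchmarking and random-forest recursive feature elimination.

A roster of eight classical learners is scored under repeated stratified
cross-validation on one shared fold plan, so differences between learners
are never an artifact of resampling.  The signature panel itself is chosen
by RF-RFE: forests ranked by mean decrease in Gini importance inside a
repeated-CV loop trace an error-vs-panel-size curve, and the final panel is
the top genes by full-training-set Gini importance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .core import ExpressionMatrix, SignaturePanel

logger = logging.getLogger("ucquant")

__all__ = [
    "split_cohort",
    "default_learners",
    "benchmark_learners",
    "rf_rfe",
    "LearnerBenchmark",
    "RFESelection",
    "PLSClassifier",
]


def split_cohort(
    expr: ExpressionMatrix,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Stratified train/test split of samples preserving group proportions."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    groups = expr.groups
    counts = groups.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each of the two groups needs >=2 samples to stratify")
    train_ids, test_ids = train_test_split(
        list(expr.sample_ids),
        train_size=train_fraction,
        stratify=groups.to_numpy(),
        random_state=int(seed) % (2**32),
    )
    return expr.subset_samples(train_ids), expr.subset_samples(test_ids)


class PLSClassifier(BaseEstimator, ClassifierMixin):
    """Partial-least-squares regression on 0/1 labels with clipped scores
    used as class probabilities (the classical PLS-DA shortcut)."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        ncomp = min(self.n_components, X.shape[1], max(1, X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=ncomp)
        self.pls_.fit(X, np.asarray(y, dtype=float))
        return self

    def predict_proba(self, X):
        p = np.clip(self.pls_.predict(X).ravel(), 0.0, 1.0)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def default_learners(rf_trees: int = 250, seed: int = 0) -> dict[str, BaseEstimator]:
    """The eight-learner roster: neural net, random forest, boosted GLM,
    elastic-net GLM, bagged CART, GLM, PLS and CART."""
    rs = int(seed) % (2**32)
    return {
        "nnet": MLPClassifier(hidden_layer_sizes=(10, 6), solver="lbfgs",
                              max_iter=1000, random_state=rs),
        "rf": RandomForestClassifier(n_estimators=rf_trees, random_state=rs),
        "glmboost": GradientBoostingClassifier(random_state=rs),
        "glmnet": LogisticRegression(penalty="elasticnet", solver="saga",
                                     l1_ratio=0.5, C=1.0, max_iter=5000,
                                     random_state=rs),
        "bagged_cart": BaggingClassifier(DecisionTreeClassifier(random_state=rs),
                                         n_estimators=25, random_state=rs),
        "glm": LogisticRegression(max_iter=5000, random_state=rs),
        "pls": PLSClassifier(),
        "cart": DecisionTreeClassifier(random_state=rs),
    }


@dataclass
class LearnerBenchmark:
    """Cross-validated metric means and SDs per learner on one fold plan."""

    summary: pd.DataFrame           # learner x (metric_mean, metric_sd)
    residuals: dict[str, np.ndarray]  # pooled probability - label residuals
    fold_plan: list[tuple[np.ndarray, np.ndarray]]
    failed_folds: dict[str, int] = field(default_factory=dict)


def _fold_metrics(y_true: np.ndarray, prob: np.ndarray) -> dict[str, float]:
    pred = (prob >= 0.5).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    recall = tp / (tp + fn) if tp + fn else np.nan
    precision = tp / (tp + fp) if tp + fp else np.nan
    f1 = (2 * precision * recall / (precision + recall)
          if precision and recall and np.isfinite(precision) and np.isfinite(recall)
          and precision + recall > 0 else (0.0 if (tp + fp and tp + fn) else np.nan))
    accuracy = (tp + tn) / len(y_true)
    if len(np.unique(y_true)) == 2:
        if len(np.unique(prob)) == 1:
            c_index = 0.5  # constant ranking carries no concordance information
        else:
            c_index = roc_auc_score(y_true, prob)
    else:
        c_index = np.nan
    rmsr = float(np.sqrt(np.mean((prob - y_true) ** 2)))
    return {"recall": recall, "precision": precision, "f1": f1,
            "accuracy": accuracy, "c_index": c_index, "rmsr": rmsr}


_METRICS = ["recall", "precision", "f1", "accuracy", "c_index", "rmsr"]


def benchmark_learners(
    train: ExpressionMatrix,
    learners: dict[str, BaseEstimator] | None = None,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    case_label: str = "case",
) -> LearnerBenchmark:
    """Score every learner on identical repeated stratified CV folds.

    Metrics per fold: recall, precision, F1, accuracy, concordance index
    (= ROC AUC of the ranked probabilities for a binary outcome) and the
    root mean square of the probability residuals (RMSR).
    """
    if learners is None:
        learners = default_learners(seed=seed)
    if not learners:
        raise ValueError("learner roster is empty")
    X = train.values.to_numpy().T
    y = (train.groups == case_label).astype(int).to_numpy()

    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=int(seed) % (2**32))
    fold_plan = [(tr.copy(), te.copy()) for tr, te in cv.split(X, y)]

    rows, residuals, failed = {}, {}, {}
    for name, proto in learners.items():
        per_fold = []
        resid = []
        n_failed = 0
        for tr, te in fold_plan:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = clone(proto).fit(X[tr], y[tr])
                    prob = model.predict_proba(X[te])[:, 1]
            except Exception as exc:  # noqa: BLE001 - learner failures are data
                n_failed += 1
                logger.warning("learner %s failed on a fold: %s", name, exc)
                continue
            per_fold.append(_fold_metrics(y[te], prob))
            resid.append(prob - y[te])
        if not per_fold:
            raise RuntimeError(f"learner {name} failed on every fold")
        if n_failed:
            failed[name] = n_failed
        tbl = pd.DataFrame(per_fold)
        rows[name] = {
            **{f"{m}_mean": tbl[m].mean() for m in _METRICS},
            **{f"{m}_sd": tbl[m].std(ddof=1) for m in _METRICS},
        }
        residuals[name] = np.concatenate(resid)

    return LearnerBenchmark(pd.DataFrame(rows).T, residuals, fold_plan, failed)


@dataclass
class RFESelection:
    """RF-RFE output: CV error curve, optimum, importances and the panel."""

    error_curve: pd.DataFrame      # index: panel size; columns: mean, sd
    optimal_size: int
    importance: pd.DataFrame       # per gene: gini, accuracy_decrease
    panel: SignaturePanel


def rf_rfe(
    train: ExpressionMatrix,
    deg: pd.DataFrame | None = None,
    folds: int = 10,
    repeats: int = 10,
    n_trees: int = 250,
    candidate_sizes: list[int] | None = None,
    panel_size: int = 12,
    seed: int = 0,
    case_label: str = "case",
    accuracy_importance: bool = True,
) -> RFESelection:
    """Recursive feature elimination by random-forest Gini importance.

    Per CV fold a forest ranks all genes by mean decrease in Gini; forests
    refit on the top-k genes for each candidate size give the held-out error
    curve.  ``optimal_size`` is the argmin of mean error (ties break to the
    smallest size, favouring parsimony).  The final panel is the top
    ``panel_size`` genes by Gini importance of a forest on the full training
    set, with directions taken from the DEG table (or the sign of the group
    mean difference when no table is supplied).
    """
    if n_trees < 50:
        logger.warning("n_trees=%d is small; forest importances will be noisy", n_trees)
    X = train.values.to_numpy().T
    y = (train.groups == case_label).astype(int).to_numpy()
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must be binary")
    genes = np.array(train.gene_ids)
    if candidate_sizes is None:
        candidate_sizes = [k for k in (2, 4, 8, 12, 16, 24, 32, 48, 64, 96)
                           if k <= len(genes)]
    candidate_sizes = sorted(set(candidate_sizes))
    if candidate_sizes[0] < 1 or candidate_sizes[-1] > len(genes):
        raise ValueError("candidate_sizes must lie within [1, n_features]")

    rs = int(seed) % (2**32)
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=rs)
    errors: dict[int, list[float]] = {k: [] for k in candidate_sizes}
    for tr, te in cv.split(X, y):
        ranker = RandomForestClassifier(n_estimators=n_trees, random_state=rs)
        ranker.fit(X[tr], y[tr])
        order = np.argsort(-ranker.feature_importances_, kind="stable")
        for k in candidate_sizes:
            cols = order[:k]
            sub = RandomForestClassifier(n_estimators=n_trees, random_state=rs)
            sub.fit(X[tr][:, cols], y[tr])
            err = 1.0 - sub.score(X[te][:, cols], y[te])
            errors[k].append(err)

    curve = pd.DataFrame(
        {"mean": [np.mean(errors[k]) for k in candidate_sizes],
         "sd": [np.std(errors[k], ddof=1) for k in candidate_sizes]},
        index=pd.Index(candidate_sizes, name="panel_size"),
    )
    optimal_size = int(curve.index[np.argmin(curve["mean"].to_numpy())])

    final = RandomForestClassifier(n_estimators=n_trees, random_state=rs)
    final.fit(X, y)
    gini = pd.Series(final.feature_importances_, index=genes, name="gini")
    if accuracy_importance:
        perm = permutation_importance(final, X, y, n_repeats=5, random_state=rs)
        acc_drop = pd.Series(perm.importances_mean, index=genes, name="accuracy_decrease")
    else:
        acc_drop = pd.Series(np.nan, index=genes, name="accuracy_decrease")
    importance = pd.concat([gini, acc_drop], axis=1)

    top = list(gini.sort_values(ascending=False, kind="stable").index[:panel_size])
    if deg is not None:
        directions = {g: (1 if deg.loc[g, "log2_fc"] > 0 else -1) for g in top}
    else:
        case_mean = X[y == 1].mean(axis=0)
        ctrl_mean = X[y == 0].mean(axis=0)
        diff = pd.Series(case_mean - ctrl_mean, index=genes)
        directions = {g: (1 if diff[g] > 0 else -1) for g in top}
    panel = SignaturePanel([(g, directions[g]) for g in top])
    return RFESelection(curve, optimal_size, importance, panel)
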