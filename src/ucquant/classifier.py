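"""Feature-score encoding and the backpropagation neural diagnostic model.

Panel expression is binarized against each gene's cohort median in a
direction-aware way: an up-regulated gene strictly above its median scores
1 (otherwise 0), a down-regulated gene strictly above its median scores 0
(otherwise 1).  The resulting 0/1 table trains a fully connected
feed-forward network with two hidden layers of 10 and 6 logistic units and
a logistic output, fit by full-batch gradient descent on cross-entropy
loss.  External cohorts are encoded against their own medians (medians are
not comparable across platforms) and assessed with the full confusion-matrix
metric suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, SignaturePanel

logger = logging.getLogger("ucquant")

__all__ = [
    "feature_score",
    "train_model",
    "validate_external",
    "cohen_kappa",
    "FeatureScoreMatrix",
    "DiagnosticModel",
]


@dataclass
class FeatureScoreMatrix:
    """Samples x panel-genes binary encoding plus the medians used."""

    scores: pd.DataFrame   # samples x genes, values in {0, 1}
    medians: pd.Series     # per-gene encoding median

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("feature scores must be 0/1")


def feature_score(
    expr: ExpressionMatrix,
    panel: SignaturePanel,
    medians: pd.Series | None = None,
) -> FeatureScoreMatrix:
    """Direction-aware median binarization of panel expression.

    up-gene: value > median -> 1 else 0; down-gene: value > median -> 0
    else 1.  Ties go to "not above" (strict ``>``).  ``medians`` defaults to
    the per-gene medians of this cohort.
    """
    missing = [g for g in panel.genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"panel genes absent from expression matrix: {missing}")
    sub = expr.values.loc[panel.genes]
    if medians is None:
        medians = sub.median(axis=1)
    above = sub.gt(medians, axis=0)  # genes x samples bool
    directions = panel.directions.loc[panel.genes]
    encoded = above.where(directions == 1, ~above).astype(int)
    return FeatureScoreMatrix(encoded.T, medians.copy())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class DiagnosticModel:
    """Feed-forward logistic network with stored weights and training trace."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    panel: SignaturePanel
    hidden: tuple[int, ...] = (10, 6)
    epochs: int = 0
    learning_rate: float = 0.5
    seed: int = 0
    loss_curve: list[float] = field(default_factory=list)

    def predict_proba(self, scores: FeatureScoreMatrix | pd.DataFrame) -> pd.Series:
        X = scores.scores if isinstance(scores, FeatureScoreMatrix) else scores
        X = X[self.panel.genes]  # enforce training feature order
        a = X.to_numpy(dtype=float)
        for W, b in zip(self.weights, self.biases):
            a = _sigmoid(a @ W + b)
        return pd.Series(a.ravel(), index=X.index, name="probability")

    def to_json(self, path) -> None:
        payload = {
            "hidden": list(self.hidden),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "panel": self.panel.entries,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "loss_curve": self.loss_curve,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "DiagnosticModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            [np.asarray(w) for w in d["weights"]],
            [np.asarray(b) for b in d["biases"]],
            SignaturePanel([(g, int(x)) for g, x in d["panel"]]),
            tuple(d["hidden"]), d["epochs"], d["learning_rate"], d["seed"],
            d["loss_curve"],
        )


def train_model(
    scores: FeatureScoreMatrix,
    labels: pd.Series,
    panel: SignaturePanel,
    hidden: tuple[int, ...] = (10, 6),
    epochs: int = 2000,
    learning_rate: float = 0.5,
    seed: int = 0,
) -> DiagnosticModel:
    """Train the backpropagation diagnostic network on a feature-score table.

    Logistic activations throughout, mean cross-entropy loss, full-batch
    gradient descent; deterministic given the seed.
    """
    X = scores.scores.to_numpy(dtype=float)
    y = np.asarray(labels.loc[scores.scores.index], dtype=float).reshape(-1, 1)
    counts = np.bincount(y.ravel().astype(int), minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples in each class")

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    sizes = [X.shape[1], *hidden, 1]
    weights = [rng.normal(0.0, 0.5, size=(a, b)) for a, b in zip(sizes[:-1], sizes[1:])]
    biases = [np.zeros(b) for b in sizes[1:]]

    loss_curve: list[float] = []
    n = X.shape[0]
    for epoch in range(epochs):
        activations = [X]
        a = X
        for W, b in zip(weights, biases):
            a = _sigmoid(a @ W + b)
            activations.append(a)
        p = np.clip(activations[-1], 1e-12, 1 - 1e-12)
        loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        loss_curve.append(loss)

        # backprop: logistic output with cross-entropy gives delta = p - y
        delta = (activations[-1] - y) / n
        for layer in range(len(weights) - 1, -1, -1):
            a_prev = activations[layer]
            grad_W = a_prev.T @ delta
            grad_b = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ weights[layer].T) * activations[layer] * (1 - activations[layer])
            weights[layer] -= learning_rate * grad_W
            biases[layer] -= learning_rate * grad_b

    return DiagnosticModel(weights, biases, panel, tuple(hidden), epochs,
                           learning_rate, seed, loss_curve)


def cohen_kappa(tp: int, fp: int, tn: int, fn: int) -> float:
    """Cohen's kappa from a 2x2 confusion matrix: (po - pe) / (1 - pe)."""
    n = tp + fp + tn + fn
    if n == 0:
        return float("nan")
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1 - pe)


def _auc(y: np.ndarray, prob: np.ndarray) -> float:
    """Rank-based ROC AUC (Mann-Whitney form) with midrank tie handling."""
    pos = prob[y == 1]
    neg = prob[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    return (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))


def _cohort_report(y: np.ndarray, prob: np.ndarray, threshold: float,
                   n_boot: int, rng: np.random.Generator) -> dict:
    pred = (prob >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    if not (tp + fn) or not (tn + fp):
        logger.warning("single-class cohort: sensitivity or specificity undefined")
    prec = tp / (tp + fp) if tp + fp else np.nan
    rec = sens
    f1 = (2 * prec * rec / (prec + rec)
          if np.isfinite(prec) and np.isfinite(rec) and prec + rec > 0 else np.nan)
    auc = _auc(y, prob)
    boots = []
    idx = np.arange(len(y))
    for _ in range(n_boot):
        b = rng.choice(idx, size=len(idx), replace=True)
        a = _auc(y[b], prob[b])
        if np.isfinite(a):
            boots.append(a)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))) if boots else (np.nan, np.nan)
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": sens, "specificity": spec,
        "accuracy": (tp + tn) / len(y),
        "kappa": cohen_kappa(tp, fp, tn, fn),
        "precision": prec, "recall": rec, "f1": f1,
        "auc": auc, "auc_ci_low": ci[0], "auc_ci_high": ci[1],
    }


def validate_external(
    model: DiagnosticModel,
    cohorts: dict[str, ExpressionMatrix],
    panel: SignaturePanel | None = None,
    threshold: float = 0.5,
    case_label: str = "case",
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Score labeled external cohorts and report the full metric suite.

    Each cohort is feature-score-encoded against its *own* medians (medians
    do not transfer across platforms), scored by the trained network and
    thresholded; sensitivity, specificity, accuracy, kappa, precision,
    recall, F1 and bootstrap-CI AUC are reported per cohort.  A cohort
    missing panel genes fails individually; the rest proceed.
    """
    panel = panel or model.panel
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    rows = {}
    for name, cohort in cohorts.items():
        try:
            fs = feature_score(cohort, panel)
        except KeyError as exc:
            logger.warning("cohort %s failed encoding: %s", name, exc)
            rows[name] = {"error": str(exc)}
            continue
        prob = model.predict_proba(fs)
        y = (cohort.groups.loc[prob.index] == case_label).astype(int).to_numpy()
        rows[name] = _cohort_report(y, prob.to_numpy(), threshold, n_boot, rng)
    return pd.DataFrame(rows).T
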