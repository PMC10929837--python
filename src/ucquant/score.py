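"""The unsupervised disease-quantification system.

Bray-Curtis dissimilarities over signature-panel expression are embedded by
principal coordinates analysis (PCoA, Gower double-centering); group
structure is tested with ANOSIM and PERMANOVA; the per-sample score is the
sum of the first two PCoA axes (sign-oriented so high = disease-like), with
a median split into High/Low strata.  The same module provides rank-based
gene-set activity scoring (recovery-curve AUC within a top-ranking window)
for bulk signatures and per-cell scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .core import ExpressionMatrix, GeneSetCollection, SignaturePanel, substream

logger = logging.getLogger("ucquant")

__all__ = [
    "bray_curtis",
    "pcoa",
    "anosim",
    "permanova",
    "compute_ucrscore",
    "activity_score",
    "threshold_cells",
    "cell_ucrscore",
    "DissimilarityMatrix",
    "PCoAResult",
    "ActivityScore",
]


@dataclass
class DissimilarityMatrix:
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be square and symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def bray_curtis(expr: ExpressionMatrix) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between samples over the given genes.

    BC(a, b) = sum|a_i - b_i| / sum(a_i + b_i).  Log2 expression can be
    negative, so any matrix with negative entries is shifted by its global
    minimum first (logged).  A pair with zero combined abundance is defined
    as dissimilarity 0 with a warning.
    """
    X = expr.values.to_numpy(dtype=float).T  # samples x genes
    if X.min() < 0:
        logger.info("shifting expression by %.4f so Bray-Curtis sees non-negative values",
                    -X.min())
        X = X - X.min()
    n = X.shape[0]
    D = np.zeros((n, n))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = pdist(X, metric="braycurtis")
    if np.isnan(d).any():
        logger.warning("%d sample pairs have zero combined abundance; dissimilarity set to 0",
                       int(np.isnan(d).sum()))
        d = np.nan_to_num(d, nan=0.0)
    D = squareform(d)
    return DissimilarityMatrix(D, expr.sample_ids)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame      # samples x retained axes
    eigenvalues: np.ndarray        # descending, all (including non-positive)
    negative_mass: float           # sum of |negative eigenvalues|

    @property
    def axes(self) -> list[str]:
        return list(self.coordinates.columns)


def pcoa(d: DissimilarityMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical (metric) multidimensional scaling by Gower double-centering.

    B = -1/2 J D^2 J, eigendecomposition; coordinates are eigenvectors
    scaled by sqrt(eigenvalue) for positive eigenvalues only; the absolute
    mass of negative eigenvalues is reported.
    """
    D2 = d.values**2
    n = d.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-10).sum())
    if n_axes > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues; truncating",
                       n_axes, n_pos)
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    return PCoAResult(
        pd.DataFrame(coords, index=d.sample_ids,
                     columns=[f"PCoA{i + 1}" for i in range(n_axes)]),
        evals,
        float(np.abs(evals[evals < 0]).sum()),
    )


def _condensed_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju


def _check_groups(labels: np.ndarray) -> None:
    vals, counts = np.unique(labels, return_counts=True)
    if len(vals) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")


def anosim(
    d: DissimilarityMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Analysis of similarities: rank-based between- vs within-group contrast.

    R = (mean rank between - mean rank within) / (M/2) with M = n(n-1)/2;
    the P-value is by label permutation, p = (1 + #{R_perm >= R_obs}) /
    (n_perm + 1).
    """
    labels = np.asarray(groups)
    _check_groups(labels)
    if n_perm < 99:
        logger.warning("n_perm=%d is small; permutation p-values will be coarse", n_perm)
    n = d.n
    ranks = rankdata(d.condensed())
    M = n * (n - 1) / 2
    iu, ju = _condensed_pairs(n)

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2)

    r_obs = r_stat(labels)
    rng = substream(seed, "anosim")
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    within = perms[:, iu] == perms[:, ju]  # n_perm x n_pairs
    w_counts = within.sum(axis=1)
    sum_within = (ranks[None, :] * within).sum(axis=1)
    total = ranks.sum()
    mean_within = sum_within / w_counts
    mean_between = (total - sum_within) / (len(ranks) - w_counts)
    r_perm = (mean_between - mean_within) / (M / 2)
    p = (1 + int((r_perm >= r_obs).sum())) / (n_perm + 1)
    return float(r_obs), float(p)


def permanova(
    d: DissimilarityMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutational MANOVA pseudo-F on squared dissimilarities.

    SS_total = sum d_ij^2 / n over all pairs; SS_within sums within-group
    pair terms / group size; pseudo-F = (SS_between/(g-1)) /
    (SS_within/(n-g)); P by label permutation.
    """
    labels = np.asarray(groups)
    _check_groups(labels)
    if n_perm < 99:
        logger.warning("n_perm=%d is small; permutation p-values will be coarse", n_perm)
    n = d.n
    d2 = d.condensed() ** 2
    iu, ju = _condensed_pairs(n)
    uniq = np.unique(labels)
    g = len(uniq)
    ss_total = d2.sum() / n

    codes = np.searchsorted(uniq, labels)
    sizes = np.bincount(codes, minlength=g).astype(float)

    def pseudo_f(code_rows: np.ndarray) -> np.ndarray:
        # code_rows: n_perm x n integer labels
        li, lj = code_rows[:, iu], code_rows[:, ju]
        within = li == lj
        ss_within = np.zeros(code_rows.shape[0])
        for gi in range(g):
            mask = within & (li == gi)
            ss_within += (d2[None, :] * mask).sum(axis=1) / sizes[gi]
        ss_between = ss_total - ss_within
        return (ss_between / (g - 1)) / (ss_within / (n - g))

    f_obs = float(pseudo_f(codes[None, :])[0])
    rng = substream(seed, "permanova")
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    f_perm = pseudo_f(perms)
    p = (1 + int((f_perm >= f_obs).sum())) / (n_perm + 1)
    return f_obs, float(p)


def compute_ucrscore(
    pcoa_result: PCoAResult,
    expr: ExpressionMatrix,
    panel: SignaturePanel,
    mode: str = "sum_axes",
) -> pd.DataFrame:
    """Per-sample disease score from the first two PCoA axes.

    Default ``sum_axes``: score = PCoA1 + PCoA2, each axis sign-oriented to
    correlate positively with summed panel up-gene expression so the High
    stratum is reproducibly disease-like (PCoA axis signs are arbitrary).
    ``weighted`` implements the multiplicative reading:
    (PCoA1 + PCoA2) x sum of panel-gene expression.  Samples are split into
    High/Low strata at the median score.
    """
    if mode not in ("sum_axes", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(pcoa_result.axes) < 2:
        raise ValueError("need at least 2 PCoA axes")
    coords = pcoa_result.coordinates.iloc[:, :2].copy()
    if (coords.std(ddof=1) == 0).any():
        raise ValueError("degenerate PCoA axis with zero variance")

    anchor_genes = panel.up_genes or panel.genes
    anchor = expr.values.loc[[g for g in anchor_genes if g in expr.values.index]].sum(axis=0)
    anchor = anchor.loc[coords.index]
    for col in coords.columns:
        if np.corrcoef(coords[col], anchor)[0, 1] < 0:
            coords[col] = -coords[col]

    score = coords.iloc[:, 0] + coords.iloc[:, 1]
    if mode == "weighted":
        total_expr = expr.values.loc[[g for g in panel.genes if g in expr.values.index]].sum(axis=0)
        score = score * total_expr.loc[score.index]

    med = score.median()
    if np.allclose(score, score.iloc[0]):
        raise ValueError("all scores identical; cannot stratify at the median")
    # median split; ties at the median go Low so strata stay balanced
    order = score.rank(method="first")
    stratum = np.where(order > len(score) / 2, "High", "Low")
    out = pd.DataFrame(
        {"ucr_score": score, "group": expr.groups.loc[score.index], "stratum": stratum}
    )
    out.attrs["median"] = float(med)
    return out


@dataclass
class ActivityScore:
    """Per-column (sample or cell) recovery-curve AUCs per gene set."""

    scores: pd.DataFrame   # columns x gene sets
    top_fraction: float


def activity_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    top_fraction: float = 0.05,
) -> ActivityScore:
    """Rank-recovery AUC of each gene set within each column's top ranks.

    Genes are ranked by expression descending (stable tie-break by input
    gene order); the recovery curve counts set genes among the top k for
    k = 1..ceil(top_fraction x n_genes), and its area is normalized by the
    maximum achievable area.  A set with no genes in the matrix scores NA.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    V = expr.values.to_numpy(dtype=float)
    n_genes, n_cols = V.shape
    w = int(np.ceil(top_fraction * n_genes))
    # stable descending sort: gene order breaks ties
    order = np.argsort(-V, axis=0, kind="stable")[:w]  # w x cols: gene indices per rank

    gene_index = {g: i for i, g in enumerate(expr.values.index)}
    out = {}
    for name in sets.names:
        members = [gene_index[g] for g in sets[name] if g in gene_index]
        if not members:
            logger.warning("gene set %s has no overlap with the matrix; score NA", name)
            out[name] = np.full(n_cols, np.nan)
            continue
        member_mask = np.zeros(n_genes, dtype=bool)
        member_mask[members] = True
        hits = member_mask[order]                 # w x cols
        curve = np.cumsum(hits, axis=0)           # recovery counts at k=1..w
        area = curve.sum(axis=0).astype(float)
        ks = np.arange(1, w + 1)
        max_area = np.minimum(ks, len(members)).sum()
        out[name] = area / max_area
    return ActivityScore(pd.DataFrame(out, index=expr.values.columns), top_fraction)


def threshold_cells(
    scores: ActivityScore,
    threshold: float,
    set_name: str | None = None,
) -> tuple[pd.Series, int]:
    """Flag cells scoring strictly above the threshold for one gene set."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if set_name is None:
        if scores.scores.shape[1] != 1:
            raise ValueError("multiple gene sets scored; name one")
        set_name = scores.scores.columns[0]
    flags = scores.scores[set_name] > threshold
    return flags, int(flags.sum())


def cell_ucrscore(
    expr: ExpressionMatrix,
    panel: SignaturePanel,
    method: str = "mean",
    top_fraction: float = 0.05,
) -> pd.Series:
    """Per-cell panel score: mean panel-gene expression or the rank AUC."""
    if method == "mean":
        genes = [g for g in panel.genes if g in expr.values.index]
        if not genes:
            raise KeyError("no panel genes present in the matrix")
        return expr.values.loc[genes].mean(axis=0).rename("cell_ucrscore")
    if method == "auc":
        sets = GeneSetCollection({"panel": list(panel.genes)})
        return activity_score(expr, sets, top_fraction).scores["panel"].rename("cell_ucrscore")
    raise ValueError(f"unknown method {method!r}")
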