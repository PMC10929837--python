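"""Differential expression, global expression divergence and lightweight
weighted co-expression network (WGCNA-style) module detection.

Differential calls use a per-gene Welch t-test on log2 values with the
classical raw-P and |log2FC| thresholds; a BH-adjusted FDR column is always
reported.  The divergence statistic between two expression profiles is the
root-mean-square difference of log2 values (a scaled Euclidean distance).
Module detection raises |Pearson| correlations to a soft power beta, smooths
the adjacency into a topological overlap matrix (TOM) and clusters 1-TOM by
average linkage, with eigengene-based module merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, SignaturePanel

logger = logging.getLogger("ucquant")

__all__ = [
    "differential_expression",
    "rmsd_divergence",
    "pairwise_divergence_summary",
    "topological_overlap",
    "scale_free_fit",
    "detect_modules",
    "common_degs",
    "ModuleAssignment",
]

_MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]


def differential_expression(
    expr: ExpressionMatrix,
    p_cut: float = 0.05,
    lfc_cut: float = 1.0,
    case_label: str = "case",
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-gene Welch t-test between the two groups of ``expr``.

    Returns a frame indexed by gene with ``log2_fc`` (case mean - control
    mean), ``p_value``, BH-adjusted ``fdr`` and a ``direction`` call in
    {up, down, ns}.  Direction uses the raw P threshold (the FDR column is
    reported alongside); genes constant in both groups are called ``ns``.
    """
    groups = set(expr.groups.unique())
    if groups != {case_label, control_label}:
        raise ValueError(f"expected groups {{{case_label}, {control_label}}}, got {groups}")
    case = expr.values.loc[:, (expr.groups == case_label).to_numpy()].to_numpy()
    ctrl = expr.values.loc[:, (expr.groups == control_label).to_numpy()].to_numpy()
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.warning("%d genes constant in both groups; called ns", int(degenerate.sum()))

    fdr = np.full_like(lfc, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]

    direction = np.where(
        ok & (p < p_cut) & (np.abs(lfc) > lfc_cut),
        np.where(lfc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {"log2_fc": lfc, "p_value": p, "fdr": fdr, "direction": direction},
        index=expr.values.index,
    )


def rmsd_divergence(x, y, gene_ids=None, log2_input: bool = True) -> float:
    """Root-mean-square log2 divergence between two expression profiles.

    sqrt(mean((log2 x_i - log2 y_i)^2)) over the shared genes.  With
    ``log2_input=False`` the inputs are linear-scale and must be positive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must share the same gene vector")
    if not log2_input:
        bad = (x <= 0) | (y <= 0)
        if bad.any():
            names = (
                [gene_ids[i] for i in np.flatnonzero(bad)] if gene_ids is not None
                else list(np.flatnonzero(bad))
            )
            raise ValueError(f"non-positive linear values for genes: {names[:10]}")
        x, y = np.log2(x), np.log2(y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def pairwise_divergence_summary(
    expr: ExpressionMatrix,
    case_label: str = "case",
    control_label: str = "control",
) -> dict[str, np.ndarray]:
    """Distributions of pairwise divergences binned by group relation.

    Returns arrays for the three bins ``between`` (case<->control),
    ``within_case`` and ``within_control``; empty within-bins (group of
    size 1) are flagged with a warning.
    """
    X = expr.values.to_numpy().T  # samples x genes
    n = X.shape[0]
    labels = expr.groups.to_numpy()
    from scipy.spatial.distance import pdist

    d = pdist(X, metric="euclidean") / np.sqrt(X.shape[1])
    iu, ju = np.triu_indices(n, k=1)
    both_case = (labels[iu] == case_label) & (labels[ju] == case_label)
    both_ctrl = (labels[iu] == control_label) & (labels[ju] == control_label)
    out = {
        "between": d[~both_case & ~both_ctrl],
        "within_case": d[both_case],
        "within_control": d[both_ctrl],
    }
    for key, arr in out.items():
        if arr.size == 0:
            logger.warning("divergence bin %s is empty (singleton group)", key)
    return out


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned TOM of a symmetric adjacency with zero diagonal.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij); the
    diagonal is set to 1.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    num = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def scale_free_fit(expr: ExpressionMatrix, betas=(1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20),
                   n_bins: int = 10) -> pd.Series:
    """R^2 of the scale-free topology fit (log p(k) vs log k) per soft power.

    Diagnostic sweep only; the working beta is taken from configuration.
    """
    X = expr.values.to_numpy()
    corr = np.corrcoef(X)
    np.fill_diagonal(corr, 0.0)
    out = {}
    for beta in betas:
        k = (np.abs(corr) ** beta).sum(axis=1)
        hist, edges = np.histogram(k, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = (hist > 0) & (centers > 0)
        if keep.sum() < 3:
            out[beta] = np.nan
            continue
        lx, ly = np.log10(centers[keep]), np.log10(hist[keep])
        r = np.corrcoef(lx, ly)[0, 1]
        out[beta] = float(r**2)
    return pd.Series(out, name="scale_free_r2")


@dataclass
class ModuleAssignment:
    """Result of module detection: labels, eigengenes and trait statistics."""

    labels: pd.Series                 # gene -> module color or "unassigned"
    eigengenes: pd.DataFrame          # samples x modules, unit variance
    trait_correlation: pd.DataFrame   # per module: r, p vs the case/control trait
    gene_significance: pd.Series      # |cor(gene, trait)|
    module_membership: pd.Series      # |cor(gene, its module eigengene)|
    merge_trace: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    def module_genes(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _eigengene(X: np.ndarray) -> np.ndarray:
    """First principal component sample scores of standardized expression,
    unit variance, sign-oriented to correlate positively with the module mean."""
    sd = X.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    e = e / e.std(ddof=1)
    mean_profile = X.mean(axis=0)
    if np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    return e


def detect_modules(
    expr: ExpressionMatrix,
    beta: float = 14.0,
    min_module_size: int = 50,
    merge_cut_height: float = 0.25,
    top_n_variable: int = 5000,
    cut_height: float = 0.995,
    case_label: str = "case",
    drop_outliers: bool = True,
) -> ModuleAssignment:
    """WGCNA-style unsigned module detection on the most variable genes.

    Pipeline: optional outlier-sample exclusion (mean inter-sample
    correlation > 3 SD below the cohort mean), restriction to the
    ``top_n_variable`` genes by SD, adjacency |r|^beta, TOM smoothing,
    average-linkage clustering of 1-TOM cut at ``cut_height`` with clusters
    below ``min_module_size`` left unassigned, and eigengene-correlation
    merging at ``1 - merge_cut_height``.
    """
    values = expr.values
    dropped: list[str] = []
    if drop_outliers and expr.n_samples >= 4:
        sc = np.corrcoef(values.to_numpy().T)
        np.fill_diagonal(sc, np.nan)
        mean_corr = np.nanmean(sc, axis=1)
        z = (mean_corr - mean_corr.mean()) / (mean_corr.std(ddof=1) or 1.0)
        dropped = [s for s, zi in zip(values.columns, z) if zi < -3]
        if dropped:
            logger.info("excluding %d outlier samples: %s", len(dropped), dropped)
            expr = expr.subset_samples([s for s in values.columns if s not in dropped])
            values = expr.values

    sds = values.std(axis=1, ddof=1)
    constant = sds == 0
    if constant.any():
        logger.warning("removing %d constant genes before correlation", int(constant.sum()))
    values = values.loc[~constant]
    keep = values.std(axis=1, ddof=1).nlargest(min(top_n_variable, values.shape[0])).index
    values = values.loc[keep]
    if values.shape[0] < min_module_size:
        raise ValueError("fewer genes than min_module_size after variance filtering")

    X = values.to_numpy()
    corr = np.corrcoef(X)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    tom = topological_overlap(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = average(squareform(dist, checks=False))
    raw = fcluster(Z, t=cut_height, criterion="distance")

    genes = list(values.index)
    sizes = pd.Series(raw).value_counts()
    big = [c for c in sizes.index if sizes[c] >= min_module_size]
    # order modules by size (descending) for stable color naming
    big.sort(key=lambda c: (-sizes[c], c))
    labels = pd.Series("unassigned", index=genes, dtype=object)
    module_map = {}
    for i, c in enumerate(big):
        color = _MODULE_COLORS[i] if i < len(_MODULE_COLORS) else f"module{i}"
        module_map[c] = color
        labels[[g for g, r in zip(genes, raw) if r == c]] = color

    trait = (expr.groups == case_label).astype(float).to_numpy()
    merge_trace: list[str] = []

    def eigengene_frame(lbl: pd.Series) -> pd.DataFrame:
        cols = {}
        for m in sorted(set(lbl) - {"unassigned"}):
            cols[m] = _eigengene(values.loc[lbl == m].to_numpy())
        return pd.DataFrame(cols, index=values.columns)

    eig = eigengene_frame(labels)
    # iterative eigengene merging
    while eig.shape[1] > 1:
        ec = eig.corr().to_numpy()
        np.fill_diagonal(ec, -np.inf)
        i, j = np.unravel_index(np.argmax(ec), ec.shape)
        if ec[i, j] <= 1.0 - merge_cut_height:
            break
        a, b = eig.columns[i], eig.columns[j]
        keep_lbl, drop_lbl = (a, b) if (labels == a).sum() >= (labels == b).sum() else (b, a)
        merge_trace.append(f"merge {drop_lbl} -> {keep_lbl} (eigengene r={ec[i, j]:.3f})")
        labels[labels == drop_lbl] = keep_lbl
        eig = eigengene_frame(labels)

    if eig.shape[1] == 0:
        logger.warning("no module reached min_module_size; all genes unassigned")

    trait_rows = {}
    for m in eig.columns:
        r, p = stats.pearsonr(eig[m].to_numpy(), trait)
        trait_rows[m] = {"r": r, "p": p}
    trait_corr = pd.DataFrame(trait_rows).T if trait_rows else pd.DataFrame(columns=["r", "p"])

    gs = pd.Series(
        [abs(np.corrcoef(row, trait)[0, 1]) if row.std() > 0 else np.nan for row in X],
        index=genes, name="GS",
    )
    mm = pd.Series(np.nan, index=genes, name="MM")
    for m in eig.columns:
        e = eig[m].to_numpy()
        for g in labels.index[labels == m]:
            mm[g] = abs(np.corrcoef(values.loc[g].to_numpy(), e)[0, 1])

    return ModuleAssignment(labels, eig, trait_corr, gs, mm, merge_trace, dropped)


def common_degs(
    deg: pd.DataFrame,
    modules: ModuleAssignment,
    key_module: str | None = None,
) -> SignaturePanel:
    """Intersect the key (most trait-correlated) module with the DEG calls.

    Directions are inherited from the DEG table; an empty intersection is an
    error suggesting threshold review.
    """
    if key_module is None:
        if modules.trait_correlation.empty:
            raise ValueError("no modules available to choose a key module from")
        key_module = modules.trait_correlation["r"].abs().idxmax()
    if key_module not in modules.modules:
        raise ValueError(f"module {key_module!r} not found")
    module_genes = set(modules.module_genes(key_module))
    called = deg[deg["direction"].isin(["up", "down"])]
    shared = [g for g in called.index if g in module_genes]
    if not shared:
        raise ValueError(
            f"key module {key_module!r} shares no genes with the DEG calls; "
            "review DEG/module thresholds"
        )
    return SignaturePanel(
        [(g, 1 if called.loc[g, "direction"] == "up" else -1) for g in shared]
    )
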