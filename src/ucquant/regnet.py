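"""Multi-dimensional regulatory landscape around the signature panel.

Candidate regulators come in five dimensions — transcription factors,
hallmark signatures, pathway signatures, biochemical reactions and cell
compositions — each filtered by its own dysregulation thresholds.  Retained
components are correlated against panel-gene expression with a
normality-aware choice of coefficient (Pearson when both vectors pass a
Shapiro-Wilk test at alpha = 0.05, Spearman otherwise) and assembled into an
undirected network whose every edge satisfies |r| >= r_min and p < p_max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix

logger = logging.getLogger("ucquant")

__all__ = [
    "DIMENSION_FILTERS",
    "component_dysregulation",
    "filter_components",
    "correlate_components",
    "RegulatoryNetwork",
]

# per-dimension (statistic column, |stat| threshold, FDR threshold)
DIMENSION_FILTERS: dict[str, tuple[str, float, float]] = {
    "TF": ("logFC", 0.5, 0.01),
    "Hallmark": ("t", 2.0, 0.01),
    "Pathway": ("t", 5.0, 0.01),
    "Reactome": ("t", 5.0, 0.01),
    "Cell": ("t", 2.0, 0.01),
}


def component_dysregulation(
    activities: pd.DataFrame,
    groups: pd.Series,
    case_label: str = "case",
    control_label: str = "control",
) -> pd.DataFrame:
    """Welch t / logFC and BH-FDR per component activity row.

    ``activities`` is components x samples (e.g. per-sample gene-set
    activity or TF expression); returns ``t``, ``logFC`` (case - control
    mean) and ``fdr`` per component.
    """
    case = activities.loc[:, (groups == case_label).reindex(activities.columns, fill_value=False)]
    ctrl = activities.loc[:, (groups == control_label).reindex(activities.columns, fill_value=False)]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    fdr = np.full_like(t, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {"t": t, "logFC": case.mean(axis=1) - ctrl.mean(axis=1), "fdr": fdr},
        index=activities.index,
    )


def filter_components(
    tables: dict[str, pd.DataFrame],
    thresholds: dict[str, tuple[str, float, float]] | None = None,
) -> pd.DataFrame:
    """Retain dysregulated components per dimension-specific thresholds.

    ``tables`` maps a dimension name to a frame with the dimension's
    statistic column and an ``fdr`` column.  The statistic test is strict
    (``|stat| > cut``), the FDR test strict below (``fdr < cut``).
    """
    thresholds = thresholds or DIMENSION_FILTERS
    rows = []
    for dim, table in tables.items():
        if dim not in thresholds:
            raise ValueError(f"unknown dimension {dim!r}; known: {sorted(thresholds)}")
        stat_col, stat_cut, fdr_cut = thresholds[dim]
        if stat_col not in table.columns:
            raise ValueError(f"dimension {dim}: missing statistic column {stat_col!r}")
        keep = (table[stat_col].abs() > stat_cut) & (table["fdr"] < fdr_cut)
        sub = table.loc[keep].copy()
        sub["dimension"] = dim
        sub["statistic"] = sub[stat_col]
        sub["stat_threshold"] = stat_cut
        sub["fdr_threshold"] = fdr_cut
        rows.append(sub[["dimension", "statistic", "fdr", "stat_threshold", "fdr_threshold"]])
    if not rows:
        return pd.DataFrame(columns=["dimension", "statistic", "fdr",
                                     "stat_threshold", "fdr_threshold"])
    return pd.concat(rows)


@dataclass
class RegulatoryNetwork:
    nodes: pd.DataFrame   # id, dimension ("panel" for hub genes)
    edges: pd.DataFrame   # source, target, r, p, method

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for _, row in self.nodes.iterrows():
            g.add_node(row["id"], dimension=row["dimension"])
        for _, row in self.edges.iterrows():
            g.add_edge(row["source"], row["target"], r=float(row["r"]),
                       p=float(row["p"]), method=row["method"])
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def correlate_components(
    panel_expr: ExpressionMatrix,
    activities: pd.DataFrame,
    dimensions: pd.Series | None = None,
    r_min: float = 0.5,
    p_max: float = 0.001,
    shapiro_alpha: float = 0.05,
    literal_less_than: bool = False,
    adjust: bool = False,
) -> RegulatoryNetwork:
    """Correlate each panel gene with each retained component activity.

    Pearson is used when both vectors pass Shapiro-Wilk normality at
    ``shapiro_alpha``, Spearman otherwise.  An edge is kept iff
    |r| >= r_min and p < p_max (``literal_less_than`` flips the magnitude
    test to |r| < r_min).  Constant vectors are skipped with a warning;
    ``adjust=True`` applies BH across the whole edge grid before filtering.
    """
    shared = [s for s in panel_expr.sample_ids if s in activities.columns]
    if len(shared) < 4:
        raise ValueError("panel expression and activities share too few samples")
    P = panel_expr.values[shared]
    A = activities[shared]

    normal_cache: dict[tuple[str, str], bool] = {}

    def is_normal(key: str, v: np.ndarray, kind: str) -> bool:
        k = (kind, key)
        if k not in normal_cache:
            normal_cache[k] = bool(stats.shapiro(v).pvalue > shapiro_alpha)
        return normal_cache[k]

    records = []
    for gene in P.index:
        gv = P.loc[gene].to_numpy(dtype=float)
        if gv.std() == 0:
            logger.warning("panel gene %s is constant; skipped", gene)
            continue
        g_norm = is_normal(gene, gv, "gene")
        for comp in A.index:
            cv = A.loc[comp].to_numpy(dtype=float)
            if cv.std() == 0:
                logger.warning("component %s is constant; skipped", comp)
                continue
            if g_norm and is_normal(comp, cv, "comp"):
                r, p = stats.pearsonr(gv, cv)
                method = "pearson"
            else:
                r, p = stats.spearmanr(gv, cv)
                method = "spearman"
            records.append((gene, comp, float(r), float(p), method))

    grid = pd.DataFrame(records, columns=["source", "target", "r", "p", "method"])
    if adjust and len(grid):
        grid["p"] = multipletests(grid["p"], method="fdr_bh")[1]
    if len(grid):
        mag_ok = grid["r"].abs() < r_min if literal_less_than else grid["r"].abs() >= r_min
        edges = grid[mag_ok & (grid["p"] < p_max)].reset_index(drop=True)
    else:
        edges = grid

    dims = dimensions if dimensions is not None else pd.Series("component", index=A.index)
    node_rows = [{"id": g, "dimension": "panel"} for g in P.index]
    node_rows += [{"id": c, "dimension": dims.get(c, "component")}
                  for c in A.index if c in set(edges["target"])]
    return RegulatoryNetwork(pd.DataFrame(node_rows), edges)
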