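"""Dynamic network biomarker (DNB) detection across ordered disease stages.

A DNB is a gene group that, at the critical pre-disease stage, shows (i) a
marked rise in per-gene standard deviation, (ii) elevated mean |Pearson|
correlation within the group, and (iii) reduced mean |Pearson| correlation
between the group and the rest of the transcriptome.  The three criteria
combine into the composite index CI = SD_in x PCC_in / (PCC_out + eps);
the CI of a fixed gene panel traced across stages is its module criticality
index (MCI).  Stages are treated as independent cross-sections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .core import StageSeries

logger = logging.getLogger("ucquant")

__all__ = ["composite_index", "find_dnb", "DNBReport"]


def _drop_constant(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("excluding %d constant genes from correlation terms",
                       int((~keep).sum()))
    return X[keep], [n for n, k in zip(names, keep) if k]


def composite_index(
    module_expr: pd.DataFrame,
    rest_expr: pd.DataFrame,
    epsilon: float = 1e-6,
) -> tuple[float, float, float, float]:
    """(sd_in, pcc_in, pcc_out, ci) for one candidate module at one stage.

    sd_in is the mean per-gene sample SD; pcc_in the mean |Pearson| over
    module gene pairs; pcc_out the mean |Pearson| over module x rest pairs;
    ci = sd_in * pcc_in / (pcc_out + epsilon).  Constant genes are excluded
    from the correlation terms (with a warning) but counted in sd_in.
    """
    if module_expr.shape[0] < 2:
        raise ValueError("module needs at least 2 genes")
    if module_expr.shape[1] < 3:
        raise ValueError("stage needs at least 3 samples")
    M = module_expr.to_numpy(dtype=float)
    sd_in = float(M.std(axis=1, ddof=1).mean())

    Mc, _ = _drop_constant(M, list(module_expr.index))
    if Mc.shape[0] >= 2:
        cm = np.corrcoef(Mc)
        iu = np.triu_indices(Mc.shape[0], k=1)
        pcc_in = float(np.abs(cm[iu]).mean())
    else:
        pcc_in = float("nan")

    R = rest_expr.to_numpy(dtype=float)
    Rc, _ = _drop_constant(R, list(rest_expr.index)) if R.size else (R, [])
    if Mc.shape[0] >= 1 and Rc.shape[0] >= 1:
        both = np.corrcoef(np.vstack([Mc, Rc]))
        cross = both[: Mc.shape[0], Mc.shape[0]:]
        pcc_out = float(np.abs(cross).mean())
    else:
        pcc_out = float("nan")

    ci = sd_in * pcc_in / (pcc_out + epsilon) if np.isfinite(pcc_in) and np.isfinite(pcc_out) else float("nan")
    return sd_in, pcc_in, pcc_out, ci


def _stage_candidates(values: pd.DataFrame, min_size: int, cut_height: float) -> list[list[str]]:
    """Candidate modules by average-linkage clustering of 1 - |Pearson|.

    If the distance cut yields no cluster of the required size (as in pure
    noise), fall back to a fixed-count cut so downstream calibration still
    sees candidates.
    """
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    X = X[sd > 0]
    names = [g for g, s in zip(values.index, sd) if s > 0]
    if len(names) < min_size:
        return []
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - np.abs(corr), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform((dist + dist.T) / 2, checks=False))

    labels = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    clusters = [
        [n for n, l in zip(names, labels) if l == c]
        for c in sizes.index if sizes[c] >= min_size
    ]
    if not clusters:
        k = max(2, len(names) // (2 * min_size))
        labels = fcluster(Z, t=k, criterion="maxclust")
        sizes = pd.Series(labels).value_counts()
        clusters = [
            [n for n, l in zip(names, labels) if l == c]
            for c in sizes.index if sizes[c] >= min_size
        ]
    return clusters


@dataclass
class DNBReport:
    """Per-stage criticality table, the selected DNB and panel trajectories."""

    table: pd.DataFrame            # rows: (stage, module); sd_in, pcc_in, pcc_out, ci
    dnb_genes: list[str]
    peak_stage: str
    stage_scores: pd.Series        # per-stage mean CI of the top modules
    mci: pd.DataFrame              # provided panels x stages CI trajectories


def find_dnb(
    series: StageSeries,
    panels: dict[str, list[str]] | None = None,
    min_size: int = 10,
    cut_height: float = 0.7,
    epsilon: float = 1e-6,
    top_fraction: float = 0.1,
) -> DNBReport:
    """Search candidate modules for the stage with the strongest criticality.

    Candidates are clustered per stage (pooled across stages), the composite
    index of every candidate is evaluated at every stage, and the DNB is the
    candidate with the global maximum CI; its argmax stage is the predicted
    critical (pre-disease) stage.  The per-stage DNB score averages the CI
    of the top ``top_fraction`` of candidates; ``panels`` adds fixed gene
    groups whose CI trajectory across stages (the MCI) is reported as given.
    """
    if len(series.stages) < 2:
        raise ValueError("need at least 2 stages")
    usable = [s for s in series.stages if series.matrices[s].n_samples >= 3]
    skipped = set(series.stages) - set(usable)
    if skipped:
        logger.warning("skipping stages with <3 samples: %s", sorted(skipped))

    candidates: dict[str, list[str]] = {}
    for stage in usable:
        for i, genes in enumerate(_stage_candidates(series.matrices[stage].values,
                                                    min_size, cut_height)):
            candidates[f"{stage}_m{i}"] = genes
    if not candidates:
        raise ValueError("no candidate modules found at any stage")

    rows = []
    ci_grid = pd.DataFrame(index=sorted(candidates), columns=usable, dtype=float)
    for stage in usable:
        values = series.matrices[stage].values
        for mod_name in sorted(candidates):
            genes = candidates[mod_name]
            rest = values.drop(index=[g for g in genes if g in values.index])
            sd_in, pcc_in, pcc_out, ci = composite_index(
                values.loc[genes], rest, epsilon=epsilon
            )
            ci_grid.loc[mod_name, stage] = ci
            rows.append({"stage": stage, "module": mod_name, "n_genes": len(genes),
                         "sd_in": sd_in, "pcc_in": pcc_in, "pcc_out": pcc_out, "ci": ci})
    table = pd.DataFrame(rows).set_index(["stage", "module"])

    best_module = ci_grid.max(axis=1).idxmax()
    peak_stage = str(ci_grid.loc[best_module].idxmax())
    dnb_genes = candidates[best_module]

    n_top = max(1, int(np.ceil(top_fraction * ci_grid.shape[0])))
    stage_scores = ci_grid.apply(lambda col: col.nlargest(n_top).mean(), axis=0)
    stage_scores.name = "dnb_score"

    mci_rows = {}
    for name, genes in (panels or {}).items():
        traj = {}
        for stage in usable:
            values = series.matrices[stage].values
            present = [g for g in genes if g in values.index]
            rest = values.drop(index=present)
            traj[stage] = composite_index(values.loc[present], rest, epsilon=epsilon)[3]
        mci_rows[name] = traj
    mci = pd.DataFrame(mci_rows).T if mci_rows else pd.DataFrame(columns=usable)

    return DNBReport(table, dnb_genes, peak_stage, stage_scores, mci)
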