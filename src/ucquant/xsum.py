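"""eXtreme-Sum signature matching against a drug-perturbation library.

Each drug profile is truncated to its most extreme values (top and bottom
``extreme_n``; everything else treated as 0); the score sums the truncated
values over the disease up-genes minus the sum over the down-genes, so a
strongly negative score marks a compound whose perturbation opposes the
disease signature (a reversal candidate).  Significance comes from a
randomization null of size-matched random gene-label signatures, one-sided
toward reversal, and drugs are ranked ascending by score (rank 1 = best
reverser).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import DrugSignatureLibrary, SignaturePanel, substream

logger = logging.getLogger("ucquant")

__all__ = ["DiseaseSignature", "extreme_truncate", "xsum_score", "permutation_significance"]


class DiseaseSignature:
    """Disjoint up- and down-regulated disease gene lists."""

    def __init__(self, up_genes, down_genes):
        self.up_genes = list(up_genes)
        self.down_genes = list(down_genes)
        if not self.up_genes or not self.down_genes:
            raise ValueError("both up_genes and down_genes must be non-empty")
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene lists must be disjoint")

    @classmethod
    def from_panel(cls, panel: SignaturePanel) -> "DiseaseSignature":
        return cls(panel.up_genes, panel.down_genes)


def extreme_truncate(profile: pd.Series, extreme_n: int) -> pd.Series:
    """Keep only the ``extreme_n`` highest and lowest profile values.

    All other genes are set to 0.  Ties at either cut break by stable input
    gene order, so the result is deterministic.
    """
    if extreme_n <= 0:
        raise ValueError("extreme_n must be positive")
    if extreme_n > len(profile) // 2:
        raise ValueError("extreme_n exceeds half the profile length")
    values = profile.to_numpy(dtype=float)
    keep = np.zeros(len(values), dtype=bool)
    keep[np.argsort(values, kind="stable")[:extreme_n]] = True   # lowest, first of ties
    keep[np.argsort(-values, kind="stable")[:extreme_n]] = True  # highest, first of ties
    out = np.where(keep, values, 0.0)
    return pd.Series(out, index=profile.index)


def xsum_score(
    sig: DiseaseSignature,
    truncated: pd.Series,
    mode: str = "difference",
) -> tuple[float, float, float]:
    """(sum_up, sum_down, score) of a truncated drug profile vs a signature.

    sum_up/sum_down sum the truncated values over the disease up/down
    genes (absent genes ignored, counted).  Default ``difference`` scoring
    is sum_up - sum_down, so a drug that represses the disease's up-genes
    and induces its down-genes scores strongly negative; the ``literal_sum``
    variant returns sum_up + sum_down.
    """
    if mode not in ("difference", "literal_sum"):
        raise ValueError(f"unknown mode {mode!r}")
    universe = set(truncated.index)
    up = [g for g in sig.up_genes if g in universe]
    down = [g for g in sig.down_genes if g in universe]
    absent = (len(sig.up_genes) - len(up)) + (len(sig.down_genes) - len(down))
    if not up and not down:
        raise ValueError("signature has zero overlap with the drug profile universe")
    if absent:
        logger.info("%d signature genes absent from the profile universe", absent)
    sum_up = float(truncated[up].sum())
    sum_down = float(truncated[down].sum())
    score = sum_up - sum_down if mode == "difference" else sum_up + sum_down
    return sum_up, sum_down, score


def permutation_significance(
    sig: DiseaseSignature,
    library: DrugSignatureLibrary,
    extreme_n: int = 500,
    n_perm: int = 999,
    seed: int = 0,
    mode: str = "difference",
) -> pd.DataFrame:
    """Score every drug and attach a randomization P-value and rank.

    The null per drug uses random gene-label signatures of matched up/down
    sizes drawn from the profile universe; P is one-sided toward reversal,
    p = (1 + #{null <= observed}) / (n_perm + 1).  Drugs are ranked
    ascending by score: rank 1 is the most negative (strongest reverser).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    genes = library.gene_ids
    n_up = len([g for g in sig.up_genes if g in set(genes)])
    n_down = len([g for g in sig.down_genes if g in set(genes)])

    T = np.vstack([
        extreme_truncate(library.values.loc[drug], extreme_n).to_numpy()
        for drug in library.drug_ids
    ])  # drugs x genes

    rows = {}
    for i, drug in enumerate(library.drug_ids):
        su, sd, sc = xsum_score(sig, pd.Series(T[i], index=genes), mode=mode)
        rows[drug] = {"sum_up": su, "sum_down": sd, "xsum_score": sc}
    result = pd.DataFrame(rows).T

    rng = substream(seed, "xsum_permutation")
    n_genes = len(genes)
    null_counts = np.zeros(len(library.drug_ids))
    obs = result["xsum_score"].to_numpy()
    down_sign = -1.0 if mode == "difference" else 1.0
    for _ in range(n_perm):
        pick = rng.choice(n_genes, size=n_up + n_down, replace=False)
        up_idx, down_idx = pick[:n_up], pick[n_up:]
        null = T[:, up_idx].sum(axis=1) + down_sign * T[:, down_idx].sum(axis=1)
        null_counts += null <= obs
    result["permutation_p"] = (1 + null_counts) / (n_perm + 1)
    result["rank"] = result["xsum_score"].rank(method="first").astype(int)
    return result.sort_values("rank")
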