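"""Synthetic data generators mirroring the statistical structure of the
cohorts the pipeline targets.

Four generators cover the whole pipeline: multi-cohort case/control matrices
with planted differentially expressed genes, co-expression blocks and
additive batch shifts; a three-stage cross-sectional series with a planted
dynamic-network-biomarker group at one stage; a drug-perturbation library
with a planted signature reverser and mimic; and a sparse cell-by-gene
matrix with a planted "active" cell population for rank-based set scoring.

Noise is Gaussian on the log2 scale — the emulated cohorts are normalized
microarrays, already continuous — and batch effects are additive per cohort.
Every generator returns a first-class truth record so downstream tests never
re-derive ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DrugSignatureLibrary,
    ExpressionMatrix,
    SignaturePanel,
    StageSeries,
    substream,
)

__all__ = [
    "SimSpec",
    "simulate_cohorts",
    "simulate_stage_series",
    "simulate_drug_library",
    "simulate_cells",
]


@dataclass
class SimSpec:
    """Parameters of the multi-cohort case/control generator.

    Defaults give a single 40 case / 40 control cohort of 2000 genes with 30
    up- and 30 down-regulated genes at a mean log2 fold change of 2 over
    per-gene Gaussian noise of SD 0.5 — comfortably detectable effects of
    the size the emulated disease cohorts show for their top markers.
    """

    n_genes: int = 2000
    n_case: int = 40
    n_control: int = 40
    n_up: int = 30
    n_down: int = 30
    effect_lfc: float = 2.0
    noise_sd: float = 0.5
    n_cohorts: int = 1
    batch_sd: float = 0.2
    module_spec: list[tuple[int, float]] = field(default_factory=list)
    plant_in_blocks: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down exceeds n_genes")
        if self.effect_lfc < 0:
            raise ValueError("effect_lfc must be non-negative")
        for size, rho in self.module_spec:
            if not 0 <= rho < 1:
                raise ValueError("intra-block correlation must lie in [0, 1)")
        if sum(s for s, _ in self.module_spec) > self.n_genes:
            raise ValueError("block sizes exceed n_genes")
        if self.plant_in_blocks and self.module_spec:
            if self.n_up + self.n_down > sum(s for s, _ in self.module_spec):
                raise ValueError("planted DEGs do not fit inside the blocks")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_cohorts(spec: SimSpec) -> list[tuple[ExpressionMatrix, dict]]:
    """Generate ``spec.n_cohorts`` case/control matrices with shared truth.

    Baseline per-gene means are log-normal on the log2 scale; planted up/down
    genes are shifted by +/- ``effect_lfc`` in cases; co-expression blocks
    share a latent factor with loading sqrt(rho); each cohort receives one
    additive batch shift ~ N(0, batch_sd).
    """
    rng = substream(spec.seed, "simulate_cohorts")
    genes = _gene_names(spec.n_genes)

    # co-expression blocks occupy the leading genes
    blocks: list[list[str]] = []
    start = 0
    for size, _ in spec.module_spec:
        blocks.append(genes[start:start + size])
        start += size

    pool = [g for b in blocks for g in b] if spec.plant_in_blocks and blocks else genes
    planted = rng.choice(pool, size=spec.n_up + spec.n_down, replace=False)
    up_genes = sorted(planted[: spec.n_up])
    down_genes = sorted(planted[spec.n_up:])

    base_means = rng.lognormal(mean=2.0, sigma=0.35, size=spec.n_genes)
    direction = pd.Series(0.0, index=genes)
    direction[up_genes] = 1.0
    direction[down_genes] = -1.0

    truth = {
        "up_genes": up_genes,
        "down_genes": down_genes,
        "blocks": [list(b) for b in blocks],
        "batch_shifts": [],
    }

    cohorts = []
    for c in range(spec.n_cohorts):
        n = spec.n_case + spec.n_control
        eps = rng.normal(size=(spec.n_genes, n))
        noise = eps.copy()
        for (size, rho), block in zip(spec.module_spec, blocks):
            if rho > 0:
                f = rng.normal(size=n)
                idx = [genes.index(g) for g in block]
                noise[idx, :] = np.sqrt(rho) * f + np.sqrt(1 - rho) * eps[idx, :]
        X = base_means[:, None] + spec.noise_sd * noise
        # cases shifted by the planted effect
        X[:, : spec.n_case] += spec.effect_lfc * direction.to_numpy()[:, None]
        shift = float(rng.normal(0.0, spec.batch_sd)) if spec.batch_sd > 0 else 0.0
        X += shift
        truth["batch_shifts"].append(shift)

        samples = [f"C{c}S{i:03d}" for i in range(n)]
        ann = pd.DataFrame(
            {
                "group": ["case"] * spec.n_case + ["control"] * spec.n_control,
                "cohort": f"cohort{c}",
            },
            index=samples,
        )
        cohorts.append((ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples), ann), truth))
    return cohorts


def simulate_stage_series(
    n_genes: int = 200,
    dnb_size: int = 20,
    stages: tuple[str, ...] = ("Normal", "Inactive", "Active"),
    perturbed_stage: str = "Inactive",
    n_per_stage: int = 30,
    sd_scale: float = 3.0,
    rin_in: float = 0.8,
    rout: float = 0.05,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[StageSeries, dict]:
    """Cross-sectional stage series with a planted critical-transition group.

    At ``perturbed_stage`` only, a ``dnb_size``-gene group has its SD
    inflated by ``sd_scale``, intra-group correlation ``rin_in`` and
    correlation to the remaining genes shrunk toward ``rout``; all other
    stages are homogeneous noise.  Emulates the pre-disease criticality
    pattern of a normal -> inactive -> active colitis course.
    """
    if dnb_size > n_genes:
        raise ValueError("dnb_size exceeds n_genes")
    if perturbed_stage not in stages:
        raise ValueError(f"perturbed_stage {perturbed_stage!r} not in stages {stages}")
    if sd_scale < 1:
        raise ValueError("sd_scale must be >= 1")
    if rout > rin_in:
        raise ValueError("rout must not exceed rin_in")

    rng = substream(seed, "simulate_stage_series")
    genes = _gene_names(n_genes)
    group = genes[:dnb_size]
    base_means = rng.lognormal(mean=2.0, sigma=0.35, size=n_genes)

    matrices = {}
    for stage in stages:
        eps = rng.normal(size=(n_genes, n_per_stage))
        if stage == perturbed_stage:
            f = rng.normal(size=n_per_stage)
            lam_in = np.sqrt(rin_in)
            # rest genes get a small shared loading so group<->rest correlation ~ rout
            lam_out = min(1.0, rout / lam_in) if lam_in > 0 else 0.0
            noise = np.empty_like(eps)
            noise[:dnb_size] = sd_scale * (lam_in * f + np.sqrt(1 - rin_in) * eps[:dnb_size])
            noise[dnb_size:] = lam_out * f + np.sqrt(1 - lam_out**2) * eps[dnb_size:]
        else:
            noise = eps
        X = base_means[:, None] + noise_sd * noise
        samples = [f"{stage}_{i:03d}" for i in range(n_per_stage)]
        ann = pd.DataFrame({"group": stage, "stage": stage}, index=samples)
        matrices[stage] = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples), ann)

    truth = {"dnb_genes": list(group), "perturbed_stage": perturbed_stage}
    return StageSeries(list(stages), matrices), truth


def simulate_drug_library(
    n_drugs: int = 20,
    disease_panel: SignaturePanel | None = None,
    reversal_strength: float = 3.0,
    n_genes: int = 1000,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[DrugSignatureLibrary, dict]:
    """Drug x gene perturbation library with one planted reverser and mimic.

    All drugs are Gaussian noise; the reverser scores ``-reversal_strength x
    direction`` on every panel gene (opposing the disease signature) and the
    mimic ``+reversal_strength x direction``.
    """
    if n_drugs < 3:
        raise ValueError("need at least 3 drugs (reverser, mimic, background)")
    rng = substream(seed, "simulate_drug_library")

    if disease_panel is None:
        genes = _gene_names(n_genes)
        disease_panel = SignaturePanel(
            [(g, 1) for g in genes[:6]] + [(g, -1) for g in genes[6:12]]
        )
    else:
        extra = [g for g in _gene_names(n_genes) if g not in set(disease_panel.genes)]
        genes = list(disease_panel.genes) + extra[: max(0, n_genes - len(disease_panel))]

    drugs = [f"DRUG{i:03d}" for i in range(n_drugs)]
    values = rng.normal(0.0, noise_sd, size=(n_drugs, len(genes)))
    df = pd.DataFrame(values, index=drugs, columns=genes)

    reverser, mimic = drugs[0], drugs[1]
    for g, d in disease_panel.entries:
        df.loc[reverser, g] = -reversal_strength * d
        df.loc[mimic, g] = reversal_strength * d

    truth = {"reverser": reverser, "mimic": mimic, "panel": disease_panel.entries}
    return DrugSignatureLibrary(df), truth


def simulate_cells(
    n_genes: int = 500,
    n_cells: int = 300,
    panel: SignaturePanel | None = None,
    active_fraction: float = 0.3,
    boost: float = 4.0,
    dropout: float = 0.6,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict]:
    """Sparse cell-by-gene matrix with a planted panel-active population.

    Baseline expression is log-normal thinned by Bernoulli dropout; in the
    active cells the panel's up-genes are boosted so they dominate the
    per-cell expression ranking, the pattern rank-based set scoring detects.
    """
    rng = substream(seed, "simulate_cells")
    genes = _gene_names(n_genes)
    if panel is None:
        panel = SignaturePanel([(g, 1) for g in genes[:20]])
    n_active = int(round(active_fraction * n_cells))

    X = rng.lognormal(mean=0.5, sigma=1.0, size=(n_genes, n_cells))
    X *= rng.random(size=X.shape) > dropout
    up_idx = [genes.index(g) for g in panel.up_genes]
    X[np.ix_(up_idx, range(n_active))] += boost * rng.lognormal(0.5, 0.5, size=(len(up_idx), n_active))

    cells = [f"CELL{i:04d}" for i in range(n_cells)]
    ann = pd.DataFrame(
        {"group": ["active"] * n_active + ["background"] * (n_cells - n_active)},
        index=cells,
    )
    expr = ExpressionMatrix(pd.DataFrame(np.log2(X + 1), index=genes, columns=cells), ann)
    truth = {"active_cells": cells[:n_active], "panel": panel.entries}
    return expr, truth
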