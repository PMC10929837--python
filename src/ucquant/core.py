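"""Core in-memory containers shared by every stage of the pipeline.

The pipeline operates on log2-scale gene-by-sample expression matrices with
per-sample annotations (``group``: control/case; optional ``stage`` and
``cohort``), directional gene signatures, named gene sets, drug-perturbation
libraries and stage-ordered expression series.  All containers validate their
invariants on construction so downstream stages can assume clean input.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ucquant")

__all__ = [
    "ExpressionMatrix",
    "SignaturePanel",
    "GeneSetCollection",
    "DrugSignatureLibrary",
    "StageSeries",
    "RunConfig",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from a single run seed.

    Every module draws randomness from its own substream so any stage can be
    re-run in isolation without replaying the whole pipeline.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode()) & 0x7FFFFFFF])
    )


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    if len(ids) != len(set(ids)):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample annotations.

    ``values`` is a DataFrame indexed by gene ID with sample IDs as columns;
    ``annotations`` is indexed by sample ID and carries at least a ``group``
    column plus optional ``stage`` and ``cohort``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene IDs")
        _check_unique(self.values.columns, "sample IDs")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite with no missing entries")
        missing = [s for s in self.values.columns if s not in self.annotations.index]
        if missing:
            raise ValueError(f"samples absent from annotations: {missing}")
        self.annotations = self.annotations.loc[self.values.columns]

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> pd.Series:
        return self.annotations["group"]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.annotations.copy())

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.annotations.loc[list(samples)])

    def split_by_group(self) -> dict[str, "ExpressionMatrix"]:
        return {
            g: self.subset_samples(list(self.annotations.index[self.groups == g]))
            for g in self.groups.unique()
        }


@dataclass
class SignaturePanel:
    """Ordered gene signature with an up (+1) / down (-1) direction per gene."""

    entries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        _check_unique((g for g, _ in self.entries), "panel gene IDs")
        bad = [(g, d) for g, d in self.entries if d not in (1, -1)]
        if bad:
            raise ValueError(f"directions must be +1 or -1, got {bad}")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def up_genes(self) -> list[str]:
        return [g for g, d in self.entries if d == 1]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, d in self.entries if d == -1]

    @property
    def directions(self) -> pd.Series:
        return pd.Series({g: d for g, d in self.entries}, dtype=int)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene", "direction"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignaturePanel":
        return cls([(str(g), int(d)) for g, d in zip(df["gene"], df["direction"])])


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. hallmark, pathway or cell-type signatures)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class DrugSignatureLibrary:
    """Drug x gene signed perturbation scores (positive = induced)."""

    values: pd.DataFrame  # drugs x genes

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "drug IDs")
        _check_unique(self.values.columns, "gene IDs")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("drug signature values must be finite")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class StageSeries:
    """Expression matrices keyed by ordered disease-stage labels.

    Emulates a cross-sectional time course (e.g. normal -> inactive -> active
    colitis); all stages share one gene universe and stage order is explicit.
    """

    stages: list[str]
    matrices: dict[str, ExpressionMatrix]

    def __post_init__(self) -> None:
        if set(self.stages) != set(self.matrices):
            raise ValueError("stage labels and matrix keys differ")
        universe = self.matrices[self.stages[0]].gene_ids
        for s in self.stages[1:]:
            if self.matrices[s].gene_ids != universe:
                raise ValueError(f"stage {s!r} has a different gene universe")
        small = [s for s in self.stages if self.matrices[s].n_samples < 3]
        if small:
            logger.warning("stages with <3 samples: %s", small)

    @property
    def gene_ids(self) -> list[str]:
        return self.matrices[self.stages[0]].gene_ids


@dataclass
class RunConfig:
    """All tunable thresholds and sizes of the pipeline, plus the run seed.

    Defaults follow the study design this pipeline models: DEGs at raw
    P < 0.05 and |log2FC| > 1; WGCNA-style network with soft power 14,
    minimum module size 50 and merge cut height 0.25; random forests of 250
    trees; network edges at |r| >= 0.5 and P < 0.001; component filters per
    dimension (TF |logFC| > 0.5, hallmark/cell |t| > 2, pathway/reaction
    |t| > 5, all at FDR < 0.01).
    """

    # differential expression
    deg_p: float = 0.05
    deg_abs_lfc: float = 1.0
    # regulatory network edges
    net_abs_r: float = 0.5
    net_p: float = 0.001
    # component dysregulation filters
    tf_abs_lfc: float = 0.5
    tf_fdr: float = 0.01
    hallmark_abs_t: float = 2.0
    pathway_abs_t: float = 5.0
    reactome_abs_t: float = 5.0
    cells_abs_t: float = 2.0
    component_fdr: float = 0.01
    # WGCNA-style module detection
    beta: float = 14.0
    min_module_size: int = 50
    merge_cut_height: float = 0.25
    top_n_variable: int = 5000
    # machine learning
    folds: int = 10
    repeats: int = 10
    rf_trees: int = 250
    train_fraction: float = 0.7
    panel_size: int = 12
    # drug reversion
    extreme_n: int = 500
    n_permutations: int = 999
    # input handling
    log2_input: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "deg_p", "deg_abs_lfc", "net_abs_r", "net_p", "tf_abs_lfc", "tf_fdr",
            "hallmark_abs_t", "pathway_abs_t", "reactome_abs_t", "cells_abs_t",
            "component_fdr", "beta", "merge_cut_height",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"# config_hash={self.config_hash()}", f"# seed={self.seed}"]

    def rng(self, name: str) -> np.random.Generator:
        return substream(self.seed, name)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
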