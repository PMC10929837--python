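"""Readers and writers for the on-disk formats of the pipeline.

Expression matrices are tab-delimited (first column gene ID, header = sample
IDs) with a separate sample annotation table; gene sets use the standard GMT
layout; drug libraries are drug x gene TSVs.  All writers prepend ``#``
comment lines recording the config hash and seed so outputs are traceable.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    DrugSignatureLibrary,
    ExpressionMatrix,
    GeneSetCollection,
    RunConfig,
    SignaturePanel,
)

logger = logging.getLogger("ucquant")

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_drug_library",
    "write_drug_library",
    "read_panel",
    "write_panel",
    "write_table",
]


def read_expression(
    path,
    annotation_path,
    log2_input: bool = True,
) -> ExpressionMatrix:
    """Load a gene-by-sample expression matrix plus its sample annotations.

    Rows with any missing value are dropped (and counted); duplicate gene
    rows (e.g. multiple probes for one symbol) are collapsed by averaging.
    With ``log2_input=False`` a log2(x+1) transform is applied on load.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, comment="#")

    n_missing = int(raw.isna().any(axis=1).sum())
    if n_missing:
        logger.info("dropping %d gene rows with missing values", n_missing)
        raw = raw.dropna(axis=0)

    n_dup = int(raw.index.duplicated().sum())
    if n_dup:
        logger.info("collapsing %d duplicate gene rows by mean", n_dup)
        raw = raw.groupby(level=0, sort=False).mean()

    orphans = [s for s in raw.columns if s not in ann.index]
    if orphans:
        raise ValueError(f"samples missing from annotation table: {orphans}")

    values = raw.astype(float)
    values.index.name = None
    values.columns.name = None
    if not log2_input:
        if (values.to_numpy() < 0).any():
            raise ValueError("negative values are incompatible with log2(x+1) input transform")
        values = np.log2(values + 1.0)
    return ExpressionMatrix(values, ann.loc[values.columns])


def write_expression(expr: ExpressionMatrix, path, annotation_path=None,
                     config: Optional[RunConfig] = None) -> None:
    _write_with_header(expr.values, path, config, index_label="gene")
    if annotation_path is not None:
        _write_with_header(expr.annotations, annotation_path, config, index_label="sample")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name / description / genes...

    Duplicate genes within a set are removed (order preserved); a repeated
    set name or a line with fewer than three fields is an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(g for g in fields[2:] if g))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_drug_library(path) -> DrugSignatureLibrary:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#").astype(float)
    return DrugSignatureLibrary(df)


def write_drug_library(lib: DrugSignatureLibrary, path,
                       config: Optional[RunConfig] = None) -> None:
    _write_with_header(lib.values, path, config, index_label="drug")


def read_panel(path) -> SignaturePanel:
    df = pd.read_csv(path, sep="\t", comment="#")
    return SignaturePanel.from_frame(df)


def write_panel(panel: SignaturePanel, path, config: Optional[RunConfig] = None) -> None:
    _write_with_header(panel.to_frame(), path, config, index=False)


def write_table(df: pd.DataFrame, path, config: Optional[RunConfig] = None, **to_csv_kwargs) -> None:
    """Write any result table as TSV with the standard comment header."""
    _write_with_header(df, path, config, **to_csv_kwargs)


def _write_with_header(df: pd.DataFrame, path, config: Optional[RunConfig],
                       index: bool = True, index_label=None) -> None:
    with open(path, "w") as fh:
        for line in (config.header_lines() if config is not None else []):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)
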