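"""Input/output: expression matrices with sample annotations, packaged
panel fixtures, target-source tables and GMT gene-set collections."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt as _read_gmt

REQUIRED_CELL_LINE_KEYS = ("cell_line", "condition")
REQUIRED_COHORT_KEYS = ("tissue",)

CONDITIONS = ("parental", "exposed")
TISSUES = ("tumor", "normal")


@dataclass
class ExpressionMatrix:
    """A miRNA-by-sample non-negative intensity table with annotations.

    values : DataFrame, rows = miRNA identifiers, columns = sample ids.
    annotations : DataFrame indexed by sample id.  Paired cell-line designs
        carry ``cell_line`` and ``condition`` in {parental, exposed}; cohort
        designs carry ``tissue`` in {tumor, normal} and optionally
        ``purity`` in (0, 1].
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifiers: {dups}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression intensities must be non-negative")
        missing = self.values.columns.difference(self.annotations.index)
        if len(missing):
            raise ValueError(f"samples lacking annotations: {missing.tolist()}")
        self.annotations = self.annotations.loc[self.values.columns]
        if "purity" in self.annotations:
            p = self.annotations["purity"].dropna()
            if ((p <= 0) | (p > 1)).any():
                raise ValueError("purity must lie in (0, 1]")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_where(self, **criteria) -> list[str]:
        """Sample ids whose annotations match all keyword criteria."""
        mask = pd.Series(True, index=self.annotations.index)
        for key, val in criteria.items():
            if key not in self.annotations:
                raise KeyError(f"annotation key {key!r} not present")
            mask &= self.annotations[key] == val
        return self.annotations.index[mask].tolist()


def read_expression(
    expression_tsv: str | Path, annotation_tsv: str | Path
) -> ExpressionMatrix:
    """Read an expression TSV (rows = miRNAs) plus its annotation sidecar."""
    values = pd.read_csv(expression_tsv, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_tsv, sep="\t", index_col=0)
    return ExpressionMatrix(values, ann)


def write_expression(
    m: ExpressionMatrix, expression_tsv: str | Path, annotation_tsv: str | Path
) -> None:
    m.values.to_csv(expression_tsv, sep="\t", index_label="mirna")
    m.annotations.to_csv(annotation_tsv, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Packaged panel fixtures (published OncomiR / TSmiR tables)

PANEL_COLUMNS = ["mirna", "tn_fr", "p", "oec_fc", "sas_fc", "avg_fc"]


def _data_path(name: str):
    return importlib.resources.files("arecamir.data").joinpath(name)


def load_panel_table(which: str) -> pd.DataFrame:
    """Load a packaged panel fixture.

    Parameters
    ----------
    which : {"oncomir", "tsmir"}
        ``oncomir``: tumor/normal-overexpressed miRNAs up-regulated under
        areca nut exposure (per-line FCs in ratio dialect).
        ``tsmir``: tumor-suppressive miRNAs, printed in signed dialect.
    """
    names = {"oncomir": "table1_oncomirs.tsv", "tsmir": "table2_tsmirs.tsv"}
    if which not in names:
        raise ValueError(f"which must be one of {sorted(names)}, got {which!r}")
    with importlib.resources.as_file(_data_path(names[which])) as path:
        df = pd.read_csv(path, sep="\t", dtype={"p": str})
    if list(df.columns) != PANEL_COLUMNS:
        raise ValueError(f"malformed panel fixture {names[which]}")
    # p kept verbatim (report round-trips); p_value is the numeric view
    df["p_value"] = df["p"].astype(float)
    df["dialect"] = "ratio" if which == "oncomir" else "signed"
    return df


# ---------------------------------------------------------------------------
# Target-assertion tables and GMT collections

EVIDENCE_CLASSES = ("validated", "predicted")


def read_target_table(path: str | Path) -> pd.DataFrame:
    """Read one miRNA→gene source table (source, mirna, gene, evidence)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source", "mirna", "gene", "evidence"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    bad = set(df["evidence"].unique()) - set(EVIDENCE_CLASSES)
    if bad:
        raise ValueError(f"{path}: unknown evidence tag(s) {sorted(bad)}")
    return df


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection as {pathway name: gene list}."""
    return _read_gmt(str(path))


def write_gmt(gene_sets: Mapping[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name, *genes]) + "\n")


def geometric_mean(values: np.ndarray | pd.DataFrame, axis: int = 1):
    """Geometric mean along an axis; inputs must be strictly positive."""
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return np.exp(np.log(arr).mean(axis=axis))
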