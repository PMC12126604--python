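"""Protein-group matrix parsing, log2 transform, per-fibre counts and PCA QC.

The quantification input is a DIA search "PG matrix": a tab-separated table
with protein-group metadata columns followed by one column of label-free
quantification (LFQ) intensities per run (here, per single myofibre).  Blank
cells and zeros mean "not quantified in this run" — zeros are censored
values, not measured zeros, in label-free DIA data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import FormatError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinMatrix",
    "QcReport",
    "read_pg_matrix",
    "log2_transform",
    "protein_counts",
    "pca_outliers",
    "write_pg_matrix",
    "PG_META_COLUMNS",
]

#: Metadata columns recognised in a DIA-NN style PG matrix header.
PG_META_COLUMNS = (
    "Protein.Group",
    "Protein.Ids",
    "Protein.Names",
    "Genes",
    "First.Protein.Description",
)


@dataclass
class ProteinMatrix:
    """Protein-groups x fibres intensity matrix plus per-fibre annotations.

    ``values`` is indexed by protein-group id with one column per fibre;
    missing quantifications are NaN.  ``scale`` records whether values are raw
    LFQ intensities or log2-transformed.  ``annotations`` is indexed by fibre
    id and carries at least ``participant`` and ``condition``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    genes: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError("duplicate protein ids in matrix")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate fibre ids in matrix")
        if self.scale not in ("raw", "log2"):
            raise FormatError(f"unknown scale {self.scale!r}")
        unknown = self.annotations.index.difference(self.values.columns)
        if len(unknown):
            raise FormatError(
                f"annotated fibres absent from matrix: {list(unknown)[:5]}"
            )
        self.genes = self.genes.reindex(self.values.index)

    @property
    def fibres(self) -> list[str]:
        return list(self.values.columns)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    def subset(
        self,
        proteins: Iterable[str] | None = None,
        fibres: Iterable[str] | None = None,
    ) -> "ProteinMatrix":
        vals = self.values
        if proteins is not None:
            vals = vals.loc[list(proteins)]
        if fibres is not None:
            vals = vals[list(fibres)]
        annot = self.annotations.loc[self.annotations.index.intersection(vals.columns)]
        return ProteinMatrix(
            values=vals.copy(),
            annotations=annot.copy(),
            genes=self.genes.reindex(vals.index),
            scale=self.scale,
        )


@dataclass(frozen=True)
class QcReport:
    """Per-fibre protein counts, PC1/PC2 coordinates and outlier flags."""

    counts: pd.Series
    coords: pd.DataFrame
    outliers: list[str]
    n_complete_proteins: int


def _dedupe_ids(ids: pd.Series) -> pd.Index:
    """Disambiguate duplicate protein-group ids deterministically (id, id_dup1, ...)."""
    seen: dict[str, int] = {}
    out = []
    for pid in ids.astype(str):
        if pid in seen:
            seen[pid] += 1
            new = f"{pid}_dup{seen[pid]}"
            logger.warning("duplicate protein-group id %r renamed to %r", pid, new)
            out.append(new)
        else:
            seen[pid] = 0
            out.append(pid)
    return pd.Index(out, name="protein")


def read_pg_matrix(path, annotation_path) -> ProteinMatrix:
    """Parse a PG-matrix TSV and a fibre annotation CSV into a ProteinMatrix.

    Run columns are matched to annotation fibre ids; unmatched runs are
    excluded with a warning.  Zeros and blanks are treated as missing.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    run_cols = [c for c in header if c not in PG_META_COLUMNS]
    if not run_cols:
        raise FormatError("PG matrix has no run columns")
    dup = pd.Index(header)[pd.Index(header).duplicated()]
    if len(dup):
        raise FormatError(f"duplicate fibre columns in PG matrix: {list(dup)}")

    df = pd.read_csv(path, sep="\t")
    id_col = "Protein.Group" if "Protein.Group" in df.columns else None
    if id_col is None:
        raise FormatError("PG matrix lacks a Protein.Group column")
    index = _dedupe_ids(df[id_col])
    genes = pd.Series(
        df["Genes"].astype(str).to_numpy() if "Genes" in df.columns else index,
        index=index,
        name="gene",
    )
    values = df[run_cols].astype(float)
    values.index = index
    values = values.mask(values <= 0)  # zeros are censored, not measured

    annot = pd.read_csv(annotation_path)
    if "fibre_id" not in annot.columns:
        raise FormatError("annotation file lacks a fibre_id column")
    annot = annot.set_index(annot["fibre_id"].astype(str)).drop(columns="fibre_id")
    if annot.index.has_duplicates:
        raise FormatError("duplicate fibre ids in annotation file")

    matched = [c for c in run_cols if c in annot.index]
    unmatched = [c for c in run_cols if c not in annot.index]
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} run column(s) without annotation excluded: "
            f"{unmatched[:5]}",
            UserWarning,
            stacklevel=2,
        )
        logger.warning("unannotated runs excluded: %s", unmatched)
    if not matched:
        raise FormatError("no run column matches any annotated fibre id")
    return ProteinMatrix(
        values=values[matched],
        annotations=annot.loc[matched],
        genes=genes,
        scale="raw",
    )


def write_pg_matrix(matrix: ProteinMatrix, path) -> None:
    """Write a ProteinMatrix back to PG-matrix TSV layout (raw scale expected)."""
    out = matrix.values.copy()
    out.insert(0, "Genes", matrix.genes)
    out.insert(0, "Protein.Group", out.index)
    out.to_csv(path, sep="\t", index=False)


def log2_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    """log2 all quantified intensities; missing cells stay missing."""
    if matrix.scale == "log2":
        return matrix
    vals = matrix.values
    bad = (vals <= 0).stack()
    if bad.any():
        protein, fibre = bad[bad].index[0]
        raise ValueError(
            f"non-positive intensity at protein {protein!r}, fibre {fibre!r}"
        )
    return replace(matrix, values=np.log2(vals), scale="log2")


def protein_counts(matrix: ProteinMatrix) -> tuple[pd.Series, dict]:
    """Number of quantified proteins per fibre, with cohort mean +- SD."""
    counts = matrix.values.notna().sum(axis=0)
    counts.name = "n_proteins"
    summary = {
        "mean": float(counts.mean()),
        "sd": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
    }
    return counts, summary


def pca_outliers(matrix: ProteinMatrix, k_mad: float = 5.0) -> QcReport:
    """Flag outlier fibres in PC1-PC2 space of the complete-case submatrix.

    PCA uses only proteins quantified in every fibre (the deterministic
    reading of "omitting NA values" that needs no imputation).  A fibre is an
    outlier when the robust z-score of its Euclidean distance from the median
    PC1-PC2 point — (d - median d) / (1.4826 * MAD(d)) — exceeds ``k_mad``.
    """
    if matrix.values.shape[1] < 3:
        raise InsufficientDataError("PCA QC needs at least 3 fibres")
    complete = matrix.values.dropna(axis=0)
    if complete.shape[0] < 2:
        raise InsufficientDataError(
            "fewer than 2 complete-case proteins; imputation is out of scope"
        )
    X = complete.to_numpy().T  # fibres x proteins
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords_arr = pca.fit_transform(X)
    if n_comp < 2:  # pad so the report always has pc1/pc2
        coords_arr = np.column_stack([coords_arr, np.zeros(X.shape[0])])
    coords = pd.DataFrame(
        coords_arr[:, :2], index=matrix.values.columns, columns=["pc1", "pc2"]
    )
    centre = coords.median(axis=0).to_numpy()
    d = np.sqrt(((coords.to_numpy() - centre) ** 2).sum(axis=1))
    mad = np.median(np.abs(d - np.median(d)))
    if mad == 0 or not np.isfinite(k_mad):
        robust_z = np.zeros_like(d)
    else:
        robust_z = (d - np.median(d)) / (1.4826 * mad)
    flagged = [] if not np.isfinite(k_mad) else list(coords.index[robust_z > k_mad])
    counts, _ = protein_counts(matrix)
    return QcReport(
        counts=counts,
        coords=coords,
        outliers=flagged,
        n_complete_proteins=int(complete.shape[0]),
    )
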