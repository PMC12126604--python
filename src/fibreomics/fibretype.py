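"""Proteome-based myofibre subtype calling from MYH isoform abundance.

Human skeletal myofibres are classed by their dominant myosin heavy chain:
MYH7 (slow, type I), MYH2 (fast, type IIa) and MYH1 (fast, type IIx), with
hybrid fibres co-expressing adjacent isoforms.  Each fibre's relative
raw-scale LFQ abundance of the three isoforms is computed, and a fibre is
called "pure" when its dominant isoform fraction reaches an absolute
threshold, otherwise a hybrid of its top two isoforms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, UntypeableFibreError
from .qc import ProteinMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MYH_GENES",
    "PURE_LABELS",
    "myh_relative_abundance",
    "assign_fibre_type",
    "type_fibres",
    "rank_and_summarise",
    "threshold_sensitivity",
    "DEFAULT_PURE_THRESHOLD",
]

#: Isoform genes in (slow -> fast) canonical order.
MYH_GENES = ("MYH7", "MYH2", "MYH1")
PURE_LABELS = {"MYH7": "I", "MYH2": "IIa", "MYH1": "IIx"}
#: Canonical slow->fast ordering used to compose hybrid labels.
_CANONICAL = ("I", "IIa", "IIx")
DEFAULT_PURE_THRESHOLD = 0.7


def _myh_raw(matrix: ProteinMatrix, fibre_id: str) -> np.ndarray:
    """Raw-scale (MYH7, MYH2, MYH1) intensities; missing isoform -> 0."""
    vals = np.zeros(3)
    gene_to_protein = {}
    for protein, gene in matrix.genes.items():
        if gene in MYH_GENES and gene not in gene_to_protein:
            gene_to_protein[gene] = protein
    for i, gene in enumerate(MYH_GENES):
        protein = gene_to_protein.get(gene)
        if protein is None:
            continue
        v = matrix.values.at[protein, fibre_id]
        if pd.isna(v):
            continue
        vals[i] = 2.0**v if matrix.scale == "log2" else float(v)
    return vals


def myh_relative_abundance(
    matrix: ProteinMatrix, fibre_id: str
) -> tuple[float, float, float]:
    """Relative raw-scale abundance (rel7, rel2, rel1) of the MYH isoforms.

    Log2 matrices are back-transformed before ratioing; a missing isoform
    contributes zero.  Raises :class:`UntypeableFibreError` when none of the
    three isoforms was quantified.
    """
    raw = _myh_raw(matrix, fibre_id)
    total = raw.sum()
    if total <= 0:
        raise UntypeableFibreError(
            f"fibre {fibre_id!r}: no MYH7/MYH2/MYH1 quantification"
        )
    rel = raw / total
    return float(rel[0]), float(rel[1]), float(rel[2])


def assign_fibre_type(
    rel7: float,
    rel2: float,
    rel1: float,
    pure_threshold: float = DEFAULT_PURE_THRESHOLD,
) -> str:
    """Pure label when the dominant fraction reaches the threshold, else the
    hybrid of the top two isoforms in canonical slow->fast order."""
    fr = np.array([rel7, rel2, rel1], dtype=float)
    if np.any(fr < -1e-9) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must be non-negative and sum to 1: {fr}")
    if not (0.5 < pure_threshold <= 1.0):
        raise InvalidParameterError("pure_threshold must lie in (0.5, 1]")
    order = np.argsort(-fr, kind="stable")  # stable: ties prefer slow->fast
    if fr[order[0]] >= pure_threshold:
        return _CANONICAL[order[0]]
    top2 = sorted(order[:2])
    label = f"{_CANONICAL[top2[0]]}/{_CANONICAL[top2[1]]}"
    if top2 == [0, 2]:  # MYH7 + MYH1 dominant with MYH2 lowest: non-adjacent
        logger.warning("non-adjacent hybrid (MYH7+MYH1 dominant) labelled %s", label)
    return label


def type_fibres(
    matrix: ProteinMatrix,
    pure_threshold: float = DEFAULT_PURE_THRESHOLD,
    on_untypeable: str = "skip",
) -> pd.DataFrame:
    """Call the subtype of every fibre; returns fibre_id, rel7, rel2, rel1, label.

    ``on_untypeable`` is "skip" (drop fibres without MYH data, logged) or
    "raise".
    """
    rows = []
    for fibre in matrix.fibres:
        try:
            rel7, rel2, rel1 = myh_relative_abundance(matrix, fibre)
        except UntypeableFibreError:
            if on_untypeable == "raise":
                raise
            logger.warning("fibre %r untypeable (no MYH data); skipped", fibre)
            continue
        rows.append(
            {
                "fibre_id": fibre,
                "rel7": rel7,
                "rel2": rel2,
                "rel1": rel1,
                "label": assign_fibre_type(rel7, rel2, rel1, pure_threshold),
                "threshold": pure_threshold,
            }
        )
    return pd.DataFrame(
        rows, columns=["fibre_id", "rel7", "rel2", "rel1", "label", "threshold"]
    )


def rank_and_summarise(
    calls: pd.DataFrame, annotations: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Order fibres by MYH7 relative abundance (high to low) and tabulate the
    subtype composition, per condition when annotations are supplied."""
    if calls.empty:
        raise ValueError("no fibre-type calls to summarise")
    ordered = calls.sort_values(
        ["rel7", "fibre_id"], ascending=[False, True]
    ).reset_index(drop=True)
    if annotations is not None and "condition" in annotations.columns:
        cond = annotations["condition"].reindex(ordered["fibre_id"]).to_numpy()
        tab = (
            ordered.assign(condition=cond)
            .groupby(["condition", "label"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
    else:
        tab = ordered.groupby("label").size().to_frame().T
        tab.index = pd.Index(["all"], name="condition")
    composition = tab.div(tab.sum(axis=1), axis=0)
    return ordered, composition


def threshold_sensitivity(
    matrix: ProteinMatrix, thresholds=(0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9)
) -> pd.DataFrame:
    """Subtype composition across a sweep of pure-call thresholds."""
    rows = []
    for thr in thresholds:
        calls = type_fibres(matrix, pure_threshold=thr)
        frac = calls["label"].value_counts(normalize=True)
        rows.append(pd.Series(frac, name=thr))
    out = pd.DataFrame(rows).fillna(0.0)
    out.index.name = "pure_threshold"
    return out
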