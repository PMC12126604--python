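"""Quantifying loss of fibre-subtype divergence in disease.

In healthy muscle, type I and type IIa fibres differ in hundreds of protein
abundances.  In disease the question is whether those same subtype
differences persist: of the proteins differentially abundant between control
type I and type IIa fibres, which are still tested in the disease
cross-contrast, which remain significant ("maintained"), which do not
("lost"), and how much the surviving fold changes are attenuated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import compare_groups_anova_tukey
from .exceptions import InsufficientDataError
from .qc import ProteinMatrix

__all__ = [
    "ShrinkageReport",
    "partition_maintained",
    "foldchange_attenuation",
    "protein_boxplot_stats",
]


@dataclass
class ShrinkageReport:
    """Partition of control subtype-divergent proteins by their disease fate."""

    control_daps: pd.Series  # control log2fc indexed by protein (significant set)
    identified_in_disease: list[str]
    maintained: list[str]
    lost: list[str]
    fc_pairs: pd.DataFrame  # control_log2fc, disease_log2fc, disease_significant
    attenuation_count: int = 0
    attenuation_ratio: float = np.nan  # median over maintained (selection-prone)
    attenuation_ratio_identified: float = np.nan  # median over all identified
    sign_flips: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Subtype-divergence shrinkage report",
            "-" * 40,
            f"  control DAPs                 : {len(self.control_daps)}",
            f"  identified in disease tests  : {len(self.identified_in_disease)}",
            f"  maintained significant       : {len(self.maintained)}",
            f"  lost significance            : {len(self.lost)}",
            f"  |fc| attenuated (of pairs)   : {self.attenuation_count}/{len(self.fc_pairs)}",
            f"  median fc ratio (maintained) : {self.attenuation_ratio:.3f}",
            f"  median fc ratio (identified) : {self.attenuation_ratio_identified:.3f}",
            f"  sign flips                   : {self.sign_flips or 'none'}",
        ]
        return "\n".join(lines)


def foldchange_attenuation(
    fc_pairs: pd.DataFrame,
) -> tuple[int, float, pd.DataFrame]:
    """Count pairs with strictly smaller |disease fc| and the median ratio.

    ``fc_pairs`` needs columns control_log2fc / disease_log2fc.  Pairs with a
    zero control fold change are excluded from the ratio; sign flips are
    flagged, not counted as attenuation.
    """
    if fc_pairs.empty or (fc_pairs["control_log2fc"] == 0).all():
        raise InsufficientDataError(
            "attenuation undefined: no pair with non-zero control fold change"
        )
    tab = fc_pairs.copy()
    tab["attenuated"] = tab["disease_log2fc"].abs() < tab["control_log2fc"].abs()
    nonzero = tab["control_log2fc"] != 0
    tab["ratio"] = np.where(
        nonzero, tab["disease_log2fc"].abs() / tab["control_log2fc"].abs(), np.nan
    )
    tab["sign_flip"] = (
        np.sign(tab["disease_log2fc"]) * np.sign(tab["control_log2fc"]) < 0
    )
    count = int(tab["attenuated"].sum())
    ratio = float(np.nanmedian(tab["ratio"].to_numpy()))
    return count, ratio, tab


def partition_maintained(
    control_results: pd.DataFrame,
    disease_results: pd.DataFrame,
    alpha: float = 0.05,
) -> ShrinkageReport:
    """Split control DAPs by their fate in the disease cross-contrast.

    ``control_results``/``disease_results`` are scored contrast tables
    (indexed by protein, with log2fc, xiao_pi, significant).  The control
    significant set is intersected with the disease tested universe and split
    by disease significance at ``alpha``; attenuation statistics are computed
    on the maintained subset.
    """
    ctrl_sig = control_results[control_results["significant"]]
    universe = set(disease_results.index)
    if not (set(control_results.index) & universe):
        warnings.warn(
            "control and disease protein universes are disjoint",
            UserWarning,
            stacklevel=2,
        )
    identified = sorted(set(ctrl_sig.index) & universe)
    disease_pi = disease_results["xiao_pi"].reindex(identified)
    maintained = sorted(p for p in identified if disease_pi[p] < alpha)
    lost = sorted(set(identified) - set(maintained))
    fc_pairs = pd.DataFrame(
        {
            "control_log2fc": ctrl_sig["log2fc"].reindex(identified),
            "disease_log2fc": disease_results["log2fc"].reindex(identified),
            "disease_significant": disease_results["significant"].reindex(identified),
        }
    )
    all_att = int(
        (fc_pairs["disease_log2fc"].abs() < fc_pairs["control_log2fc"].abs()).sum()
    )
    if identified and (fc_pairs["control_log2fc"] != 0).any():
        _, ratio_ident, tab_all = foldchange_attenuation(fc_pairs)
        flips = sorted(tab_all.index[tab_all["sign_flip"]])
    else:
        ratio_ident, flips = np.nan, []
    if maintained:
        _, ratio, _ = foldchange_attenuation(fc_pairs.loc[maintained])
    else:
        ratio = np.nan
    return ShrinkageReport(
        control_daps=ctrl_sig["log2fc"],
        identified_in_disease=identified,
        maintained=maintained,
        lost=lost,
        fc_pairs=fc_pairs,
        attenuation_count=all_att,
        attenuation_ratio=ratio,
        attenuation_ratio_identified=ratio_ident,
        sign_flips=flips,
    )


def protein_boxplot_stats(
    matrix: ProteinMatrix,
    protein: str,
    groups: pd.Series,
) -> dict:
    """Per-group median/IQR plus ANOVA + Tukey HSD for one protein.

    ``groups`` maps fibre id -> group label; fibres missing the protein are
    dropped.  Needs >= 2 groups with >= 2 quantified fibres each.
    """
    vals = matrix.values.loc[protein]
    by_group: dict[str, np.ndarray] = {}
    stats_rows = {}
    for g, fibres in groups.dropna().groupby(groups.dropna()).groups.items():
        x = vals.reindex(fibres).dropna().to_numpy()
        if x.size >= 2:
            by_group[str(g)] = x
            stats_rows[str(g)] = {
                "n": int(x.size),
                "median": float(np.median(x)),
                "q1": float(np.percentile(x, 25)),
                "q3": float(np.percentile(x, 75)),
            }
    if len(by_group) < 2:
        raise InsufficientDataError(
            f"protein {protein!r}: fewer than 2 groups with >=2 fibres"
        )
    anova = compare_groups_anova_tukey(by_group)
    return {"protein": protein, "groups": stats_rows, **anova}
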