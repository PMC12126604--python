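"""Same-fibre SRX/DRX vs proteome correlation with presence filtering and
hierarchical clustering of subtype correlation profiles.

Fibres carrying both a fitted myosin-state measurement and a proteome column
("dual" fibres) are retained, QC outliers removed, and proteins thinned by
presence floors: quantified in at least ``min_n_all`` dual fibres for the
overall analysis, and in at least ``min_n_subtype`` fibres of *each* pure
subtype for the subtype-resolved analysis.  Correlations are Spearman,
reported with unadjusted p-values.
"""

from __future__ import annotations

import logging
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .qc import ProteinMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "filter_dual",
    "spearman",
    "correlate_phenotype",
    "correlate_srx_proteome",
    "cluster_correlation_profiles",
    "linkage_to_newick",
]

#: Sample sizes at or below this use exact permutation p-values.
EXACT_PERM_MAX_N = 9


def filter_dual(
    matrix: ProteinMatrix,
    srx_pct: pd.Series,
    outliers: tuple[str, ...] = (),
    min_n_all: int = 22,
) -> tuple[ProteinMatrix, pd.Series]:
    """Keep dual fibres (proteome + SRX, minus outliers) and proteins present
    in at least ``min_n_all`` of them.  Idempotent."""
    dual = [
        f
        for f in matrix.fibres
        if f in srx_pct.index and pd.notna(srx_pct[f]) and f not in set(outliers)
    ]
    if not dual:
        raise InsufficientDataError("no fibre has both proteome and SRX data")
    sub = matrix.subset(fibres=dual)
    present = sub.values.notna().sum(axis=1)
    keep = present.index[present >= min_n_all]
    return sub.subset(proteins=keep), srx_pct.reindex(dual)


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (n <= 9)."""
    n = rx.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    perms = np.array(list(permutations(range(n))))
    rhos = (ry_c[perms] @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value is an exact permutation enumeration for n <= 9 and
    the t-approximation above; p is clipped into (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need n >= 4 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    rho = float((rx_c @ ry_c) / np.sqrt((rx_c**2).sum() * (ry_c**2).sum()))
    if n <= EXACT_PERM_MAX_N:
        p = _exact_perm_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, float(np.clip(p, np.finfo(float).tiny, 1.0))


def correlate_phenotype(
    matrix: ProteinMatrix,
    phenotype: pd.Series,
    fibres: list[str],
    min_present: int,
    scope: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein Spearman rho of a phenotype over a fixed fibre scope."""
    if len(fibres) < 4:
        raise InsufficientDataError(
            f"scope {scope!r} has {len(fibres)} fibres; need >= 4"
        )
    pheno = phenotype.reindex(fibres)
    rows = []
    for protein in matrix.proteins:
        vals = matrix.values.loc[protein, fibres]
        ok = vals.notna() & pheno.notna()
        if int(ok.sum()) < max(min_present, 4):
            continue
        try:
            rho, p = spearman(vals[ok].to_numpy(), pheno[ok].to_numpy())
        except UndefinedCorrelationError:
            continue
        rows.append(
            {
                "protein": protein,
                "scope": scope,
                "rho": rho,
                "p_raw": p,
                "n": int(ok.sum()),
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(
        rows, columns=["protein", "scope", "rho", "p_raw", "n", "significant"]
    ).set_index("protein")


def correlate_srx_proteome(
    matrix: ProteinMatrix,
    srx_pct: pd.Series,
    scope: str = "all",
    type_calls: pd.DataFrame | None = None,
    min_n_subtype: int = 10,
    alpha: float = 0.05,
    phenotype: str = "srx",
) -> pd.DataFrame:
    """Spearman SRX (or DRX = 100 - SRX) vs protein abundance per scope.

    ``scope`` is "all" (every dual fibre, hybrids included), "typeI" or
    "typeIIa".  Subtype scopes additionally require each protein to be
    present in at least ``min_n_subtype`` fibres of *both* pure subtypes.
    """
    if scope not in ("all", "typeI", "typeIIa"):
        raise InvalidParameterError(f"unknown scope {scope!r}")
    pheno = srx_pct if phenotype == "srx" else 100.0 - srx_pct
    if scope == "all":
        return correlate_phenotype(
            matrix, pheno, matrix.fibres, min_present=4, scope=scope, alpha=alpha
        )
    if type_calls is None:
        raise InvalidParameterError("subtype scopes need fibre-type calls")
    calls = type_calls.set_index("fibre_id")["label"] if "fibre_id" in type_calls else type_calls["label"]
    fibres_by = {
        "typeI": [f for f in matrix.fibres if calls.get(f) == "I"],
        "typeIIa": [f for f in matrix.fibres if calls.get(f) == "IIa"],
    }
    # presence floor applies in each pure subtype
    present_I = matrix.values[fibres_by["typeI"]].notna().sum(axis=1)
    present_IIa = matrix.values[fibres_by["typeIIa"]].notna().sum(axis=1)
    eligible = matrix.values.index[
        (present_I >= min_n_subtype) & (present_IIa >= min_n_subtype)
    ]
    sub = matrix.subset(proteins=eligible)
    return correlate_phenotype(
        sub,
        pheno,
        fibres_by[scope],
        min_present=min_n_subtype,
        scope=scope,
        alpha=alpha,
    )


def _node_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _node_to_newick(node.get_left(), labels)
    right = _node_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)
    return _node_to_newick(tree, labels) + ";"


def cluster_correlation_profiles(
    profiles: pd.DataFrame,
    k: int | None = None,
    cut_height: float | None = None,
    linkage: str = "complete",
    metric: str = "euclidean",
) -> tuple[pd.Series, str]:
    """Agglomeratively cluster per-protein (rho_typeI, rho_typeIIa) profiles.

    One of ``k`` or ``cut_height`` selects the flat clustering (``k`` wins if
    both given).  Returns deterministic integer labels and the dendrogram as
    a Newick string.
    """
    if profiles.shape[0] < 2:
        raise InsufficientDataError("need >=2 proteins to cluster")
    if k is None and cut_height is None:
        raise InvalidParameterError("provide k or cut_height")
    if k is not None and k > profiles.shape[0]:
        raise ValueError(f"k={k} exceeds number of proteins {profiles.shape[0]}")
    X = profiles.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method=linkage, metric=metric)
    if k is not None:
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    newick = linkage_to_newick(Z, [str(i) for i in profiles.index])
    return pd.Series(labels, index=profiles.index, name="cluster"), newick
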