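"""Pseudo-bulk differential abundance with empirical-Bayes moderation and
composite fold-change/p significance (pi-value) calls.

Single-fibre intensities are first "mathematically downsampled" to one median
log2 value per protein per participant per group (pseudo-bulk), so the unit
of replication is the participant, not the fibre.  The pseudo-bulk columns
are quantile-normalised, each protein is tested with a two-group linear model
(optionally blocked on participant, i.e. paired), and the per-protein
residual variances are squeezed towards a common prior by the standard
empirical-Bayes scheme: the sample variances are modelled as scaled-F
distributed around a prior variance ``s0^2`` with prior degrees of freedom
``d0`` estimated by method of moments on the log variances, giving

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_mod       = log2FC / (s_tilde_g * sqrt(v_g)),   df = d0 + d_g.

Significance is called on the composite pi-value ``pi = p ^ |log2FC|``
(equivalently 10^(-s) with s = |log2FC| * (-log10 p)), which demands both a
small p and a material fold change; calls are deliberately unadjusted for
multiple testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import InsufficientDataError, InvalidParameterError
from .qc import ProteinMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PseudoBulkMatrix",
    "pseudobulk_median",
    "quantile_normalise",
    "quantile_normalise_frame",
    "estimate_variance_prior",
    "moderated_fit",
    "xiao_score",
    "score_results",
    "call_significant",
    "srx_cluster_contrast",
    "run_contrast",
    "overlap_direction",
]


@dataclass
class PseudoBulkMatrix:
    """Proteins x (participant, group) median log2 matrix with fibre counts."""

    values: pd.DataFrame  # columns: MultiIndex (participant, group)
    n_fibres: pd.DataFrame

    def columns_for(self, group: str) -> list:
        return [c for c in self.values.columns if c[1] == group]


def pseudobulk_median(
    matrix: ProteinMatrix,
    grouping: pd.Series,
) -> PseudoBulkMatrix:
    """Median per (participant, group, protein) over that participant's fibres.

    ``grouping`` maps fibre id -> group label; fibres with a null group are
    excluded (e.g. hybrids in a pure-subtype contrast).
    """
    grouping = grouping.dropna()
    fibres = [f for f in matrix.fibres if f in grouping.index]
    if not fibres:
        raise ValueError("grouping assigns no fibre of the matrix to any group")
    participants = matrix.annotations["participant"]
    cells: dict[tuple, pd.Series] = {}
    counts: dict[tuple, pd.Series] = {}
    key_df = pd.DataFrame(
        {
            "participant": participants.reindex(fibres),
            "group": grouping.reindex(fibres),
        },
        index=pd.Index(fibres),
    )
    for (part, grp), sub in key_df.groupby(["participant", "group"], sort=True):
        block = matrix.values[sub.index]
        cells[(part, grp)] = block.median(axis=1, skipna=True)
        counts[(part, grp)] = block.notna().sum(axis=1)
    cols = pd.MultiIndex.from_tuples(sorted(cells), names=["participant", "group"])
    values = pd.DataFrame({c: cells[c] for c in cols}, index=matrix.values.index)
    values.columns = cols
    n_fibres = pd.DataFrame({c: counts[c] for c in cols}, index=matrix.values.index)
    n_fibres.columns = cols
    return PseudoBulkMatrix(values=values, n_fibres=n_fibres)


def quantile_normalise_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Classical quantile normalisation tolerant of missing cells.

    The reference distribution is the across-column mean of the sorted values
    of complete rows.  Complete columns are mapped rank-for-rank onto the
    reference (ties receive the mean of their target values); columns with
    missing entries map their observed average ranks onto the reference by
    linear interpolation.
    """
    if df.shape[1] < 2:
        warnings.warn(
            "quantile normalisation of a single column is the identity",
            UserWarning,
            stacklevel=2,
        )
        return df.copy()
    complete = df.dropna(axis=0)
    if complete.shape[0] < 2:
        raise InsufficientDataError(
            "quantile normalisation needs >=2 complete rows for a reference"
        )
    reference = np.sort(complete.to_numpy(), axis=0).mean(axis=1)
    n_ref = reference.size
    out = df.copy()
    for col in df.columns:
        obs = df[col].dropna()
        n_obs = obs.size
        if n_obs == 0:
            continue
        if n_obs == 1:
            out.loc[obs.index, col] = reference[(n_ref - 1) // 2]
            continue
        order = np.argsort(obs.to_numpy(), kind="stable")
        # ordinal target positions on the reference grid
        pos = np.arange(n_obs) * (n_ref - 1) / (n_obs - 1)
        mapped = np.interp(pos, np.arange(n_ref), reference)
        # tie groups get the mean of their member target values
        sorted_vals = obs.to_numpy()[order]
        assigned = np.empty(n_obs)
        i = 0
        while i < n_obs:
            j = i
            while j + 1 < n_obs and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            assigned[i : j + 1] = mapped[i : j + 1].mean()
            i = j + 1
        new_vals = np.empty(n_obs)
        new_vals[order] = assigned
        out.loc[obs.index, col] = new_vals
    return out


def quantile_normalise(pb: PseudoBulkMatrix) -> PseudoBulkMatrix:
    return PseudoBulkMatrix(
        values=quantile_normalise_frame(pb.values), n_fibres=pb.n_fibres
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Brent on a bracketing interval)."""
    if y <= 0:
        return np.inf
    lo, hi = 1e-8, 1e8
    if special.polygamma(1, lo) < y:
        return lo
    if special.polygamma(1, hi) > y:
        return hi
    return float(
        optimize.brentq(lambda x: special.polygamma(1, x) - y, lo, hi, xtol=1e-12)
    )


def estimate_variance_prior(
    s2: np.ndarray, df: np.ndarray
) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) to sample variances.

    Models s2_g / s0^2 ~ F(df_g, d0); moments of log s2_g identify d0 via the
    trigamma function and s0^2 via the digamma correction.  Returns
    (d0, s0sq); d0 = inf when the log variances show no excess dispersion.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise InsufficientDataError("too few positive variances to fit a prior")
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = float(
            np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
        ) if np.isfinite(d0) else float(np.exp(emean))
    else:
        # No excess dispersion in the log variances: infinite prior df.  The
        # prior variance is then the plain average of the sample variances,
        # so that exactly equal variances squeeze to themselves.
        d0, s0sq = np.inf, float(s2.mean())
    return float(d0), s0sq


def _per_protein_stats(
    pb: PseudoBulkMatrix, contrast: tuple[str, str], paired: bool
) -> pd.DataFrame:
    """Per-protein log2FC, residual variance, df and scale factor v_g."""
    group_a, group_b = contrast
    cols_a = pb.columns_for(group_a)
    cols_b = pb.columns_for(group_b)
    if not cols_a or not cols_b:
        raise InsufficientDataError(
            f"contrast groups {contrast} not both present in pseudo-bulk columns"
        )
    rows = []
    if paired:
        parts = sorted(
            {c[0] for c in cols_a} & {c[0] for c in cols_b}
        )
        if len(parts) < 2:
            raise InsufficientDataError(
                "paired fit needs >=2 participants with both groups"
            )
        a = pb.values[[(p, group_a) for p in parts]].to_numpy()
        b = pb.values[[(p, group_b) for p in parts]].to_numpy()
        d = a - b
        for g, protein in enumerate(pb.values.index):
            dg = d[g][np.isfinite(d[g])]
            n = dg.size
            if n < 2:
                continue
            rows.append(
                {
                    "protein": protein,
                    "log2fc": dg.mean(),
                    "s2": dg.var(ddof=1),
                    "df": n - 1,
                    "v": 1.0 / n,
                    "n_A": n,
                    "n_B": n,
                }
            )
    else:
        a = pb.values[cols_a].to_numpy()
        b = pb.values[cols_b].to_numpy()
        for g, protein in enumerate(pb.values.index):
            xa = a[g][np.isfinite(a[g])]
            xb = b[g][np.isfinite(b[g])]
            na, nb = xa.size, xb.size
            if na < 2 or nb < 2:
                continue
            s2 = (
                np.sum((xa - xa.mean()) ** 2) + np.sum((xb - xb.mean()) ** 2)
            ) / (na + nb - 2)
            rows.append(
                {
                    "protein": protein,
                    "log2fc": xa.mean() - xb.mean(),
                    "s2": s2,
                    "df": na + nb - 2,
                    "v": 1.0 / na + 1.0 / nb,
                    "n_A": na,
                    "n_B": nb,
                }
            )
    if not rows:
        raise InsufficientDataError("no protein has enough observations to test")
    return pd.DataFrame(rows).set_index("protein")


def moderated_fit(
    pb: PseudoBulkMatrix,
    contrast: tuple[str, str],
    paired: bool = False,
) -> pd.DataFrame:
    """Two-group (A - B) linear-model fit with empirical-Bayes moderation.

    Returns a DataFrame indexed by protein with log2fc, t_mod, p_raw,
    s2, df_total, n_A, n_B.  Falls back to the ordinary t-statistic when the
    prior cannot be estimated (fewer than 5 testable proteins), logged.
    """
    st = _per_protein_stats(pb, contrast, paired)
    usable = st["s2"] > 0
    if usable.sum() >= 5:
        d0, s0sq = estimate_variance_prior(
            st.loc[usable, "s2"].to_numpy(), st.loc[usable, "df"].to_numpy()
        )
    else:
        logger.warning(
            "only %d proteins with positive variance; ordinary t fallback",
            int(usable.sum()),
        )
        d0, s0sq = 0.0, 0.0
    if np.isinf(d0):
        s2_post = np.full(len(st), s0sq)
        df_total = np.full(len(st), np.inf)
    else:
        s2_post = (d0 * s0sq + st["df"] * st["s2"]) / (d0 + st["df"])
        df_total = d0 + st["df"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = st["log2fc"] / np.sqrt(s2_post * st["v"])
    t_arr = np.asarray(t_mod, dtype=float)
    p = np.where(
        np.isfinite(df_total),
        2 * stats.t.sf(np.abs(t_arr), np.where(np.isfinite(df_total), df_total, 1)),
        2 * stats.norm.sf(np.abs(t_arr)),
    )
    p = np.where(np.isnan(t_arr), 1.0, p)  # zero fc with zero variance
    t_arr = np.where(np.isnan(t_arr), 0.0, t_arr)
    out = st.copy()
    out["t_mod"] = t_arr
    out["p_raw"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["df_total"] = df_total
    out.attrs["d0"] = d0
    out.attrs["s0sq"] = s0sq
    return out[["log2fc", "t_mod", "p_raw", "s2", "df", "df_total", "n_A", "n_B"]]


def xiao_score(p_raw, log2fc):
    """Composite significance pi = p ^ |log2FC| (vectorised).

    Monotone increasing in p and decreasing in |log2FC| (for p < 1): larger
    fold changes make a given p-value more credible.
    """
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p_raw must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("p_raw of 0 clipped to smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    return np.power(p, np.abs(np.asarray(log2fc, dtype=float)))


def score_results(
    results: pd.DataFrame,
    alpha: float = 0.05,
    scorer: Callable = xiao_score,
) -> pd.DataFrame:
    """Attach the composite score and the significance call (pi < alpha)."""
    out = results.copy()
    out["xiao_pi"] = scorer(out["p_raw"].to_numpy(), out["log2fc"].to_numpy())
    out["significant"] = out["xiao_pi"] < alpha
    return out


def call_significant(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Strict pi < alpha subset, with per-direction counts in .attrs."""
    if "xiao_pi" not in results.columns:
        results = score_results(results, alpha=alpha)
    sig = results[results["xiao_pi"] < alpha].copy()
    sig.attrs["n_up"] = int((sig["log2fc"] > 0).sum())
    sig.attrs["n_down"] = int((sig["log2fc"] < 0).sum())
    return sig


def run_contrast(
    matrix: ProteinMatrix,
    grouping: pd.Series,
    contrast: tuple[str, str],
    paired: bool = False,
    alpha: float = 0.05,
    normalise: bool = True,
    scorer: Callable = xiao_score,
) -> pd.DataFrame:
    """Pseudo-bulk -> quantile normalisation -> moderated fit -> pi calls."""
    pb = pseudobulk_median(matrix, grouping)
    if normalise:
        pb = quantile_normalise(pb)
    res = moderated_fit(pb, contrast, paired=paired)
    return score_results(res, alpha=alpha, scorer=scorer)


def srx_cluster_contrast(
    matrix: ProteinMatrix,
    srx_pct: pd.Series,
    low_cut: float = 35.0,
    high_cut: float = 65.0,
    alpha: float = 0.05,
    normalise: bool = True,
) -> pd.DataFrame:
    """Paired high-vs-low SRX-cluster contrast, restricted to participants
    contributing fibres to both clusters; mid-cluster fibres are excluded."""
    from .decay import classify_srx

    srx = srx_pct.reindex(matrix.fibres).dropna()
    labels = srx.map(lambda v: classify_srx(v, low_cut, high_cut).label)
    grouping = labels.where(labels.isin(["low", "high"]))
    participants = matrix.annotations["participant"]
    have = pd.DataFrame(
        {"participant": participants.reindex(grouping.dropna().index),
         "cluster": grouping.dropna()}
    )
    both = {
        p
        for p, sub in have.groupby("participant")
        if {"low", "high"} <= set(sub["cluster"])
    }
    excluded = sorted(set(have["participant"]) - both)
    if excluded:
        logger.info(
            "participants without both SRX clusters excluded: %s", excluded
        )
    if len(both) < 2:
        raise InsufficientDataError(
            f"only {len(both)} participant(s) contain both SRX clusters"
        )
    keep = have.index[have["participant"].isin(both)]
    sub = matrix.subset(fibres=[f for f in matrix.fibres if f in set(keep)])
    return run_contrast(
        sub,
        grouping.reindex(sub.fibres),
        contrast=("high", "low"),
        paired=True,
        alpha=alpha,
        normalise=normalise,
    )


def overlap_direction(set_a: pd.DataFrame, set_b: pd.DataFrame) -> dict:
    """Overlap of two significant-hit tables with direction concordance.

    Returns ``common`` (proteins significant in both), ``concordant_count``
    (same sign of log2fc) and ``discordant`` (named sign flips).
    """
    sig_a = set_a[set_a["significant"]] if "significant" in set_a else set_a
    sig_b = set_b[set_b["significant"]] if "significant" in set_b else set_b
    common = sorted(set(sig_a.index) & set(sig_b.index))
    concordant, discordant = 0, []
    for protein in common:
        same = np.sign(sig_a.loc[protein, "log2fc"]) == np.sign(
            sig_b.loc[protein, "log2fc"]
        )
        if same:
            concordant += 1
        else:
            discordant.append(protein)
    return {
        "common": common,
        "concordant_count": concordant,
        "discordant": discordant,
    }
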