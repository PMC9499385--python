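"""qPCR Cq-table processing and sequencing concordance.

Cq (quantification cycle) is treated as a log2 abundance scale with 100%
amplification efficiency: one cycle = one twofold change, and lower Cq
means more template. Relative plasma levels are expressed against the
reference assay miR-30e-5p as EXP = Cq(reference) - Cq(target).

Reference-assay stability is ranked with a NormFinder-style model-based
variance decomposition: per assay and group, an intra-group variance is
estimated from the within-group two-way (assay x sample) residuals, and
an inter-group component from the assay's group-mean deviations, shrunk
toward zero according to the estimated between-group variance; the
stability value averages |shrunken inter-group deviation| +
sqrt(intra-group variance / group size) over groups, lower = more stable.
Being reference-free, the decomposition is invariant to per-sample global
shifts and to assay-wise constant offsets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

REFERENCE_ASSAY = "hsa-miR-30e-5p"


def exclude_cq_outliers(cq: pd.DataFrame, max_mean_cq: float = 25.0) -> tuple[list[str], list[dict]]:
    """Exclude samples whose mean Cq across all assays strictly exceeds the cap.

    Unconfident overall detection (mean Cq > 25) marks a degenerate
    sample. Returns (retained sample ids, exclusion log). Missing Cq
    values are an error: every retained assay must be measured in every
    sample.
    """
    if cq.isna().any().any():
        bad = cq.columns[cq.isna().any(axis=0)]
        raise InputError(f"missing Cq values in sample(s): {list(bad)}")
    mean_cq = cq.mean(axis=0)
    retained, log = [], []
    for s in cq.columns:
        if mean_cq[s] > max_mean_cq:
            log.append({"sample": s, "reason": "mean_cq_above_threshold", "value": float(mean_cq[s]), "excluded": True})
        else:
            retained.append(s)
    return retained, log


def relative_expression(cq: pd.DataFrame, reference: str = REFERENCE_ASSAY) -> pd.DataFrame:
    """EXP = Cq(reference) - Cq(target), per target per sample.

    The reference's own EXP row is identically 0; EXP differences between
    two targets do not depend on the reference choice.
    """
    if reference not in cq.index:
        raise InputError(f"reference assay absent from Cq table: {reference}")
    if cq.loc[reference].isna().any():
        missing = cq.columns[cq.loc[reference].isna()]
        raise InputError(f"reference {reference} unmeasured in sample(s): {list(missing)}")
    return cq.loc[reference] - cq


def exp_from_log2cpm(log2cpm_df: pd.DataFrame, reference: str = REFERENCE_ASSAY) -> pd.DataFrame:
    """Sequencing-side analogue: EXP_CPM = log2CPM(target) - log2CPM(reference)."""
    if reference not in log2cpm_df.index:
        raise InputError(f"reference miRNA absent from expression matrix: {reference}")
    return log2cpm_df - log2cpm_df.loc[reference]


def normfinder_stability(cq: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Model-based reference-gene stability per assay; lower = more stable."""
    assays = list(cq.index)
    if len(assays) < 2:
        raise InputError("need at least two candidate assays")
    groups = groups.loc[cq.columns]
    g_levels = sorted(groups.unique())
    if len(g_levels) < 2:
        raise InputError("need at least two groups")
    x = -cq  # log2 abundance orientation; stability is location-invariant anyway
    I = len(assays)
    G = len(g_levels)

    group_mean = pd.DataFrame(index=assays, columns=g_levels, dtype=float)  # m_ig
    sigma2 = pd.DataFrame(index=assays, columns=g_levels, dtype=float)
    n_per_group = {}
    for g in g_levels:
        cols = groups.index[groups == g]
        n_g = len(cols)
        if n_g < 2:
            raise InputError(f"group {g} has fewer than two samples; variance inestimable")
        n_per_group[g] = n_g
        sub = x[cols]
        m_ig = sub.mean(axis=1)
        s_gj = sub.mean(axis=0)
        M_g = float(sub.to_numpy().mean())
        z = sub.sub(m_ig, axis=0).sub(s_gj, axis=1) + M_g
        # residuals sum to zero over assays, deflating each variance by (1 - 1/I)
        sigma2[g] = (z**2).sum(axis=1) / ((n_g - 1) * (1.0 - 1.0 / I))
        group_mean[g] = m_ig

    M_g_series = pd.Series({g: float(x[groups.index[groups == g]].to_numpy().mean()) for g in g_levels})
    a = group_mean.sub(M_g_series, axis=1)  # assay deviation from its group mean
    d = a.sub(a.mean(axis=1), axis=0)  # inter-group variation, sums to 0 per assay and per group

    nvec = pd.Series(n_per_group)
    noise = (sigma2 / nvec).to_numpy().mean()
    gamma2 = max(0.0, float((d**2).to_numpy().sum()) / ((I - 1) * (G - 1)) - noise)
    shrink = gamma2 / (gamma2 + sigma2.div(nvec, axis=1)) if gamma2 > 0 else sigma2 * 0.0
    d_shrunk = d * shrink

    stability = (d_shrunk.abs() + np.sqrt(sigma2.div(nvec, axis=1))).mean(axis=1)
    return stability.sort_values()


def concordance(
    exp_cpm: pd.DataFrame,
    exp_pcr: pd.DataFrame,
    mode: str = "per_sample",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Agreement between sequencing- and qPCR-based relative expression.

    ``per_sample`` (default): for each target present in both tables, OLS
    R-squared and Spearman rho across matched samples. ``target_mean``:
    one point per target (mean over matched samples), a single pooled
    regression. Returns (statistics table, paired long-format table).
    """
    targets = [t for t in exp_pcr.index if t in exp_cpm.index]
    samples = [s for s in exp_pcr.columns if s in exp_cpm.columns]
    if len(samples) < 3:
        raise InputError("fewer than 3 matched samples")
    pairs = []
    for t in targets:
        for s in samples:
            pairs.append({"target": t, "sample": s, "exp_cpm": float(exp_cpm.loc[t, s]), "exp_pcr": float(exp_pcr.loc[t, s])})
    paired = pd.DataFrame(pairs)

    if mode == "per_sample":
        rows = {}
        for t in targets:
            sub = paired[paired["target"] == t]
            rows[t] = _fit_stats(sub["exp_cpm"], sub["exp_pcr"])
        return pd.DataFrame(rows).T, paired
    if mode == "target_mean":
        means = paired.groupby("target")[["exp_cpm", "exp_pcr"]].mean()
        if len(means) < 3:
            raise InputError("fewer than 3 targets for target_mean mode")
        return pd.DataFrame({"pooled": _fit_stats(means["exp_cpm"], means["exp_pcr"])}).T, paired
    raise InputError(f"unknown concordance mode: {mode}")


def _fit_stats(x: pd.Series, y: pd.Series) -> dict:
    if x.nunique() < 2 or y.nunique() < 2:
        return {"r2": np.nan, "spearman_rho": np.nan, "n": float(len(x))}
    lin = stats.linregress(x, y)
    rho = stats.spearmanr(x, y).statistic
    return {"r2": float(lin.rvalue**2), "spearman_rho": float(rho), "n": float(len(x))}
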