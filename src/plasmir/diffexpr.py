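"""TMM normalization and blocked pairwise differential expression.

Between-sample normalization follows the trimmed-mean-of-M-values (TMM)
definition: for each sample against a reference, gene-wise log2 ratios
(M) and average log2 abundances (A) are computed over co-expressed genes,
the most extreme 30% of M and 5% of A are trimmed, and the scaling factor
is the precision-weighted mean of the remaining M values (weights =
inverse asymptotic binomial variances). Factors are normalized to
multiply to 1; the reference sample is the one whose upper-quartile count
fraction is closest to the mean.

Testing uses a negative-binomial generalized linear model per miRNA with
additive subject (block) and anticoagulant-group effects on TMM-offset
counts. Gene-wise NB dispersions are estimated by Cox-Reid adjusted
profile likelihood, smoothed into a mean-dispersion trend (binned
medians, interpolated on average log2CPM), and the trended dispersion is
used for the fits. Gene-level variability then goes into a quasi-
dispersion s2 = residual deviance / residual df, shrunk toward a common
value by an empirical-Bayes scaled-F fit (moment estimation of the prior
df on log s2). Each pairwise group contrast is a quasi-likelihood F-test
of the full model against the model with the two groups merged, on
(1, prior df + residual df) degrees of freedom. p-values are
Benjamini-Hochberg adjusted across ALL contrasts as one family, and the
selection rule for differentially expressed miRNAs is: mean log2CPM > 5,
at least one significant contrast, and (some significant contrast with
|log2FC| > 1 OR at least three significant contrasts).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import InputError
from .quantify import CountMatrix, cpm, log2cpm

_LN2 = np.log(2.0)


# --------------------------------------------------------------------------
# TMM


def tmm_factors(
    cm: CountMatrix | pd.DataFrame,
    ref_sample: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors (product normalized to 1)."""
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    if counts.shape[1] < 2:
        raise InputError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise InputError(f"zero library: {list(lib.index[lib == 0])}")
    frac = counts / lib
    if ref_sample is None:
        f75 = frac.quantile(0.75, axis=0)
        ref_sample = (f75 - f75.mean()).abs().idxmin()
    yr = counts[ref_sample].to_numpy(float)
    Nr = lib[ref_sample]
    factors = {}
    for s in counts.columns:
        if s == ref_sample:
            factors[s] = 1.0
            continue
        y = counts[s].to_numpy(float)
        N = lib[s]
        both = (y > 0) & (yr > 0)
        if not both.any():
            raise InputError(f"sample {s} shares no co-expressed genes with reference {ref_sample}")
        yy, rr = y[both], yr[both]
        M = np.log2((yy / N) / (rr / Nr))
        A = 0.5 * np.log2((yy / N) * (rr / Nr))
        # asymptotic binomial variance of M; weights are its inverse
        v = (N - yy) / (N * yy) + (Nr - rr) / (Nr * rr)
        n = len(M)
        loL = np.floor(n * logratio_trim) + 1
        hiL = n + 1 - loL
        loS = np.floor(n * sum_trim) + 1
        hiS = n + 1 - loS
        rM = stats.rankdata(M)
        rA = stats.rankdata(A)
        keep = (rM >= loL) & (rM <= hiL) & (rA >= loS) & (rA <= hiS)
        if keep.sum() == 0 or not np.isfinite(v[keep]).all():
            factors[s] = 1.0
        elif np.abs(M).max() < 1e-6:
            factors[s] = 1.0
        else:
            factors[s] = float(2 ** (np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])))
    f = pd.Series(factors)[counts.columns]
    f /= np.exp(np.mean(np.log(f)))
    return f


# --------------------------------------------------------------------------
# NB GLM internals


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        if phi > 0:
            t2 = (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
        else:
            t2 = y - mu
    return float(2.0 * np.sum(t1 - t2))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.maximum(mu, 1e-300)
    if phi <= 0:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    a = 1.0 / phi
    return float(
        np.sum(
            special.gammaln(y + a)
            - special.gammaln(a)
            - special.gammaln(y + 1)
            + y * np.log(phi * mu / (1.0 + phi * mu))
            - a * np.log1p(phi * mu)
        )
    )


def _irls_nb(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float, max_iter: int = 60, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit log mu = X beta + offset for NB(mu, phi); returns (beta, mu, deviance)."""
    # one WLS step from the data-anchored mu gives the starting beta; the
    # deviance guard only applies between model-based iterates
    mu0 = np.maximum(y, 0.0) + np.mean(y) * 0.1 + 0.1
    w0 = mu0 / (1.0 + phi * mu0)
    z0 = np.log(mu0) - offset
    WX0 = X * w0[:, None]
    try:
        beta = np.linalg.solve(X.T @ WX0, WX0.T @ z0)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(np.sqrt(w0)[:, None] * X, np.sqrt(w0) * z0, rcond=None)[0]
    eta = X @ beta
    mu = np.exp(np.clip(eta + offset, -700, 700))
    dev = _nb_deviance(y, mu, phi)
    for _ in range(max_iter):
        w = mu / (1.0 + phi * mu)
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(np.sqrt(w)[:, None] * X, np.sqrt(w) * z, rcond=None)[0]
        eta_new = X @ beta_new
        mu_new = np.exp(np.clip(eta_new + offset, -700, 700))
        dev_new = _nb_deviance(y, mu_new, phi)
        step = 1.0
        while not np.isfinite(dev_new) or dev_new > dev + 1e-8:
            step /= 2.0
            if step < 1e-4:
                return beta, mu, dev
            beta_new = beta + step * (beta_new - beta)
            eta_new = X @ beta_new
            mu_new = np.exp(np.clip(eta_new + offset, -700, 700))
            dev_new = _nb_deviance(y, mu_new, phi)
        delta = abs(dev - dev_new)
        beta, eta, mu, dev = beta_new, eta_new, mu_new, dev_new
        if delta < tol * (abs(dev) + 1.0):
            break
    return beta, mu, dev


def _cox_reid_apl(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float) -> float:
    _, mu, _ = _irls_nb(y, X, offset, phi)
    w = mu / (1.0 + phi * mu)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return _nb_loglik(y, mu, phi) - 0.5 * logdet


def estimate_dispersion(y: np.ndarray, X: np.ndarray, offset: np.ndarray) -> float:
    """Gene-wise NB dispersion maximizing the Cox-Reid adjusted profile
    likelihood over log10(phi) in [-4, 1]."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda lg: -_cox_reid_apl(y, X, offset, 10.0**lg),
        bounds=(-4.0, 1.0),
        method="bounded",
        options={"xatol": 0.02},
    )
    return float(10.0 ** res.x)


def _dispersion_trend(ave_log2cpm: np.ndarray, disp: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Binned-median trend of dispersion vs abundance, linearly interpolated."""
    n = len(disp)
    if n < 4:
        return np.full(n, np.median(disp))
    n_bins = int(np.clip(n // 5, 2, n_bins))
    order = np.argsort(ave_log2cpm)
    bins = np.array_split(order, n_bins)
    centers = np.array([ave_log2cpm[b].mean() for b in bins])
    meds = np.array([np.median(disp[b]) for b in bins])
    trend = np.interp(ave_log2cpm, centers, meds)
    return np.maximum(trend, 1e-6)


def _trigamma_inverse(y: float) -> float:
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of a scaled-F prior on sample variances (prior df, prior s2)."""
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = float(e.var(ddof=1)) * n / (n - 1) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return d0, s02
    return np.inf, float(np.exp(emean))


def _design(groups: pd.Series, subjects: pd.Series | None) -> tuple[np.ndarray, dict[str, int], list]:
    """Treatment-coded design: intercept + subject blocks + group effects.

    Returns (X, column index of each non-reference group, group levels).
    """
    g_levels = sorted(groups.unique())
    cols = [np.ones(len(groups))]
    names = ["(intercept)"]
    if subjects is not None:
        s_levels = sorted(subjects.unique())
        for s in s_levels[1:]:
            cols.append((subjects == s).to_numpy(float))
            names.append(f"subject[{s}]")
    gcol = {}
    for g in g_levels[1:]:
        gcol[g] = len(cols)
        cols.append((groups == g).to_numpy(float))
        names.append(f"group[{g}]")
    X = np.column_stack(cols)
    return X, gcol, g_levels


def fit_pairwise_de(
    cm: CountMatrix,
    group: str | pd.Series = "group",
    subject: str | pd.Series | None = "subject_id",
    norm_factors: pd.Series | None = None,
    prior_count: float = 0.125,
    dispersion: float | None = None,
    test: str = "ql",
) -> pd.DataFrame:
    """Blocked NB/QL differential expression over all pairwise group contrasts.

    Returns one row per (miRNA, contrast) with log2FC (from a fit on
    counts augmented by a library-size-scaled 0.125 prior, so fold changes
    stay finite), mean log2CPM, raw and pooled-BH-adjusted p-values and
    the significance flag (adj p < 0.05).

    ``dispersion`` overrides the estimated trended NB dispersion with a
    fixed value (useful when the dispersion is known, e.g. simulations).
    ``test`` selects the quasi-likelihood F-test (default) or the plain
    likelihood-ratio chi-square test (``"lr"``); the LR test trusts the
    supplied dispersion and has no gene-level variance moderation.
    """
    if test not in ("ql", "lr"):
        raise InputError(f"unknown test: {test!r}")
    groups = cm.samples[group] if isinstance(group, str) else group
    subjects = None
    if subject is not None:
        subjects = cm.samples[subject] if isinstance(subject, str) else subject
    g_levels = sorted(groups.unique())
    if len(g_levels) < 2:
        raise InputError("need at least two groups")
    if subjects is not None:
        per_subj = pd.crosstab(subjects, groups)
        bad = per_subj.index[(per_subj > 0).sum(axis=1) < 2]
        if len(bad):
            warnings.warn(f"subjects present in fewer than two groups: {list(bad)}")

    counts = cm.counts
    nonzero = counts.sum(axis=1) > 0
    if (~nonzero).any():
        warnings.warn(f"dropping {(~nonzero).sum()} all-zero miRNA row(s)")
        counts = counts[nonzero]
    if norm_factors is None:
        norm_factors = tmm_factors(cm)
    lib = counts.sum(axis=0).astype(float)
    eff_lib = (lib * norm_factors[counts.columns]).to_numpy()
    offset = np.log(eff_lib)

    X, gcol, _ = _design(groups, subjects)
    n, p = X.shape
    df_resid = n - p
    if df_resid <= 0:
        raise InputError("design has no residual degrees of freedom")

    l2 = log2cpm(cpm(counts))
    ave_l2 = l2.mean(axis=1).to_numpy()
    Y = counts.to_numpy(float)
    G = Y.shape[0]

    if dispersion is not None:
        trend = np.full(G, float(dispersion))
    else:
        disp = np.array([estimate_dispersion(Y[i], X, offset) for i in range(G)])
        trend = _dispersion_trend(ave_l2, disp)

    prior = prior_count * eff_lib / eff_lib.mean()
    dev_full = np.empty(G)
    beta_fc = np.empty((G, p))
    for i in range(G):
        _, _, dev_full[i] = _irls_nb(Y[i], X, offset, trend[i])
        beta_fc[i], _, _ = _irls_nb(Y[i] + prior, X, offset, trend[i])

    s2 = np.maximum(dev_full / df_resid, 0.0)
    d0, s02 = _squeeze_var(s2, df_resid)
    if np.isinf(d0):
        s2_shrunk = np.full(G, s02)
        df_total = np.inf
    else:
        s2_shrunk = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    records = []
    for g1, g2 in itertools.combinations(g_levels, 2):
        merged = groups.replace({g2: g1})
        if merged.nunique() < 2 and len(g_levels) == 2:
            Xr = _design(pd.Series("all", index=groups.index), subjects)[0]
        else:
            Xr, _, _ = _design(merged, subjects)
        c = np.zeros(p)
        if g1 in gcol:
            c[gcol[g1]] = 1.0
        if g2 in gcol:
            c[gcol[g2]] -= 1.0
        for i in range(G):
            _, _, dev_red = _irls_nb(Y[i], Xr, offset, trend[i])
            lr_stat = max(dev_red - dev_full[i], 0.0)
            if test == "lr":
                pval = float(stats.chi2.sf(lr_stat, 1))
            elif np.isinf(df_total):
                pval = float(stats.chi2.sf(lr_stat / max(s2_shrunk[i], 1e-12), 1))
            else:
                pval = float(stats.f.sf(lr_stat / max(s2_shrunk[i], 1e-12), 1, df_total))
            records.append(
                {
                    "mirna": counts.index[i],
                    "contrast": f"{g1}_vs_{g2}",
                    "log2fc": float(c @ beta_fc[i] / _LN2),
                    "mean_log2cpm": float(ave_l2[i]),
                    "p_value": pval,
                }
            )
    res = pd.DataFrame.from_records(records)
    res["adj_p"] = bh_adjust_pooled(res["p_value"].to_numpy())
    res["significant"] = res["adj_p"] < 0.05
    return res


def bh_adjust_pooled(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up over the pooled p-value vector."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise InputError("NaN p-value in adjustment input")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def select_de(
    results: pd.DataFrame,
    min_log2cpm: float = 5.0,
    min_abs_lfc: float = 1.0,
    min_sig_contrasts: int = 3,
) -> set[str]:
    """The DE selection rule over a pooled result table.

    A miRNA is differentially expressed iff its mean log2CPM exceeds
    *min_log2cpm*, it has at least one significant contrast, and either a
    significant contrast with |log2FC| > *min_abs_lfc* exists or it has at
    least *min_sig_contrasts* significant contrasts.
    """
    de = set()
    for mirna, sub in results.groupby("mirna"):
        if float(sub["mean_log2cpm"].iloc[0]) <= min_log2cpm:
            continue
        sig = sub[sub["significant"]]
        if len(sig) == 0:
            continue
        if (sig["log2fc"].abs() > min_abs_lfc).any() or len(sig) >= min_sig_contrasts:
            de.add(mirna)
    return de
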