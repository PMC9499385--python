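"""Diversity and global-structure summaries of miRNA profiles.

Shannon alpha diversity on CPM values (natural log), per-sample detected
species counts, top-N concentration per group, detected-set overlap across
groups, and PCA of per-miRNA centred/unit-variance-scaled log2CPM
profiles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .errors import InputError


def shannon_index(values) -> float:
    """Shannon diversity H = -sum p_i ln p_i over positive entries.

    Scale-invariant in the input vector; natural logarithm, so H is at
    most ln(number of positive entries).
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise InputError("abundances must be nonnegative")
    v = v[v > 0]
    if v.size == 0:
        raise InputError("all-zero vector: diversity undefined")
    return float(entropy(v))  # scipy normalises to probabilities


def detected_per_sample(cpm_df: pd.DataFrame, threshold: float = 2.0) -> pd.Series:
    """Number of miRNAs with CPM strictly above *threshold* per sample."""
    return (cpm_df > threshold).sum(axis=0)


def topn_fraction(cpm_df: pd.DataFrame, sample_ids, n: int = 20) -> float:
    """Share of a group's total mean CPM carried by its top-*n* miRNAs.

    miRNAs are ranked by mean CPM within the group; if fewer than *n*
    exist the fraction is 1 and a warning is emitted.
    """
    sub = cpm_df[list(sample_ids)]
    if sub.shape[1] == 0:
        raise InputError("group has no samples")
    mean = sub.mean(axis=1)
    if len(mean) < n:
        warnings.warn(f"only {len(mean)} miRNAs available for top-{n} fraction")
    top = mean.sort_values(ascending=False).head(n)
    total = mean.sum()
    return float(top.sum() / total) if total > 0 else 0.0


def group_overlap(detected_sets: dict[str, set]) -> dict[str, int]:
    """Counts for every region of the set partition over >= 2 groups.

    Keys are '&'-joined sorted group subsets (e.g. ``"ACD&EDTA"``); each
    element of the union is counted in exactly one region, so region counts
    sum to the union size.
    """
    if len(detected_sets) < 2:
        raise InputError("need at least two groups")
    groups = sorted(detected_sets)
    universe = set().union(*detected_sets.values())
    out: dict[str, int] = {}
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            inside = set(universe)
            for g in combo:
                inside &= detected_sets[g]
            for g in groups:
                if g not in combo:
                    inside -= detected_sets[g]
            out["&".join(combo)] = len(inside)
    return out


def detected_sets_by_group(
    cpm_df: pd.DataFrame, groups: pd.Series, min_cpm: float = 2.0, min_samples: int = 2
) -> dict[str, set]:
    """Group-wise detection rule for the overlap partition.

    A miRNA is detected in a group when CPM > *min_cpm* in at least
    *min_samples* samples of that group (the global 10-of-30 rule scaled
    to group size).
    """
    sets: dict[str, set] = {}
    for g in groups.unique():
        cols = groups.index[groups == g]
        above = (cpm_df[cols] > min_cpm).sum(axis=1)
        sets[g] = set(cpm_df.index[above >= min_samples])
    return sets


@dataclass
class PCAResult:
    scores: pd.DataFrame  # sample x PC
    loadings: pd.DataFrame  # miRNA x PC
    variance_fractions: pd.Series


def pca_profiles(log2cpm_df: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of samples over centred, unit-variance-scaled miRNA profiles.

    Rows are miRNAs, columns samples (the sequencing convention). Constant
    rows are dropped with a warning. Loadings are orthonormal; each
    component is oriented so its largest-magnitude loading is positive,
    which fixes the sign deterministically.
    """
    if log2cpm_df.shape[1] < 3:
        raise InputError("need at least 3 samples for PCA")
    X = log2cpm_df.T  # samples x features
    sd = X.std(axis=0, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"dropping {len(constant)} constant miRNA row(s) before PCA")
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    Z = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if len(S) else 0
    k = rank if n_components is None else n_components
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; truncating")
        k = rank
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic orientation: largest-|loading| positive per component
    for i in range(k):
        j = int(np.abs(Vt[i]).argmax())
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    pcs = [f"PC{i + 1}" for i in range(k)]
    var = S**2
    total_var = (Z.to_numpy() ** 2).sum()
    return PCAResult(
        scores=pd.DataFrame(U * S, index=X.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=pcs),
        variance_fractions=pd.Series(var / total_var, index=pcs),
    )
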