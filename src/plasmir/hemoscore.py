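"""Hemolysis and cell-of-origin statistics.

Free hemoglobin absorbs at 414 nm; the lipemia-independent hemolysis score
combines the 414 and 385 nm absorbances (1 mm path) as

    HS = (A414 - A385) + 0.16 * A385.

miRNA-based hemolysis indicators contrast the strongly RBC-enriched
miR-451a against hemolysis-insensitive miR-23a-3p: on sequencing data as a
log2CPM difference, on qPCR data as dCq(miR-23a-3p - miR-451a). The
RBC-Platelet miRNA ratio is the absolute difference between mean Cq of an
RBC trio (miR-451a, miR-92a-3p, miR-16-5p) and a platelet quartet
(miR-223-3p, miR-126-3p, miR-21-5p, miR-150-5p). Origin fractions
decompose TMM-normalised CPM mass over the RBC-derived /
platelet-derived / hemolysis-susceptible / other panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, InputError

MIR_RBC_SENTINEL = "hsa-miR-451a"
MIR_HEMOLYSIS_STABLE = "hsa-miR-23a-3p"
MIR_QPCR_RBC_TRIO = ("hsa-miR-451a", "hsa-miR-92a-3p", "hsa-miR-16-5p")
MIR_QPCR_PLATELET_QUARTET = ("hsa-miR-223-3p", "hsa-miR-126-3p", "hsa-miR-21-5p", "hsa-miR-150-5p")


@dataclass
class OriginPanels:
    """Cell-of-origin miRNA panels; study inputs, not algorithm outputs.

    Members appearing in both the RBC and platelet sets are resolved to
    the RBC set (the convention for miR-191-5p, which is abundant in both
    cell types); the resolution is deterministic and logged.
    """

    rbc_derived: frozenset[str]
    platelet_derived: frozenset[str]
    hemolysis_susceptible: frozenset[str] = frozenset()
    conflicts: tuple[str, ...] = ()

    @classmethod
    def resolve(
        cls,
        rbc_derived,
        platelet_derived,
        hemolysis_susceptible=(),
    ) -> "OriginPanels":
        rbc = set(rbc_derived)
        plt = set(platelet_derived)
        shared = sorted(rbc & plt)
        if shared:
            warnings.warn(f"panel members in both RBC and platelet sets assigned to RBC: {shared}")
        plt -= rbc
        hemo = set(hemolysis_susceptible) - rbc - plt
        return cls(
            rbc_derived=frozenset(rbc),
            platelet_derived=frozenset(plt),
            hemolysis_susceptible=frozenset(hemo),
            conflicts=tuple(shared),
        )

    def validate_disjoint(self) -> None:
        if self.rbc_derived & self.platelet_derived or (self.rbc_derived | self.platelet_derived) & self.hemolysis_susceptible:
            raise ConfigurationError("origin panels overlap after conflict resolution")

    @classmethod
    def default(cls) -> "OriginPanels":
        """The shipped top-10 panels (sentinel members only; synthetic
        cohorts extend them from ground truth)."""
        return cls.resolve(
            rbc_derived=["hsa-miR-451a", "hsa-miR-486-5p", "hsa-miR-92a-3p", "hsa-miR-16-5p", "hsa-miR-191-5p"],
            platelet_derived=["hsa-miR-223-3p", "hsa-miR-126-3p", "hsa-miR-21-5p", "hsa-miR-150-5p", "hsa-miR-23a-3p"],
        )


def hemolysis_score(a414: float, a385: float) -> float:
    """HS = (A414 - A385) + 0.16 * A385; linear in both absorbances."""
    if a414 < 0 or a385 < 0:
        warnings.warn("negative absorbance (blank subtraction?); HS computed anyway")
    return (a414 - a385) + 0.16 * a385


def hemolysis_scores(absorbance: pd.DataFrame) -> pd.Series:
    """Vectorised HS over a (sample x [A385, A414]) table."""
    return (absorbance["A414"] - absorbance["A385"]) + 0.16 * absorbance["A385"]


def seq_hemolysis_ratio(log2cpm_df: pd.DataFrame, sample: str | None = None):
    """Sequencing-based hemolysis ratio: log2CPM(miR-451a) - log2CPM(miR-23a-3p)."""
    for m in (MIR_RBC_SENTINEL, MIR_HEMOLYSIS_STABLE):
        if m not in log2cpm_df.index:
            raise InputError(f"sentinel miRNA absent from expression matrix: {m}")
    diff = log2cpm_df.loc[MIR_RBC_SENTINEL] - log2cpm_df.loc[MIR_HEMOLYSIS_STABLE]
    return float(diff[sample]) if sample is not None else diff


def qpcr_hemolysis_dcq(cq: pd.DataFrame, sample: str | None = None):
    """qPCR hemolysis ratio: dCq = Cq(miR-23a-3p) - Cq(miR-451a)."""
    for m in (MIR_HEMOLYSIS_STABLE, MIR_RBC_SENTINEL):
        if m not in cq.index:
            raise InputError(f"assay missing from Cq table: {m}")
    diff = cq.loc[MIR_HEMOLYSIS_STABLE] - cq.loc[MIR_RBC_SENTINEL]
    return float(diff[sample]) if sample is not None else diff


def rbc_platelet_ratio(
    cq: pd.DataFrame,
    sample: str | None = None,
    rbc_assays: tuple[str, ...] = MIR_QPCR_RBC_TRIO,
    platelet_assays: tuple[str, ...] = MIR_QPCR_PLATELET_QUARTET,
):
    """|mean Cq(RBC trio) - mean Cq(platelet quartet)| per sample."""
    for m in (*rbc_assays, *platelet_assays):
        if m not in cq.index:
            raise InputError(f"assay missing from Cq table: {m}")
    diff = (cq.loc[list(rbc_assays)].mean(axis=0) - cq.loc[list(platelet_assays)].mean(axis=0)).abs()
    return float(diff[sample]) if sample is not None else diff


def origin_fractions(
    norm_cpm: pd.DataFrame,
    panels: OriginPanels,
    groups: pd.Series,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Panel mass fractions of summed normalised CPM, per group.

    Returns (fractions, compositions): *fractions* has one row per group
    and columns (rbc_derived, platelet_derived, hemolysis_susceptible,
    other) summing to 1; *compositions* gives, per panel, each member's
    share within the panel per group.
    """
    panels.validate_disjoint()
    cats = {
        "rbc_derived": [m for m in norm_cpm.index if m in panels.rbc_derived],
        "platelet_derived": [m for m in norm_cpm.index if m in panels.platelet_derived],
        "hemolysis_susceptible": [m for m in norm_cpm.index if m in panels.hemolysis_susceptible],
    }
    assigned = set().union(*cats.values())
    cats["other"] = [m for m in norm_cpm.index if m not in assigned]

    rows = {}
    for g in groups.unique():
        cols = groups.index[groups == g]
        total = norm_cpm[cols].to_numpy().sum()
        if total <= 0:
            raise InputError(f"group {g}: zero total expression")
        rows[g] = {k: norm_cpm.loc[v, cols].to_numpy().sum() / total for k, v in cats.items()}
    fractions = pd.DataFrame(rows).T[["rbc_derived", "platelet_derived", "hemolysis_susceptible", "other"]]

    compositions = {}
    for k in ("rbc_derived", "platelet_derived", "hemolysis_susceptible"):
        members = cats[k]
        if not members:
            continue
        comp = {}
        for g in groups.unique():
            cols = groups.index[groups == g]
            mass = norm_cpm.loc[members, cols].sum(axis=1)
            comp[g] = mass / mass.sum() if mass.sum() > 0 else mass
        compositions[k] = pd.DataFrame(comp)
    return fractions, compositions
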