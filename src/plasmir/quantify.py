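"""Read-to-miRNA assignment, isomiR classification, counting and filtering.

Assignment is a gapless placement of a cleaned read against each mature
sequence, allowing end offsets of up to ``max_shift`` nt on either side.
Offsets follow the isomiR sign convention: ``offset5`` positive = 5'
trimming, negative = 5' extension; ``offset3`` positive = 3' extension,
negative = 3' trimming. Bases inside the canonical mature span may carry up
to ``max_mismatch`` mismatches (these become the "polymorphic" class);
bases beyond the canonical ends are compared to the hairpin context only to
decide templated vs non-templated extension and do not consume the
mismatch budget. The best candidate has the fewest internal mismatches,
then the smallest ``|offset5| + |offset3|``, then the lexicographically
smallest miRNA name. Reads with no candidate are unaligned.

The module also owns the count-level filters used downstream: the noisy-row
filter (mean count <= 2 AND zero in >= 90% of samples), CPM computation,
the expression filter (CPM > 2 in >= 10 samples), the isoform filter and
the per-sample QC gates (< 15% miRNA reads; > 50% unaligned).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .reference import MiRNAReference

_VALID = set("ACGTN")

CLASS_LABELS = (
    "canonical",
    "trim3",
    "ext3_templated",
    "ext3_nontemplated",
    "trim5",
    "ext5_templated",
    "ext5_nontemplated",
    "polymorphic",
)


@dataclass
class CountMatrix:
    """miRNA x sample integer counts plus per-sample metadata.

    ``samples`` is indexed by sample id and carries at least ``subject_id``
    and ``group``; quantification adds ``percent_mirna_reads`` and
    ``unaligned_pct``, and the QC gate adds exclusion flags.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InputError("negative counts")
        missing = [c for c in self.counts.columns if c not in self.samples.index]
        if missing:
            raise InputError(f"samples without metadata: {missing}")
        self.samples = self.samples.loc[self.counts.columns]

    def subset_samples(self, keep: Iterable[str]) -> "CountMatrix":
        keep = list(keep)
        return CountMatrix(counts=self.counts[keep].copy(), samples=self.samples.loc[keep].copy())

    def subset_mirnas(self, keep: Iterable[str]) -> "CountMatrix":
        keep = list(keep)
        return CountMatrix(counts=self.counts.loc[keep].copy(), samples=self.samples.copy())

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class Assignment:
    """Best placement of one read on the reference."""

    mirna: str
    read_sequence: str
    offset5: int
    offset3: int
    n_internal_mismatches: int


@dataclass(frozen=True)
class IsomiRAnnotation:
    """One read's position in the isomiR taxonomy."""

    mirna_name: str
    read_sequence: str
    offset5: int
    offset3: int
    ext3_templated: bool | None
    ext5_templated: bool | None
    internal_mismatches: tuple[tuple[int, str, str], ...]
    class_labels: frozenset[str]


# --------------------------------------------------------------------------
# alignment


class ReadAligner:
    """Precomputed placement windows for every mature, grouped by read length.

    For read length L and a mature of length M anchored at [start, end) on
    its hairpin, each 5' offset o5 in [-max_shift, max_shift] implies
    o3 = L - M + o5; placements with |o3| <= max_shift give a hairpin
    window of exactly L positions (positions outside the hairpin are
    fillers that can never match). Batch assignment is a vectorized
    mismatch count of the read against all windows of its length.
    """

    def __init__(self, reference: MiRNAReference, max_shift: int = 3, max_mismatch: int = 2):
        self.reference = reference
        self.max_shift = max_shift
        self.max_mismatch = max_mismatch
        self._name_rank = {m: i for i, m in enumerate(sorted(reference.names))}
        self._by_length: dict[int, dict] = {}

    def _index_for_length(self, L: int) -> dict:
        if L in self._by_length:
            return self._by_length[L]
        windows, internal, meta = [], [], []
        for rec in self.reference.matures:
            hp = self.reference.hairpins[rec.hairpin_id]
            M = rec.end - rec.start
            for o5 in range(-self.max_shift, self.max_shift + 1):
                o3 = L - M + o5
                if abs(o3) > self.max_shift:
                    continue
                s = rec.start + o5
                win = np.zeros(L, dtype=np.uint8)
                internal_mask = np.zeros(L, dtype=bool)
                for k in range(L):
                    p = s + k
                    if 0 <= p < len(hp):
                        win[k] = ord(hp[p])
                    internal_mask[k] = rec.start <= p < rec.end
                windows.append(win)
                internal.append(internal_mask)
                meta.append((rec.name, o5, o3))
        idx = {
            "windows": np.array(windows, dtype=np.uint8) if windows else np.zeros((0, L), np.uint8),
            "internal": np.array(internal, dtype=bool) if internal else np.zeros((0, L), bool),
            "meta": meta,
            "penalty": np.array(
                [abs(o5) + abs(o3) for (_, o5, o3) in meta], dtype=np.int64
            ),
            "rank": np.array([self._name_rank[m] for (m, _, _) in meta], dtype=np.int64),
        }
        self._by_length[L] = idx
        return idx

    def assign(self, read: str) -> Assignment | None:
        if not set(read) <= _VALID:
            raise InputError(f"read contains non-ACGTN characters: {read!r}")
        idx = self._index_for_length(len(read))
        if len(idx["meta"]) == 0:
            return None
        r = np.frombuffer(read.encode(), dtype=np.uint8)
        mm = ((idx["windows"] != r) & idx["internal"]).sum(axis=1)
        valid = mm <= self.max_mismatch
        if not valid.any():
            return None
        score = mm * 1_000_000 + idx["penalty"] * 10_000 + idx["rank"]
        score = np.where(valid, score, np.iinfo(np.int64).max)
        best = int(score.argmin())
        name, o5, o3 = idx["meta"][best]
        return Assignment(
            mirna=name,
            read_sequence=read,
            offset5=o5,
            offset3=o3,
            n_internal_mismatches=int(mm[best]),
        )

    def assign_many(self, reads: Iterable[str]) -> list[Assignment | None]:
        # group by (length, sequence) so repeated isomiRs are aligned once
        cache: dict[str, Assignment | None] = {}
        out = []
        for read in reads:
            if read not in cache:
                cache[read] = self.assign(read)
            out.append(cache[read])
        return out


def assign_read(
    read: str, reference: MiRNAReference, max_shift: int = 3, max_mismatch: int = 2
) -> Assignment | None:
    """Assign one read; see :class:`ReadAligner` for the policy."""
    key = (max_shift, max_mismatch)
    cache = getattr(reference, "_aligner_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(reference, "_aligner_cache", cache)
    if key not in cache:
        cache[key] = ReadAligner(reference, max_shift, max_mismatch)
    return cache[key].assign(read)


def classify_isomir(assignment: Assignment, reference: MiRNAReference) -> IsomiRAnnotation:
    """Expand an assignment into the full isomiR taxonomy record.

    A 3' (resp. 5') extension is templated iff every extended base equals
    the hairpin base at the corresponding position; extension beyond the
    hairpin boundary is non-templated by definition.
    """
    rec = reference[assignment.mirna]
    hp = reference.hairpins[rec.hairpin_id]
    o5, o3 = assignment.offset5, assignment.offset3
    read = assignment.read_sequence
    M = rec.end - rec.start
    if len(read) != M - o5 + o3:
        raise InputError("assignment offsets inconsistent with read length")
    s = rec.start + o5

    mismatches = []
    for p in range(max(rec.start, s), min(rec.end, rec.end + o3)):
        rbase = read[p - s]
        if hp[p] != rbase:
            mismatches.append((p - s, hp[p], rbase))

    ext3_templated: bool | None = None
    if o3 > 0:
        ext3_templated = all(
            p < len(hp) and hp[p] == read[p - s] for p in range(rec.end, rec.end + o3)
        )
    ext5_templated: bool | None = None
    if o5 < 0:
        ext5_templated = all(p >= 0 and hp[p] == read[p - s] for p in range(s, rec.start))

    labels = set()
    if o5 == 0 and o3 == 0 and not mismatches:
        labels.add("canonical")
    if o3 < 0:
        labels.add("trim3")
    if o3 > 0:
        labels.add("ext3_templated" if ext3_templated else "ext3_nontemplated")
    if o5 > 0:
        labels.add("trim5")
    if o5 < 0:
        labels.add("ext5_templated" if ext5_templated else "ext5_nontemplated")
    if mismatches:
        labels.add("polymorphic")
    return IsomiRAnnotation(
        mirna_name=assignment.mirna,
        read_sequence=read,
        offset5=o5,
        offset3=o3,
        ext3_templated=ext3_templated,
        ext5_templated=ext5_templated,
        internal_mismatches=tuple(mismatches),
        class_labels=frozenset(labels),
    )


# --------------------------------------------------------------------------
# counting


def count_samples(
    reads_per_sample: Mapping[str, Iterable[str]] | Iterable[tuple[str, Iterable[str]]],
    reference: MiRNAReference,
    metadata: pd.DataFrame | None = None,
    max_shift: int = 3,
    max_mismatch: int = 2,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Assign every read of every sample and aggregate.

    Returns the pooled-isoform count matrix (one row per miRNA) and the
    isomiR tally table, keyed by exact read sequence, with class labels,
    offsets and per-sample counts. ``percent_mirna_reads`` and
    ``unaligned_pct`` (relative to the cleaned reads given here) are
    recorded in the sample metadata.
    """
    if not isinstance(reads_per_sample, Mapping):
        pairs = list(reads_per_sample)
        ids = [s for s, _ in pairs]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate sample IDs")
        reads_per_sample = dict(pairs)

    from collections import Counter

    aligner = ReadAligner(reference, max_shift, max_mismatch)
    samples = list(reads_per_sample)
    per_sample_counts: dict[str, Counter] = {}
    tallies: dict[tuple[str, str], dict] = {}
    pct_mirna, pct_unaligned = {}, {}
    for sample in samples:
        reads = list(reads_per_sample[sample])
        ctr = per_sample_counts.setdefault(sample, Counter())
        assigned = 0
        for read, asg in zip(reads, aligner.assign_many(reads)):
            if asg is None:
                continue
            assigned += 1
            ctr[asg.mirna] += 1
            key = (asg.mirna, read)
            if key not in tallies:
                ann = classify_isomir(asg, reference)
                tallies[key] = {
                    "mirna": asg.mirna,
                    "sequence": read,
                    "offset5": asg.offset5,
                    "offset3": asg.offset3,
                    "labels": ";".join(sorted(ann.class_labels)),
                    "per_sample": dict.fromkeys(samples, 0),
                }
            tallies[key]["per_sample"][sample] += 1
        total = len(reads)
        pct_mirna[sample] = 100.0 * assigned / total if total else 0.0
        pct_unaligned[sample] = 100.0 * (total - assigned) / total if total else 0.0

    counts = pd.DataFrame(
        {s: [per_sample_counts[s].get(m, 0) for m in reference.names] for s in samples},
        index=reference.names,
        dtype=np.int64,
    )
    if metadata is not None:
        meta = metadata.loc[samples].copy()
    else:
        meta = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    meta["percent_mirna_reads"] = pd.Series(pct_mirna)
    meta["unaligned_pct"] = pd.Series(pct_unaligned)

    rows = []
    for key in sorted(tallies):
        t = tallies[key]
        row = {k: t[k] for k in ("mirna", "sequence", "offset5", "offset3", "labels")}
        row.update(t["per_sample"])
        rows.append(row)
    isomirs = pd.DataFrame(rows, columns=["mirna", "sequence", "offset5", "offset3", "labels", *samples])
    return CountMatrix(counts=counts, samples=meta), isomirs


# --------------------------------------------------------------------------
# filters


def filter_noisy(cm: CountMatrix, max_mean: float = 2.0, min_zero_fraction: float = 0.9) -> CountMatrix:
    """Drop rows that are both rare and sparse.

    A miRNA row is removed iff its mean count across samples is <=
    *max_mean* AND it is zero in >= *min_zero_fraction* of samples; all
    other rows pass unchanged.
    """
    if cm.counts.shape[1] < 1:
        raise InputError("need at least one sample")
    mean = cm.counts.mean(axis=1)
    zero_frac = (cm.counts == 0).mean(axis=1)
    keep = ~((mean <= max_mean) & (zero_frac >= min_zero_fraction))
    return cm.subset_mirnas(cm.counts.index[keep])


def cpm(cm: CountMatrix | pd.DataFrame, norm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million over (optionally TMM-scaled) library sizes."""
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    lib = counts.sum(axis=0).astype(float)
    if norm_factors is not None:
        lib = lib * norm_factors.loc[lib.index]
    zero = lib[lib == 0]
    if len(zero):
        raise InputError(f"zero library size for sample(s): {list(zero.index)}")
    return counts / lib * 1e6


def log2cpm(cpm_df: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount); the 1-CPM prior bounds values below at 0."""
    return np.log2(cpm_df + pseudocount)


def expression_filter(cpm_df: pd.DataFrame, min_cpm: float = 2.0, min_samples: int = 10) -> list[str]:
    """Retain miRNAs with CPM strictly above *min_cpm* in >= *min_samples* samples."""
    n_above = (cpm_df > min_cpm).sum(axis=1)
    return list(cpm_df.index[n_above >= min_samples])


def isoform_filter(
    isomirs: pd.DataFrame,
    cpm_df: pd.DataFrame,
    min_cpm: float = 2.0,
    min_samples: int = 10,
    min_mean_count: float = 10.0,
    major_fraction: float = 0.1,
    pooled_counts: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the isoform prevalence filter and report major isoforms.

    An isoform (unique read sequence) is retained iff its parent miRNA has
    CPM > *min_cpm* in >= *min_samples* samples and the isoform's mean read
    count across samples is strictly > *min_mean_count*. The major-isoform
    report lists retained isoforms whose pooled count exceeds
    *major_fraction* of the parent miRNA's pooled count.
    """
    sample_cols = [c for c in isomirs.columns if c not in ("mirna", "sequence", "offset5", "offset3", "labels")]
    unknown = set(isomirs["mirna"]) - set(cpm_df.index)
    if unknown:
        raise InputError(f"isoforms reference unknown miRNAs: {sorted(unknown)[:5]}")
    parent_ok = set(expression_filter(cpm_df, min_cpm, min_samples))
    mean_count = isomirs[sample_cols].mean(axis=1)
    retained = isomirs[isomirs["mirna"].isin(parent_ok) & (mean_count > min_mean_count)].copy()

    if pooled_counts is not None:
        parent_pool = pooled_counts.sum(axis=1)
    else:
        parent_pool = isomirs.groupby("mirna")[sample_cols].sum().sum(axis=1)
    iso_pool = retained[sample_cols].sum(axis=1)
    frac = iso_pool / retained["mirna"].map(parent_pool).replace(0, np.nan)
    major = retained[frac > major_fraction].copy()
    major["fraction_of_mirna"] = frac[frac > major_fraction]
    return retained, major


def sample_qc_gate(
    cm: CountMatrix,
    min_mirna_pct: float = 15.0,
    max_unaligned: float = 50.0,
    strict: bool = True,
) -> tuple[CountMatrix, list[dict]]:
    """Exclude degenerate samples.

    A sample is excluded when its miRNA-read percentage is strictly below
    *min_mirna_pct* ("low_mirna_fraction"); samples whose unaligned-read
    percentage is strictly above *max_unaligned* are flagged
    ("high_unaligned") and excluded too when *strict* is set.
    """
    log: list[dict] = []
    drop = set()
    for sample, row in cm.samples.iterrows():
        pct = row.get("percent_mirna_reads", np.nan)
        una = row.get("unaligned_pct", np.nan)
        if pd.notna(pct) and pct < min_mirna_pct:
            log.append({"sample": sample, "reason": "low_mirna_fraction", "value": float(pct), "excluded": True})
            drop.add(sample)
        elif pd.notna(una) and una > max_unaligned:
            log.append({"sample": sample, "reason": "high_unaligned", "value": float(una), "excluded": strict})
            if strict:
                drop.add(sample)
    kept = [s for s in cm.counts.columns if s not in drop]
    return cm.subset_samples(kept), log
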