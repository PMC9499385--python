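"""Synthetic plasma small-RNA cohorts with known ground truth.

The generator emulates the statistical structure of a crossed
anticoagulant-comparison design: every subject contributes one
platelet-free-plasma sample per blood-collection-tube type (ACD, citrate,
CTAD, EDTA). Each sample draws its miRNA mix from three sources — an
RBC-derived panel, a platelet-derived panel and everything else — on top of
a heavy-tailed per-subject baseline profile (a few species such as miR-451a
and miR-486-5p dominating the library, as real plasma shows). A per-sample
hemolysis fraction, with a strictly larger group mean for EDTA, multiplies
the RBC-panel abundances, which is the mechanism that couples tube type to
profile bias. The same hemolysis fraction drives spectrophotometric
absorbances (A414/A385) and, through a log-linear map, the qPCR Cq tables,
so every downstream statistic (hemolysis score, dCq ratios, origin
fractions, differential expression) has a known truth to recover.

Reads are emitted as single-end FASTQ in the randomized-adapter library
layout: 4 random bases on each side of the insert followed by the 3'
adapter TGGAATTCTCGGGTGCCAAGG. Inserts carry configurable isomiR variation
(3'/5' trimming, templated and non-templated extensions, internal
single-base substitutions). Occasional degenerate samples are diluted with
uniform-random inserts and a collapsed qPCR yield, to exercise the QC
gates downstream. All randomness derives from one seed via independent
substreams.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .reference import MatureRecord, MiRNAReference
from .quantify import CountMatrix

ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"

#: Mature sequences of the qPCR assay panel (DNA alphabet, U->T).
SENTINEL_SEQUENCES: dict[str, str] = {
    "hsa-miR-451a": "AAACCGTTACCATTACTGAGTT",
    "hsa-miR-23a-3p": "ATCACATTGCCAGGGATTTCC",
    "hsa-miR-16-5p": "TAGCAGCACGTAAATATTGGCG",
    "hsa-miR-92a-3p": "TATTGCACTTGTCCCGGCCTGT",
    "hsa-miR-223-3p": "TGTCAGTTTGTCAAATACCCCA",
    "hsa-miR-126-3p": "TCGTACCGTGAGTAATAATGCG",
    "hsa-miR-21-5p": "TAGCTTATCAGACTGATGTTGA",
    "hsa-miR-150-5p": "TCTCCCAACCCTTGTACCAGTG",
    "hsa-miR-30e-5p": "TGTAAACATCCTTGACTGGAAG",
}

SENTINEL_ORDER: tuple[str, ...] = (
    "hsa-miR-451a",
    "hsa-miR-23a-3p",
    "hsa-miR-486-5p",
    "hsa-miR-92a-3p",
    "hsa-miR-16-5p",
    "hsa-miR-223-3p",
    "hsa-miR-126-3p",
    "hsa-miR-21-5p",
    "hsa-miR-150-5p",
    "hsa-miR-30e-5p",
    "hsa-miR-191-5p",
)

#: Baseline relative plasma abundance of the sentinel species (fractions of
#: the miRNA pool, before hemolysis spiking). Chosen so that miR-451a and
#: miR-486-5p jointly carry ~35-40% of reads in unspiked samples and so the
#: log-linear Cq map lands miR-451a near Cq 15.5 and miR-30e-5p near 27.
SENTINEL_BASELINE: dict[str, float] = {
    "hsa-miR-451a": 0.22,
    "hsa-miR-486-5p": 0.15,
    "hsa-miR-16-5p": 0.05,
    "hsa-miR-92a-3p": 0.04,
    "hsa-miR-191-5p": 0.015,
    "hsa-miR-223-3p": 0.02,
    "hsa-miR-126-3p": 0.01,
    "hsa-miR-21-5p": 0.008,
    "hsa-miR-150-5p": 0.004,
    "hsa-miR-23a-3p": 0.01,
    "hsa-miR-30e-5p": 0.00008,
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class IsomiRRates:
    """Per-read probabilities of each isomiR modification (mutually
    exclusive; the remainder is the canonical sequence)."""

    trim3: float = 0.30
    ext3_templated: float = 0.12
    ext3_nontemplated: float = 0.05
    trim5: float = 0.06
    ext5_templated: float = 0.04
    ext5_nontemplated: float = 0.02
    snv: float = 0.05

    def as_probs(self) -> np.ndarray:
        p = np.array(
            [
                self.trim3,
                self.ext3_templated,
                self.ext3_nontemplated,
                self.trim5,
                self.ext5_templated,
                self.ext5_nontemplated,
                self.snv,
            ]
        )
        if (p < 0).any() or p.sum() > 1:
            raise ConfigurationError("isomiR rates must be nonnegative and sum to <= 1")
        return np.concatenate([[1 - p.sum()], p])


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated design: 10 subjects x 4 anticoagulant
    groups, ~350 miRNA species, ~2.2M reads per library with ~75% of reads
    being miRNA, a ~10% rate of degenerate (low-miRNA-fraction) samples,
    and an EDTA-specific elevation of the hemolysis fraction.
    """

    n_subjects: int = 10
    groups: tuple[str, ...] = ("ACD", "Citrate", "CTAD", "EDTA")
    n_mirnas: int = 350
    panel_sizes: tuple[int, int, int] = (10, 10, 8)  # RBC, platelet, hemolysis-susceptible
    hemolysis_mean_per_group: dict[str, float] = field(
        default_factory=lambda: {"ACD": 0.02, "Citrate": 0.02, "CTAD": 0.02, "EDTA": 0.15}
    )
    rbc_spike_coefficient: float = 12.0
    hemo_spike_coefficient: float = 6.0
    library_depth_mean: float = 2_200_000
    depth_log_sd: float = 0.35
    mirna_fraction_mean: float = 0.75
    mirna_fraction_sd: float = 0.08
    dropout_rate: float = 0.10
    degenerate_samples: tuple[str, ...] | None = None  # force specific sample ids
    subject_log_sd: float = 0.05
    isomir_rates: IsomiRRates = field(default_factory=IsomiRRates)
    # absorbance model: A = intercept + slope * hemolysis + noise (1 mm path)
    a414_intercept: float = 0.06
    a414_slope: float = 2.0
    a385_intercept: float = 0.05
    a385_slope: float = 0.6
    absorbance_sd: float = 0.01
    # qPCR model: Cq = intercept - log2(CPM * yield) + noise
    cq_intercept: float = 33.5
    cq_sd: float = 0.1
    degenerate_yield: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("group list must be non-empty")
        if self.n_subjects < 1 or self.n_mirnas < 1:
            raise ConfigurationError("n_subjects and n_mirnas must be positive")
        if set(self.hemolysis_mean_per_group) != set(self.groups):
            raise ConfigurationError("hemolysis_mean_per_group keys must match groups")
        if any(v < 0 for v in self.hemolysis_mean_per_group.values()):
            raise ConfigurationError("hemolysis means must be nonnegative")
        if "EDTA" in self.groups and any(v > 0 for v in self.hemolysis_mean_per_group.values()):
            # all-zero means define a valid pure-null (hemolysis-free) cohort
            edta = self.hemolysis_mean_per_group["EDTA"]
            others = [v for g, v in self.hemolysis_mean_per_group.items() if g != "EDTA"]
            if others and edta <= max(others):
                raise ConfigurationError("EDTA hemolysis mean must strictly exceed every other group")
        if not 0 <= self.dropout_rate <= 1:
            raise ConfigurationError("dropout_rate must be a probability")
        if not 0 < self.mirna_fraction_mean <= 1:
            raise ConfigurationError("mirna_fraction_mean must be in (0, 1]")
        if self.rbc_spike_coefficient < 0 or self.hemo_spike_coefficient < 0:
            raise ConfigurationError("spike coefficients must be >= 0")
        if sum(self.panel_sizes) + 1 > self.n_mirnas:
            raise ConfigurationError("panel sizes exceed the number of miRNAs")


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream recovery checks."""

    hemolysis_fraction: pd.Series  # per sample
    source_proportions: pd.DataFrame  # sample x (rbc, platelet, hemolysis_susceptible, other)
    true_proportions: pd.DataFrame  # miRNA x sample, post-spike, sums to 1 per sample
    subject_baselines: pd.DataFrame  # miRNA x subject
    panels: dict[str, tuple[str, ...]]
    degenerate: pd.Series  # bool per sample
    mirna_fraction: pd.Series  # per sample

    def to_json(self) -> str:
        payload = {
            "hemolysis_fraction": self.hemolysis_fraction.to_dict(),
            "source_proportions": self.source_proportions.to_dict(orient="index"),
            "panels": {k: list(v) for k, v in self.panels.items()},
            "degenerate": {k: bool(v) for k, v in self.degenerate.items()},
            "mirna_fraction": self.mirna_fraction.to_dict(),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    """Bundle of everything one simulated cohort produced."""

    config: CohortConfig
    reference: MiRNAReference
    counts: CountMatrix
    absorbance: pd.DataFrame  # sample x (A385, A414)
    cq: pd.DataFrame  # assay x sample
    metadata: pd.DataFrame  # sample x (subject_id, group)
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        """Write counts/metadata/absorbance/Cq/ground-truth as plain text."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reference.write(outdir / "reference")
        self.counts.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.counts.samples.to_csv(outdir / "metadata.tsv", sep="\t")
        self.absorbance.to_csv(outdir / "absorbance.tsv", sep="\t")
        self.cq.to_csv(outdir / "cq.tsv", sep="\t")
        (outdir / "ground_truth.json").write_text(self.ground_truth.to_json())

    def write_fastq(self, outdir: str | Path, compress: bool = False) -> dict[str, Path]:
        """Emit per-sample FASTQ consistent with the count matrix.

        Every counted miRNA read appears once, wrapped as
        4N + insert + 4N + adapter, with isomiR variation at the configured
        rates; non-miRNA filler reads (uniform-random inserts) are added to
        reach the sample's miRNA read fraction. Deterministic given the
        cohort seed.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rng = np.random.default_rng(np.random.SeedSequence([self.config.seed, 7]))
        paths: dict[str, Path] = {}
        for sample in self.counts.counts.columns:
            path = outdir / (f"{sample}.fastq.gz" if compress else f"{sample}.fastq")
            opener = gzip.open if compress else open
            with opener(path, "wt") as fh:
                n_written = _write_sample_reads(
                    fh,
                    sample,
                    self.counts.counts[sample],
                    self.reference,
                    self.config,
                    float(self.ground_truth.mirna_fraction[sample]),
                    rng,
                )
                if n_written == 0:
                    raise GenerationError(f"sample {sample}: zero reads (empty FASTQ)")
            paths[sample] = path
        return paths


# --------------------------------------------------------------------------
# reference generation


def generate_reference(n_mirnas: int = 350, seed: int = 0) -> MiRNAReference:
    """Build a mature-on-hairpin reference of *n_mirnas* species.

    The qPCR sentinel species come first (their published mature sequences
    where available, pseudo-random otherwise); remaining species are random
    18-25 nt matures. Each mature is embedded in a random hairpin with
    15-25 nt flanks so end-extensions have genuine templated context.
    """
    if n_mirnas < 1:
        raise GenerationError("n_mirnas must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    names: list[str] = list(SENTINEL_ORDER[:n_mirnas])
    seqs: dict[str, str] = {}
    for name in names:
        if name in SENTINEL_SEQUENCES:
            seqs[name] = SENTINEL_SEQUENCES[name]
        else:
            seqs[name] = _random_seq(rng, 22)
    for i in range(len(names), n_mirnas):
        name = f"sim-miR-{i - len(SENTINEL_ORDER) + 1:04d}-{'5p' if i % 2 else '3p'}"
        names.append(name)
        seqs[name] = _random_seq(rng, int(rng.integers(18, 26)))
    matures, hairpins = [], {}
    for name in names:
        mature = seqs[name]
        left = _random_seq(rng, int(rng.integers(15, 26)))
        right = _random_seq(rng, int(rng.integers(15, 26)))
        hid = f"{name}-hp"
        hairpins[hid] = left + mature + right
        matures.append(
            MatureRecord(name=name, sequence=mature, hairpin_id=hid, start=len(left), end=len(left) + len(mature))
        )
    return MiRNAReference(matures=matures, hairpins=hairpins)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.char.decode(_BASES[rng.integers(0, 4, size=length)]))


# --------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: CohortConfig, reference: MiRNAReference | None = None) -> SyntheticCohort:
    """Simulate one cohort under *config*.

    Per sample, true abundances are the subject baseline with RBC-panel
    members multiplied by (1 + rbc_spike_coefficient * hemolysis) and
    hemolysis-susceptible members by (1 + hemo_spike_coefficient *
    hemolysis), renormalized; observed counts are one multinomial draw of
    the sample's miRNA read total from those proportions.
    """
    if config.library_depth_mean <= 0:
        raise GenerationError("library depth must be positive (empty FASTQ otherwise)")
    if reference is None:
        reference = generate_reference(config.n_mirnas, seed=config.seed)
    names = reference.names
    ss = np.random.SeedSequence([config.seed, 2]).spawn(6)
    rng_base, rng_hemo, rng_depth, rng_counts, rng_abs, rng_cq = (np.random.default_rng(s) for s in ss)

    panels = _build_panels(names, config.panel_sizes, rng_base)
    global_w = _global_weights(names, rng_base)

    subjects = [f"s{i + 1:02d}" for i in range(config.n_subjects)]
    baselines = pd.DataFrame(
        {
            s: _renorm(global_w * rng_base.lognormal(0.0, config.subject_log_sd, size=len(names)))
            for s in subjects
        },
        index=names,
    )

    letters = "ABCDEFGH"[: len(config.groups)]
    rows = []
    for subj in subjects:
        for letter, group in zip(letters, config.groups):
            rows.append((f"{subj}{letter}", subj, group))
    meta = pd.DataFrame(rows, columns=["sample_id", "subject_id", "group"]).set_index("sample_id")

    n = len(meta)
    hmeans = meta["group"].map(config.hemolysis_mean_per_group).to_numpy(float)
    # Gamma(shape=2) keeps hemolysis nonnegative with CV ~0.7 at each group
    # mean; low-level in-vitro hemolysis is erratic sample to sample
    hemolysis = np.where(hmeans > 0, rng_hemo.gamma(2.0, np.maximum(hmeans, 1e-300) / 2.0, size=n), 0.0)

    if config.degenerate_samples is not None:
        unknown = set(config.degenerate_samples) - set(meta.index)
        if unknown:
            raise ConfigurationError(f"degenerate_samples not in cohort: {sorted(unknown)}")
        degenerate = meta.index.isin(config.degenerate_samples)
    else:
        degenerate = rng_depth.random(n) < config.dropout_rate

    total_reads = rng_depth.lognormal(np.log(config.library_depth_mean), config.depth_log_sd, size=n)
    frac = np.clip(rng_depth.normal(config.mirna_fraction_mean, config.mirna_fraction_sd, size=n), 0.2, 1.0)
    frac[degenerate] = rng_depth.uniform(0.03, 0.12, size=int(degenerate.sum()))

    rbc_idx = np.isin(names, panels["rbc_derived"])
    hemo_idx = np.isin(names, panels["hemolysis_susceptible"])
    plt_idx = np.isin(names, panels["platelet_derived"])

    true_props = np.empty((len(names), n))
    counts = np.empty((len(names), n), dtype=np.int64)
    for j, (sample, row) in enumerate(meta.iterrows()):
        w = baselines[row["subject_id"]].to_numpy().copy()
        w[rbc_idx] *= 1.0 + config.rbc_spike_coefficient * hemolysis[j]
        w[hemo_idx] *= 1.0 + config.hemo_spike_coefficient * hemolysis[j]
        p = _renorm(w)
        true_props[:, j] = p
        n_mirna_reads = int(round(total_reads[j] * frac[j]))
        counts[:, j] = rng_counts.multinomial(n_mirna_reads, p)

    counts_df = pd.DataFrame(counts, index=names, columns=meta.index)
    samples = meta.copy()
    samples["percent_mirna_reads"] = 100.0 * frac
    samples["unaligned_pct"] = np.where(degenerate, 100.0 * (1 - frac) * 0.9, 100.0 * (1 - frac) * 0.25)
    cm = CountMatrix(counts=counts_df, samples=samples)

    absorbance = pd.DataFrame(
        {
            "A385": config.a385_intercept
            + config.a385_slope * hemolysis
            + rng_abs.normal(0, config.absorbance_sd, size=n),
            "A414": config.a414_intercept
            + config.a414_slope * hemolysis
            + rng_abs.normal(0, config.absorbance_sd, size=n),
        },
        index=meta.index,
    )

    assays = [m for m in SENTINEL_SEQUENCES if m in set(names)]
    yields = np.where(degenerate, config.degenerate_yield, rng_cq.lognormal(0.0, 0.3, size=n))
    cpm_true = true_props * 1e6
    cq = pd.DataFrame(index=assays, columns=meta.index, dtype=float)
    name_pos = {nm: i for i, nm in enumerate(names)}
    for a in assays:
        vals = config.cq_intercept - np.log2(np.maximum(cpm_true[name_pos[a]] * yields, 1e-9))
        cq.loc[a] = vals + rng_cq.normal(0, config.cq_sd, size=n)

    source = pd.DataFrame(
        {
            "rbc": true_props[rbc_idx].sum(axis=0),
            "platelet": true_props[plt_idx].sum(axis=0),
            "hemolysis_susceptible": true_props[hemo_idx].sum(axis=0),
        },
        index=meta.index,
    )
    source["other"] = 1.0 - source.sum(axis=1)

    truth = GroundTruth(
        hemolysis_fraction=pd.Series(hemolysis, index=meta.index),
        source_proportions=source,
        true_proportions=pd.DataFrame(true_props, index=names, columns=meta.index),
        subject_baselines=baselines,
        panels={k: tuple(v) for k, v in panels.items()},
        degenerate=pd.Series(degenerate, index=meta.index),
        mirna_fraction=pd.Series(frac, index=meta.index),
    )
    return SyntheticCohort(
        config=config,
        reference=reference,
        counts=cm,
        absorbance=absorbance,
        cq=cq,
        metadata=meta,
        ground_truth=truth,
    )


def _build_panels(names: list[str], sizes: tuple[int, int, int], rng: np.random.Generator) -> dict[str, list[str]]:
    rbc_seed = ["hsa-miR-451a", "hsa-miR-486-5p", "hsa-miR-92a-3p", "hsa-miR-16-5p", "hsa-miR-191-5p"]
    plt_seed = ["hsa-miR-223-3p", "hsa-miR-126-3p", "hsa-miR-21-5p", "hsa-miR-150-5p", "hsa-miR-23a-3p"]
    rbc = [m for m in rbc_seed if m in names]
    plt = [m for m in plt_seed if m in names]
    pool = [m for m in names if m not in rbc and m not in plt]
    missing = [m for m in rbc_seed + plt_seed if m not in names]
    if missing and len(names) >= len(SENTINEL_ORDER):
        raise ConfigurationError(f"panel members absent from reference: {missing}")
    n_rbc, n_plt, n_hemo = sizes
    need = max(0, n_rbc - len(rbc)) + max(0, n_plt - len(plt)) + n_hemo
    if need > len(pool):
        raise ConfigurationError("not enough miRNAs to fill the origin panels")
    picks = list(rng.choice(pool, size=need, replace=False))
    while len(rbc) < n_rbc:
        rbc.append(picks.pop())
    while len(plt) < n_plt:
        plt.append(picks.pop())
    hemo = picks
    return {"rbc_derived": rbc, "platelet_derived": plt, "hemolysis_susceptible": hemo}


def _global_weights(names: list[str], rng: np.random.Generator) -> np.ndarray:
    w = np.zeros(len(names))
    rest_mass = 1.0 - sum(v for k, v in SENTINEL_BASELINE.items() if k in names)
    other = [i for i, nm in enumerate(names) if nm not in SENTINEL_BASELINE]
    for i, nm in enumerate(names):
        if nm in SENTINEL_BASELINE:
            w[i] = SENTINEL_BASELINE[nm]
    if other:
        # heavy-tailed tail of the profile: a handful of species dominate
        tail = rng.lognormal(0.0, 2.5, size=len(other))
        w[other] = rest_mass * tail / tail.sum()
    return _renorm(w)


def _renorm(w: np.ndarray) -> np.ndarray:
    s = w.sum()
    if s <= 0:
        raise GenerationError("abundance vector sums to zero")
    return w / s


# --------------------------------------------------------------------------
# read emission


def _write_sample_reads(
    fh,
    sample: str,
    counts: pd.Series,
    reference: MiRNAReference,
    config: CohortConfig,
    mirna_fraction: float,
    rng: np.random.Generator,
) -> int:
    probs = config.isomir_rates.as_probs()
    kinds = ["canonical", "trim3", "ext3_t", "ext3_nt", "trim5", "ext5_t", "ext5_nt", "snv"]
    i = 0
    for name, k in counts.items():
        k = int(k)
        if k == 0:
            continue
        rec = reference[name]
        hp = reference.hairpins[rec.hairpin_id]
        choice = rng.choice(len(kinds), size=k, p=probs)
        for c in choice:
            insert = _vary_insert(rec, hp, kinds[c], rng)
            _emit(fh, f"{sample}:{i}", insert, rng)
            i += 1
    n_mirna = i
    if n_mirna > 0 and mirna_fraction < 1.0:
        n_noise = int(round(n_mirna * (1.0 - mirna_fraction) / mirna_fraction))
        for _ in range(n_noise):
            insert = _random_seq(rng, int(rng.integers(18, 26)))
            _emit(fh, f"{sample}:{i}", insert, rng)
            i += 1
    return i


def _vary_insert(rec: MatureRecord, hairpin: str, kind: str, rng: np.random.Generator) -> str:
    seq = rec.sequence
    if kind == "canonical":
        return seq
    if kind == "trim3":
        amt = int(rng.integers(1, 1 + min(3, len(seq) - 16))) if len(seq) > 16 else 0
        return seq[: len(seq) - amt] if amt else seq
    if kind == "trim5":
        amt = int(rng.integers(1, 1 + min(3, len(seq) - 16))) if len(seq) > 16 else 0
        return seq[amt:] if amt else seq
    if kind == "ext3_t":
        amt = int(rng.integers(1, 3))
        amt = min(amt, len(hairpin) - rec.end, 28 - len(seq))
        return seq + hairpin[rec.end : rec.end + amt] if amt > 0 else seq
    if kind == "ext5_t":
        amt = min(1, rec.start, 28 - len(seq))
        return hairpin[rec.start - amt : rec.start] + seq if amt > 0 else seq
    if kind == "ext3_nt":
        if len(seq) >= 28:
            return seq
        templ = hairpin[rec.end] if rec.end < len(hairpin) else None
        base = _other_base(templ, rng)
        return seq + base
    if kind == "ext5_nt":
        if len(seq) >= 28:
            return seq
        templ = hairpin[rec.start - 1] if rec.start > 0 else None
        return _other_base(templ, rng) + seq
    if kind == "snv":
        pos = int(rng.integers(0, len(seq)))
        return seq[:pos] + _other_base(seq[pos], rng) + seq[pos + 1 :]
    raise ValueError(kind)


def _other_base(not_this: str | None, rng: np.random.Generator) -> str:
    options = [b for b in "ACGT" if b != not_this]
    return options[int(rng.integers(0, len(options)))]


def _emit(fh, read_id: str, insert: str, rng: np.random.Generator) -> None:
    seq = _random_seq(rng, 4) + insert + _random_seq(rng, 4) + ADAPTER_3P
    fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
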