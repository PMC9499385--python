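"""End-to-end orchestration: synth/real inputs -> report bundle.

Stage interfaces are files (FASTQ/TSV/JSON), so every stage can be re-run
independently from on-disk intermediates: a synthetic stage writes the
cohort, preprocessing and quantification turn FASTQ + reference into a
count matrix, and the count-level stages (QC, profiles, hemolysis/origin,
differential expression, qPCR) consume the TSVs. The machine-readable
report carries per-stage summaries, the serialized configuration and its
hash; no timestamps, so identical configurations yield identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hemoscore, preprocess, profiles, qpcr, quantify, synthdata
from .diffexpr import fit_pairwise_de, select_de, tmm_factors
from .errors import ConfigurationError, PlasmirError
from .quantify import CountMatrix


@dataclass
class RunConfig:
    """All stage toggles and parameters; defaults are the study values."""

    outdir: str = "plasmir_run"
    seed: int = 0
    # synthetic-cohort stage (None = use the input paths below)
    synth: dict | None = None
    synth_reads: bool = False
    # real inputs (used when synth is None)
    counts_tsv: str | None = None
    metadata_tsv: str | None = None
    absorbance_tsv: str | None = None
    cq_tsv: str | None = None
    fastq_dir: str | None = None
    reference_dir: str | None = None
    # stage toggles
    do_preprocess: bool = True
    do_quantify: bool = True
    do_profiles: bool = True
    do_hemoscore: bool = True
    do_diffexpr: bool = True
    do_qpcr: bool = True
    # parameters
    adapter: str = preprocess.DEFAULT_ADAPTER
    randomized_bases: int = 4
    min_len: int = 16
    max_len: int = 28
    max_shift: int = 3
    max_mismatch: int = 2
    min_cpm: float = 2.0
    min_samples: int = 10
    min_mirna_pct: float = 15.0
    max_unaligned: float = 50.0
    max_mean_cq: float = 25.0
    de_min_log2cpm: float = 5.0
    de_min_abs_lfc: float = 1.0
    de_min_sig_contrasts: int = 3

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the report dict.

    On stage failure the error is re-raised annotated with the stage name;
    outputs of completed stages remain on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.as_dict(), "config_hash": config.hash(), "seed": config.seed, "stages": {}}

    stage = "synth"
    try:
        if config.synth is not None:
            cfg_kwargs = dict(config.synth)
            cfg_kwargs.setdefault("seed", config.seed)
            if "isomir_rates" in cfg_kwargs and isinstance(cfg_kwargs["isomir_rates"], dict):
                cfg_kwargs["isomir_rates"] = synthdata.IsomiRRates(**cfg_kwargs["isomir_rates"])
            for key in ("groups", "panel_sizes", "degenerate_samples"):
                if key in cfg_kwargs and cfg_kwargs[key] is not None:
                    cfg_kwargs[key] = tuple(cfg_kwargs[key])
            cohort_cfg = synthdata.CohortConfig(**cfg_kwargs)
            cohort = synthdata.generate_cohort(cohort_cfg)
            synth_dir = out / "synth"
            cohort.write(synth_dir)
            if config.synth_reads:
                cohort.write_fastq(synth_dir / "fastq")
                config = dataclasses.replace(
                    config,
                    fastq_dir=str(synth_dir / "fastq"),
                    reference_dir=str(synth_dir / "reference"),
                )
            config = dataclasses.replace(
                config,
                counts_tsv=None if config.synth_reads else str(synth_dir / "counts.tsv"),
                metadata_tsv=str(synth_dir / "metadata.tsv"),
                absorbance_tsv=str(synth_dir / "absorbance.tsv"),
                cq_tsv=str(synth_dir / "cq.tsv"),
            )
            report["stages"]["synth"] = {
                "n_samples": int(cohort.counts.counts.shape[1]),
                "n_mirnas": int(cohort.counts.counts.shape[0]),
                "n_degenerate": int(cohort.ground_truth.degenerate.sum()),
            }

        stage = "preprocess+quantify"
        if config.fastq_dir is not None and (config.do_preprocess or config.do_quantify):
            cm, iso_summary = _reads_to_counts(config, out)
            report["stages"]["preprocess"] = iso_summary.pop("preprocess")
            report["stages"]["quantify"] = iso_summary
        elif config.counts_tsv is not None:
            cm = _load_counts(config)
        else:
            raise ConfigurationError("no input: provide synth config, fastq_dir or counts_tsv")

        stage = "sample_qc"
        cm_kept, qc_log = quantify.sample_qc_gate(cm, config.min_mirna_pct, config.max_unaligned)
        report["stages"]["sample_qc"] = {
            "n_input": int(cm.counts.shape[1]),
            "n_retained": int(cm_kept.counts.shape[1]),
            "exclusions": qc_log,
        }
        (out / "qc_log.json").write_text(json.dumps(qc_log, indent=1, sort_keys=True))

        stage = "filtering"
        cm_noise = quantify.filter_noisy(cm_kept)
        cpm_df = quantify.cpm(cm_noise)
        analysis_set = quantify.expression_filter(cpm_df, config.min_cpm, config.min_samples)
        cm_expr = cm_noise.subset_mirnas(analysis_set)
        cpm_expr = cpm_df.loc[analysis_set]
        l2 = quantify.log2cpm(cpm_expr)
        cm_expr.counts.to_csv(out / "counts_filtered.tsv", sep="\t")
        report["stages"]["filtering"] = {
            "n_after_noise_filter": int(cm_noise.counts.shape[0]),
            "n_analysis_mirnas": len(analysis_set),
        }

        groups = cm_expr.samples["group"] if "group" in cm_expr.samples else None

        if config.do_profiles:
            stage = "profiles"
            shannon = cpm_expr.apply(profiles.shannon_index, axis=0)
            detected = profiles.detected_per_sample(cpm_expr, config.min_cpm)
            div = pd.DataFrame({"shannon": shannon, "detected": detected})
            div.to_csv(out / "diversity.tsv", sep="\t")
            prof_report = {
                "mean_shannon": float(shannon.mean()),
                "mean_detected": float(detected.mean()),
            }
            if groups is not None:
                prof_report["topn_fraction_by_group"] = {
                    g: profiles.topn_fraction(cpm_expr, groups.index[groups == g]) for g in sorted(groups.unique())
                }
                overlap = profiles.group_overlap(profiles.detected_sets_by_group(cpm_expr, groups))
                (out / "overlap.json").write_text(json.dumps(overlap, indent=1, sort_keys=True))
                prof_report["overlap_regions"] = overlap
            pca = profiles.pca_profiles(l2)
            pca.scores.iloc[:, :2].to_csv(out / "pca_scores.tsv", sep="\t")
            prof_report["pc_variance_fractions"] = [float(v) for v in pca.variance_fractions.iloc[:5]]
            report["stages"]["profiles"] = prof_report

        norm = tmm_factors(cm_expr)
        norm_cpm = quantify.cpm(cm_expr, norm_factors=norm)

        if config.do_hemoscore:
            stage = "hemoscore"
            hemo_report = {}
            if config.absorbance_tsv:
                absorb = pd.read_csv(config.absorbance_tsv, sep="\t", index_col=0)
                hs = hemoscore.hemolysis_scores(absorb)
                hs.to_frame("HS").to_csv(out / "hemolysis_scores.tsv", sep="\t")
                if groups is not None:
                    hemo_report["mean_hs_by_group"] = {
                        g: float(hs.reindex(groups.index[groups == g]).mean()) for g in sorted(groups.unique())
                    }
            seq_ratio = hemoscore.seq_hemolysis_ratio(quantify.log2cpm(norm_cpm))
            seq_ratio.to_frame("seq_hemolysis_ratio").to_csv(out / "seq_hemolysis_ratio.tsv", sep="\t")
            hemo_report["mean_seq_hemolysis_ratio"] = float(seq_ratio.mean())
            panels = _resolve_panels(config)
            if groups is not None:
                fractions, _ = hemoscore.origin_fractions(norm_cpm, panels, groups)
                fractions.to_csv(out / "origin_fractions.tsv", sep="\t")
                hemo_report["rbc_fraction_by_group"] = {
                    g: float(fractions.loc[g, "rbc_derived"]) for g in fractions.index
                }
            report["stages"]["hemoscore"] = hemo_report

        if config.do_diffexpr and groups is not None and groups.nunique() >= 2:
            stage = "diffexpr"
            res = fit_pairwise_de(cm_expr, norm_factors=norm)
            res.to_csv(out / "de_results.tsv", sep="\t", index=False)
            norm.to_frame("tmm_factor").to_csv(out / "tmm_factors.tsv", sep="\t")
            de_set = select_de(res, config.de_min_log2cpm, config.de_min_abs_lfc, config.de_min_sig_contrasts)
            report["stages"]["diffexpr"] = {
                "n_contrasts": int(res["contrast"].nunique()),
                "n_significant_comparisons": int(res["significant"].sum()),
                "n_de_mirnas": len(de_set),
                "de_mirnas": sorted(de_set),
            }

        if config.do_qpcr and config.cq_tsv:
            stage = "qpcr"
            cq = pd.read_csv(config.cq_tsv, sep="\t", index_col=0)
            retained, cq_log = qpcr.exclude_cq_outliers(cq, config.max_mean_cq)
            cq_r = cq[retained]
            exp_pcr = qpcr.relative_expression(cq_r)
            exp_pcr.to_csv(out / "exp_pcr.tsv", sep="\t")
            qpcr_report: dict = {
                "n_retained": len(retained),
                "exclusions": cq_log,
            }
            if groups is not None:
                stab = qpcr.normfinder_stability(cq_r, cm.samples["group"])
                stab.to_frame("stability").to_csv(out / "normfinder_stability.tsv", sep="\t")
                qpcr_report["most_stable_assay"] = str(stab.index[0])
            if qpcr.REFERENCE_ASSAY in norm_cpm.index:
                exp_cpm = qpcr.exp_from_log2cpm(quantify.log2cpm(norm_cpm))
                shared_targets = [t for t in exp_pcr.index if t in exp_cpm.index and t != qpcr.REFERENCE_ASSAY]
                shared_samples = [s for s in exp_pcr.columns if s in exp_cpm.columns]
                if len(shared_samples) >= 3 and shared_targets:
                    stats_df, paired = qpcr.concordance(exp_cpm.loc[shared_targets], exp_pcr.loc[shared_targets])
                    stats_df.to_csv(out / "concordance.tsv", sep="\t")
                    qpcr_report["median_r2"] = float(stats_df["r2"].median())
                    qpcr_report["median_spearman_rho"] = float(stats_df["spearman_rho"].median())
            else:
                # the reference miRNA can fall below detection in very
                # shallow libraries; concordance is then unavailable
                qpcr_report["reference_mirna_below_detection"] = True
            report["stages"]["qpcr"] = qpcr_report
    except PlasmirError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    validate_report(report)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _load_counts(config: RunConfig) -> CountMatrix:
    counts = pd.read_csv(config.counts_tsv, sep="\t", index_col=0)
    if config.metadata_tsv:
        meta = pd.read_csv(config.metadata_tsv, sep="\t", index_col=0)
    else:
        meta = pd.DataFrame(index=counts.columns)
    return CountMatrix(counts=counts.astype(np.int64), samples=meta)


def _reads_to_counts(config: RunConfig, out: Path) -> tuple[CountMatrix, dict]:
    if config.reference_dir is None:
        raise ConfigurationError("fastq input requires reference_dir")
    from .reference import MiRNAReference

    reference = MiRNAReference.read(config.reference_dir)
    fastqs = sorted(Path(config.fastq_dir).glob("*.fastq*"))
    if not fastqs:
        raise ConfigurationError(f"no FASTQ files under {config.fastq_dir}")
    clean_dir = out / "clean"
    clean_dir.mkdir(parents=True, exist_ok=True)
    pp_stats = {}
    reads_per_sample = {}
    for fq in fastqs:
        sample = fq.name.split(".")[0]
        dest = clean_dir / f"{sample}.fastq"
        st = preprocess.preprocess_fastq(
            fq, dest, config.adapter, config.randomized_bases, config.min_len, config.max_len
        )
        pp_stats[sample] = st.as_dict()
        reads_per_sample[sample] = [seq for _, seq, _ in preprocess._iter_fastq(dest)]
    meta = None
    if config.metadata_tsv:
        meta = pd.read_csv(config.metadata_tsv, sep="\t", index_col=0)
    cm, isomirs = quantify.count_samples(
        reads_per_sample, reference, metadata=meta, max_shift=config.max_shift, max_mismatch=config.max_mismatch
    )
    cm.counts.to_csv(out / "counts.tsv", sep="\t")
    isomirs.to_csv(out / "isomirs.tsv", sep="\t", index=False)
    sample_cols = [c for c in isomirs.columns if c not in ("mirna", "sequence", "offset5", "offset3", "labels")]
    class_fracs = _isomir_class_fractions(isomirs, sample_cols)
    summary = {
        "preprocess": pp_stats,
        "n_assigned_rows": int(cm.counts.to_numpy().sum()),
        "isomir_class_fractions": class_fracs,
    }
    return cm, summary


def _isomir_class_fractions(isomirs: pd.DataFrame, sample_cols: list[str]) -> dict[str, float]:
    if isomirs.empty:
        return {}
    totals = isomirs[sample_cols].sum(axis=1)
    grand = float(totals.sum())
    label_sets = isomirs["labels"].str.split(";")
    fracs: dict[str, float] = {}
    for label in quantify.CLASS_LABELS:
        mask = label_sets.map(lambda ls: label in ls)
        fracs[label] = float(totals[mask].sum() / grand) if grand else 0.0
    return fracs


def _resolve_panels(config: RunConfig) -> hemoscore.OriginPanels:
    # synthetic cohorts carry their panels in ground_truth.json next to counts
    if config.counts_tsv:
        truth = Path(config.counts_tsv).parent / "ground_truth.json"
        if truth.exists():
            data = json.loads(truth.read_text())
            return hemoscore.OriginPanels.resolve(
                data["panels"]["rbc_derived"],
                data["panels"]["platelet_derived"],
                data["panels"]["hemolysis_susceptible"],
            )
    return hemoscore.OriginPanels.default()


# --------------------------------------------------------------------------
# report schema


def report_schema() -> dict:
    with resources.files("plasmir.data").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Validate the report against the checked-in schema (a minimal
    validator supporting type / required / properties)."""
    schema = schema or report_schema()
    _validate(report, schema, "report")


_TYPES = {"object": dict, "array": list, "string": str, "number": (int, float), "integer": int, "boolean": bool}


def _validate(value, schema: dict, path: str) -> None:
    t = schema.get("type")
    if t is not None and not isinstance(value, _TYPES[t]):
        raise ConfigurationError(f"{path}: expected {t}, got {type(value).__name__}")
    if t == "object":
        for key in schema.get("required", []):
            if key not in value:
                raise ConfigurationError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _validate(value[key], sub, f"{path}.{key}")
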