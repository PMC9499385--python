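"""qPCR-side statistics: sample exclusion, relative expression,
NormFinder reference stability and sequencing concordance.
"""

from plasmir import CohortConfig, generate_cohort
from plasmir.qpcr import (
    concordance, exclude_cq_outliers, exp_from_log2cpm,
    normfinder_stability, relative_expression, REFERENCE_ASSAY,
)
from plasmir.quantify import cpm, filter_noisy, log2cpm, sample_qc_gate

cohort = generate_cohort(CohortConfig(seed=1))

retained, log = exclude_cq_outliers(cohort.cq)
print(f"{len(retained)} of {cohort.cq.shape[1]} samples keep mean Cq <= 25")
for entry in log:
    print(f"  excluded {entry['sample']} (mean Cq {entry['value']:.1f})")

cq = cohort.cq[retained]
stability = normfinder_stability(cq, cohort.metadata.loc[retained, "group"])
print("\nNormFinder stability (lower = better reference):")
print(stability.round(3).to_string())

cm, _ = sample_qc_gate(cohort.counts)
l2 = log2cpm(cpm(filter_noisy(cm)))
exp_cpm = exp_from_log2cpm(l2)
exp_pcr = relative_expression(cq[[s for s in retained if s in l2.columns]])
targets = [t for t in exp_pcr.index if t in exp_cpm.index and t != REFERENCE_ASSAY]
stats, _ = concordance(exp_cpm.loc[targets], exp_pcr.loc[targets])
print("\nper-target sequencing vs qPCR concordance:")
print(stats.round(3).to_string())
print("\nEXP values are normalised to miR-30e-5p on both platforms; high")
print("rho/R2 means the two technologies rank the samples the same way.")
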