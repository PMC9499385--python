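"""Generate a synthetic plasma miRNA cohort and inspect its design.

Ten subjects each give four plasma samples, one per anticoagulant tube
(ACD, citrate, CTAD, EDTA). The EDTA tube carries a higher hemolysis
fraction, which spikes RBC-derived miRNAs into those samples.
"""

from plasmir import CohortConfig, generate_cohort
from plasmir.hemoscore import hemolysis_scores

cohort = generate_cohort(CohortConfig(seed=1))

print(f"samples: {cohort.counts.counts.shape[1]}, miRNAs: {cohort.counts.counts.shape[0]}")
print(f"degenerate (low-miRNA) samples: {int(cohort.ground_truth.degenerate.sum())}")

hs = hemolysis_scores(cohort.absorbance)
print("\nmean hemolysis score by tube type:")
print(hs.groupby(cohort.metadata["group"]).mean().round(3).to_string())
print("\nHigher HS means more free hemoglobin; the EDTA group should be the")
print("clear outlier - that is the planted contamination mechanism.")

rbc = cohort.ground_truth.source_proportions["rbc"]
print("\nmean true RBC-derived miRNA fraction by tube type:")
print(rbc.groupby(cohort.metadata["group"]).mean().round(3).to_string())
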