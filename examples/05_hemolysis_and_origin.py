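"""Hemolysis scoring and RBC-vs-platelet origin attribution.

Three independent hemolysis readouts are compared: the spectrophotometric
score HS = (A414 - A385) + 0.16*A385, the sequencing ratio
log2CPM(miR-451a) - log2CPM(miR-23a-3p), and the qPCR ratio
dCq(miR-23a-3p - miR-451a). Origin fractions decompose each group's
TMM-normalised CPM mass over the RBC / platelet / hemolysis panels.
"""

from scipy.stats import spearmanr

from plasmir import CohortConfig, generate_cohort
from plasmir.diffexpr import tmm_factors
from plasmir.hemoscore import (
    OriginPanels, hemolysis_scores, origin_fractions,
    qpcr_hemolysis_dcq, rbc_platelet_ratio, seq_hemolysis_ratio,
)
from plasmir.quantify import cpm, filter_noisy, log2cpm, sample_qc_gate

cohort = generate_cohort(CohortConfig(seed=1))
cm, _ = sample_qc_gate(cohort.counts)
cm = filter_noisy(cm)
groups = cm.samples["group"]

hs = hemolysis_scores(cohort.absorbance).reindex(groups.index)
seq_ratio = seq_hemolysis_ratio(log2cpm(cpm(cm)))
dcq = qpcr_hemolysis_dcq(cohort.cq[groups.index])
print("agreement of the three hemolysis readouts (Spearman rho):")
print(f"  HS  vs seq ratio : {spearmanr(hs, seq_ratio).statistic:.3f}")
print(f"  HS  vs dCq       : {spearmanr(hs, dcq).statistic:.3f}")
print(f"  seq vs dCq       : {spearmanr(seq_ratio, dcq).statistic:.3f}")

ratio = rbc_platelet_ratio(cohort.cq[groups.index])
print("\nmedian qPCR RBC-Platelet miRNA ratio by tube type:")
print(ratio.groupby(groups).median().round(2).to_string())

panels = OriginPanels.resolve(
    *(cohort.ground_truth.panels[k]
      for k in ("rbc_derived", "platelet_derived", "hemolysis_susceptible"))
)
norm_cpm = cpm(cm, norm_factors=tmm_factors(cm))
fractions, _ = origin_fractions(norm_cpm, panels, groups)
print("\norigin fractions of normalised CPM mass (rows sum to 1):")
print(fractions.round(3).to_string())
print("\nEDTA shows the largest RBC-derived share and the smallest")
print("platelet-derived share - the origin shift behind its biased profile.")
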