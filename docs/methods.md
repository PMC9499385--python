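# Methods

This note documents the models and procedures `plasmir` implements, the
assumptions behind its synthetic-cohort generator, the numerical choices
that were genuinely open, and what passing the test suite does and does
not demonstrate.

## Read preprocessing

Reads come from randomized-adapter (4N) single-end small-RNA libraries:
4 random bases + insert + 4 random bases + 3′ adapter
`TGGAATTCTCGGGTGCCAAGG`. Cleaning proceeds in order:

1. **Adapter trimming.** The read is truncated at the *leftmost*
   adapter occurrence. An occurrence is either the full adapter or a
   prefix of it reaching the 3′ terminus with at least 6 matching
   positions; up to `floor(0.1 × matched_length)` mismatches are
   tolerated (mismatches only, no indels). These are the documented
   defaults of the standard trimming tools for this library type. Reads
   with no adapter evidence are discarded rather than kept untrimmed: an
   untrimmed read still carries its 3′ randomized bases at an unknown
   position and cannot be classified downstream.
2. **4N stripping.** The first and last 4 bases of the insert are
   removed; inserts shorter than 9 nt cannot contain a payload and are
   rejected.
3. **Length gate.** Inclusive bounds 16 ≤ length ≤ 28. The bounds are
   inclusive because the removal rule is stated as "less than 16 and
   more than 28".

Quality strings pass through untouched; no quality filtering is applied.
Statistics satisfy a conservation invariant: every input read is counted
in exactly one of {passed, no-adapter, length-rejected}.

## Assignment and isomiR taxonomy

The reference is a set of hairpins, each carrying one mature miRNA at
0-based half-open coordinates, so `hairpin[start:end] == mature`. A
cleaned read is assigned by gapless placement against each mature with
5′/3′ end offsets up to ±3 nt. Sign convention: `offset5 > 0` is 5′
trimming, `< 0` 5′ extension; `offset3 > 0` is 3′ extension, `< 0`
trimming.

Mismatches are counted only inside the canonical mature span and are
bounded by 2. Extension bases are compared with the flanking hairpin
sequence solely to decide *templated* (every extended base matches the
hairpin; an extension beyond the hairpin boundary is non-templated by
definition) versus *non-templated*; they do not consume the mismatch
budget, so mono-adenylation/uridylation events remain assignable at
full stringency. The best candidate minimizes (internal mismatches,
|offset5| + |offset3|, miRNA name) lexicographically — a deterministic,
documented multi-mapping tie-break. The aligner is validated against an
independent brute-force enumeration of all placements.

This replaces a genome-wide remapping step used by reference pipelines
for suppressing false positives; on the synthetic references used here,
cross-mapping is rare and the hairpin-context aligner is self-contained.
Counts on real, deposited data will therefore not numerically match a
genome-aware pipeline (a documented deviation).

Isoform identity is the exact read sequence. Class labels are
non-exclusive except `canonical` (offsets 0, no mismatches), and every
assigned read receives at least one label.

## Filters and QC gates

* Noisy rows: removed iff mean count ≤ 2 **and** zero in ≥ 90% of
  samples ("missing" is read as strictly zero).
* CPM = count / library × 10⁶ with the library recomputed after the
  noisy filter; log₂CPM uses a 1-CPM pseudocount (bounded below at 0).
* Expression filter: CPM strictly > 2 in ≥ 10 samples.
* Isoform filter: parent passes the CPM criterion and the isoform's
  mean read count is strictly > 10; the major-isoform report lists
  retained isoforms above 10% of their parent's pooled count.
* Sample gates: excluded below 15% miRNA reads (strict <); flagged —
  and excluded in strict mode, the default — above 50% unaligned;
  qPCR samples excluded above mean Cq 25 (strict >).

All thresholds are boundary-tested and checked against brute-force
predicate evaluation on random matrices.

## Diversity, overlap and PCA

Shannon index H = −Σ pᵢ ln pᵢ over positive CPM entries (natural log;
scale-invariant; ≤ ln richness). "Detected within a sample" means
CPM > 2, consistent with the global filter; the per-group detection
rule for the overlap partition is CPM > 2 in ≥ 2 samples of the group
(the global 10-of-30 rule scaled to group size — the per-group rule is
not uniquely determined by the source analysis, and this choice is
flagged as such). PCA centres and unit-variance-scales each miRNA's
log₂CPM profile and takes the SVD over samples; components are oriented
so the largest-magnitude loading is positive, which makes runs
deterministic. Constant rows are dropped with a warning.

## Hemolysis and origin statistics

HS = (A414 − A385) + 0.16·A385 on 1 mm-path absorbances; the leading
"∆" in the printed formula is read as the plain difference, the only
available operand. Absorbances are taken as given (no blank handling is
specified). The sequencing hemolysis ratio is
log₂CPM(miR-451a) − log₂CPM(miR-23a-3p); the qPCR analogue is
dCq = Cq(miR-23a-3p) − Cq(miR-451a); the RBC-Platelet miRNA ratio is
the absolute difference between the mean Cq of the RBC trio (451a,
92a-3p, 16-5p) and the platelet quartet (223-3p, 126-3p, 21-5p,
150-5p). Origin panels are *inputs* (shipped defaults, user-overridable);
members claimed by both the RBC and platelet sets are assigned to the
RBC set (the miR-191-5p convention), deterministically and with a
logged warning. Origin fractions decompose each group's summed
TMM-normalised CPM over the panels and sum to 1.

## TMM normalisation

Factors follow the published trimmed-mean-of-M-values definition: the
reference sample is the one whose upper-quartile count fraction is
closest to the mean; for each sample, gene-wise M = log₂ ratios and
A = average log₂ abundances are computed over genes positive in both
libraries, the most extreme 30% of M and 5% of A are rank-trimmed, and
the factor is 2^(precision-weighted mean M), weights being inverse
asymptotic binomial variances. Factors are normalised to multiply
to 1. The implementation is cross-checked in the test suite against
the reference R implementation on random matrices (agreement ~1e-6).

## Differential expression

Per miRNA, counts follow NB(μ, φ) with Var = μ + φμ² and
log μ = Xβ + log(library × TMM factor); X has an intercept, subject
blocks (treatment-coded) and group effects. Gene-wise φ is estimated by
maximizing the Cox–Reid adjusted profile likelihood (IRLS inner loop,
bounded search over log₁₀φ ∈ [−4, 1]); a mean-dispersion trend (binned
medians over average log₂CPM, linearly interpolated, ≤ 10 bins) is used
for the final fits. Gene-level variability enters through the
quasi-dispersion s² = residual deviance / residual df, shrunk toward a
common value by fitting a scaled-F prior on log s² (moment estimation
of the prior df via trigamma inversion). Each pairwise contrast is
tested by refitting with the two groups merged:
F = (deviance_reduced − deviance_full) / s̃², referred to
F(1, d₀ + df_resid). log₂FC comes from a parallel fit on counts
augmented with a library-size-scaled 0.125 prior count, keeping fold
changes finite. p-values are BH-adjusted **pooled across all contrasts
as one family**; "significant" means adjusted p < 0.05 strictly, and
the "≥ 3 significant comparisons" branch of the DE rule counts
contrasts after that pooled adjustment. The expression gate uses the
overall mean log₂CPM (the per-group alternative is not determined by
the source analysis; flagged).

This machinery is authored from the published definitions, not wrapped
around an existing package, and is validated by simulation rather than
bit-match: under null cohorts the raw type-I error at 0.05 sits inside
the binomial interval for 200 genes and pooled-BH DE calls are ~0;
planted 4-fold effects at n = 8/group and dispersion 0.1 are detected
with power > 0.8. A likelihood-ratio mode (`test="lr"`) and a fixed
`dispersion` override exist for methodological experiments; the
blocking demonstration in the tests uses them, because at a known
dispersion the LR test shows the classic pseudoreplication inflation
when subject blocks are omitted, whereas the default QL pipeline's
quasi-dispersion largely absorbs that misspecification (a robustness
property worth knowing in itself).

## qPCR statistics

Cq is treated as a log₂ abundance scale at 100% efficiency (one cycle =
one twofold change); non-detects are disallowed in analysis tables —
every assay must be measured in every retained sample, so no imputation
policy exists to get wrong. EXP = Cq(miR-30e-5p) − Cq(target); EXP
differences between targets are reference-invariant.

Reference stability follows the NormFinder model: per group, a two-way
(assay × sample) decomposition yields residuals whose variance
estimates the intra-group component, σ̂²ᵢ𝓰 = Σⱼz²ᵢ𝓰ⱼ/((n𝓰−1)(1−1/I))
(the 1−1/I correction accounts for residuals summing to zero across
the I assays); the inter-group component dᵢ𝓰 centres each assay's
group-mean deviation, is moment-corrected for sampling noise and
shrunk by γ̂²/(γ̂² + σ̂²ᵢ𝓰/n𝓰); stability = mean over groups of
|d̃ᵢ𝓰| + √(σ̂²ᵢ𝓰/n𝓰), lower = more stable. The exact small-sample
correction constants of the original distribution are not reproducible
from the published text, so these estimators are the package's own,
validated by limiting cases (a constant assay ranks most stable),
invariance to assay-constant and per-sample global shifts (required of
any reference-free log-scale method), and a hand-transcribed oracle.

Concordance between platforms is OLS R² plus Spearman ρ per target over
matched samples (default), or a pooled per-target-mean mode — both are
provided because the source figure caption is ambiguous between them.

## The synthetic-cohort generator

The generator defines the study conditions; downstream code never sees
its internals except through files.

* **Design**: 10 subjects × groups (ACD, Citrate, CTAD, EDTA), one
  sample each, sample IDs `s01A…s10D`.
* **Abundance**: a global profile gives the sentinel assay species
  fixed plasma-realistic masses (miR-451a 22%, miR-486-5p 15%, …,
  miR-30e-5p 0.008%) and distributes the rest over ~339 synthetic
  species with a lognormal(σ = 2.5) heavy tail, so a few species
  dominate, as real plasma shows. Subject baselines multiply each
  species by lognormal(0, 0.05) noise.
* **Hemolysis**: per-sample fraction h ~ Gamma(shape 2) with group
  means 0.02 (citrate family) and 0.15 (EDTA; validation enforces
  strict EDTA dominance whenever any mean is positive, while an
  all-zero configuration is the legitimate null cohort). RBC-panel
  members are multiplied by (1 + 12·h), hemolysis-susceptible members
  by (1 + 6·h), then proportions are renormalised — which passively
  dilutes platelet species, reproducing the observed origin shift. The
  coefficient 12 makes the EDTA top-2 share move from ~37% toward
  ~65%, the reported magnitude.
* **Counts**: one multinomial draw per sample of
  round(depth × miRNA-fraction) reads; depth ~ lognormal around 2.2 M,
  miRNA fraction ~ N(0.75, 0.08). Degenerate samples (rate 0.1, or
  forced IDs) get fractions of 3–12% and a 100-fold collapsed qPCR
  yield, so they trip both the sequencing and the qPCR gates, as the
  same samples did in the emulated study.
* **Reads**: each counted read is emitted once with one modification
  drawn from the isomiR rate table (canonical 0.36, trim3 0.30,
  templated/non-templated 3′ extension 0.12/0.05, 5′ variants
  0.06/0.04/0.02, SNV 0.05 — chosen to match reported class
  fractions), wrapped as 4N + insert + 4N + adapter. Non-miRNA filler
  reads are uniform-random inserts.
* **Absorbance/Cq**: A414 = 0.06 + 2.0·h, A385 = 0.05 + 0.6·h (+N(0,
  0.01) noise); Cq = 33.5 − log₂(CPM × yield) + N(0, 0.1), placing
  miR-451a near Cq 15.5 and miR-30e-5p near 27. The Cq noise SD (0.1
  cycles) is single-replicate repeatability for abundant targets; the
  subject-noise level makes tube-linked hemolysis the dominant axis of
  variation, which the recovery properties of the design require.
* **Seeding**: one global seed drives reference, cohort and read
  emission through independent substreams; identical seeds give
  byte-identical outputs.

**What the generator does not model**, and hence what passing tests do
not show about real data: extracellular-vesicle biology, adapter-
ligation sequence bias, qPCR efficiency curves beyond the log-linear
map, genome-wide cross-mapping, correlated inter-individual biology
(real cohorts have larger and structured subject variation), and any
quantitative hemolysis-to-miRNA transfer coefficient — the spike model
is a free parameter of the simulation, not an estimate.

## Problem sizes and numerics

Tests run cohorts at the full design size (40 samples × 350 miRNAs) at
count level; read-level checks use 4–200 k reads per sample so the
whole suite stays fast. Monte-Carlo properties use 8–50 seeds as
stated per test; correlation properties assert multi-seed means, since
single-seed Spearman values on ~35 samples carry ±0.1 sampling noise.
IRLS uses step-halving with a deviance-increase guard and a 1e−10
relative tolerance; deviance differences are clipped at 0 before the
F-test; the trigamma inversion runs Newton to 1e−10. Degenerate inputs
(all-zero expression vectors, zero libraries, single-sample groups,
missing assays) raise typed errors naming the offender.

## Known limitations

* The aligner is designed for desk-scale references (hundreds of
  hairpins); it indexes placements per read length and is not tuned
  for genome-scale work.
* NormFinder constants are the package's own documented variant (see
  above); rankings on real data may differ slightly from the original
  distribution.
* The DE machinery's agreement with reference implementations is
  statistical (calibration, power, direction), not numerical.
* The pipeline's origin panels default to the shipped sentinel lists
  when no ground-truth file is present; real analyses should supply
  study-specific panels.
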