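# Methods

This note documents the statistical models behind `cytoqtl`, the choices
made where the design was genuinely open, and what validation on
synthetic cohorts does and does not establish.

## Study setting

The package targets drug-sensitivity genetics in small panels of
genotyped, unrelated human cell lines: on the order of n = 68 lines,
genome-wide biallelic SNPs, transcriptome-scale expression
(~18,000 genes at full scale), targeted proteomics (~440 proteins), and a
cytotoxicity phenotype derived from dose–response curves over a fixed
concentration grid (defaults: 50, 100, 175, 250, 375, 500 µM; mean IC50
176.5 µM). All defaults are sized to this setting; tests and examples
scale the feature dimensions down (tens to hundreds of SNPs/genes) to
keep runs in seconds while preserving n = 68, where the statistical
behaviour actually lives.

## Association model

Every scan is ordinary least squares of a trait on the number of
minor-allele copies, with intercept and no covariates — defensible for a
small panel of unrelated donors from one population, and deliberately
free of kinship or principal-component correction (out of scope). The
two-sided p comes from the t distribution with n − 2 degrees of freedom,
and every result satisfies `r² = t² / (t² + n − 2)` exactly. Missing
trait values are handled by pairwise deletion with per-result n recorded.
Degenerate regressions (constant dosage or trait) return a flagged
`p = 1` row instead of raising, so genome-scale scans never abort
mid-run. Protein intensities are regressed as provided; no transform is
applied on the user's behalf.

Thresholds follow the study design they implement: dQTLs at p ≤ 0.001
against log2 IC50, eQTLs/pQTLs at p ≤ 0.0001 against any feature
genome-wide (no cis window), SNP inclusion at MAF ≥ 0.05 and exact-HWE
p ≥ 0.001, protein–phenotype discovery at Benjamini–Hochberg FDR 0.05.

**HWE exact test.** The conditional-on-allele-counts exact test: sum the
probabilities of all heterozygote counts no more probable than the one
observed. Monomorphic sites return p = 1 by convention. Implemented with
log-gamma weights; the test suite checks it against exact rational
enumeration for every configuration with n ≤ 30.

**LD pruning.** The measure is squared Pearson correlation of dosage
vectors. Pruning is greedy keep-best: visit candidates by ascending p
(ties broken by chromosome, position, snp_id); keep a SNP iff its r² with
every kept SNP within 1 Mb on the same chromosome is ≤ 0.2. Both
parameters are configurable; the procedure is deterministic by the stated
tie-break.

## IC50 phenotyping

The dose–response model is the four-parameter logistic
`S(c) = bottom + (top − bottom) / (1 + (c/IC50)^h)`. An unconstrained
4PL on six points is ill-posed, so the fit is hierarchical:

1. plateaus pinned at bottom = 0, top = 100 (the assay normalises to a
   no-drug control), fitting only (log10 IC50, hill slope) with IC50
   bounded to [min conc/10, max conc×10] and hill in [0.05, 10];
2. a free-plateau fit (bottom ∈ [0, 30], top ∈ [70, 130]) replaces it
   only when an extra-sum-of-squares F-test (α = 0.05) prefers it — the
   standard nested-model rule in dose–response fitting.

This matters quantitatively: on noisy six-point curves the free fit's
log2 IC50 error is ~3× the information bound (SD ≈ 0.33 vs ≈ 0.11 log2
units at 5% survival noise), which would attenuate every downstream
genotype–phenotype R² by ~half. The hierarchical fit restores ~93% of the
latent phenotype variance.

Curves that never cross 50% are censored (`above_max` when survival
stays above, `below_min` when the lowest dose is already past the
midpoint) rather than extrapolated; censoring is decided on the data
before any fitting. If the 4PL fails to converge, or the curve rises by
more than 10 percentage points between adjacent doses, the estimator
falls back to interpolating the first 50% crossing on the log
concentration axis. Replicates are expected to be averaged per
concentration upstream; the fit method and residual SSE are recorded per
sample.

Normality of the log2 IC50 vector is checked with the Lilliefors variant
of the Kolmogorov–Smirnov test, because mean and SD are estimated from
the same data — the plain KS test against a fitted normal would be
anti-conservative. Pass/fail is reported at p ≥ 0.05.

**ΔΔCT sign convention.** The standard (Livak) qPCR fold change is
2^(−ΔΔCT); some reports print 2^(+ΔΔCT), which inverts knockdown
direction. Both conventions are implemented (Livak default) and the one
used is recorded in the output — no silent guessing. The two are exact
reciprocals.

## MAF-matched permutation enrichment

The enrichment null must respect allele frequency, since power and QTL
density both track MAF. The frequency axis is cut into bins of width
0.02; each of B = 1000 null sets draws, uniformly without replacement
within each bin, exactly as many universe SNPs as the target set holds in
that bin — exact per-bin count matching, the strictest reading of
"matched distributions", and cheap. Target SNPs remain eligible for
sampling: excluding them would bias expected counts in small universes.
The empirical p is add-one smoothed, `(1 + #{null ≥ obs}) / (1 + B)`, so
p = 0 is impossible and the floor 1/1001 is exactly the "≤ 0.001"
boundary a thousand permutations can certify. Enrichment defaults to the
LD-pruned dQTL set, with a flag to use the unpruned set.

Under a null in which flags are assigned at random at a rate shared by
target and universe, the empirical p is approximately uniform; the
residual discreteness of count ties makes it mildly conservative (the
acceptance suite measures the fraction ≤ 0.05 at ~0.04 over 200
repetitions).

## mRNA-independent protein QTLs

To ask whether a protein QTL acts through transcript abundance, each
protein is residualised on its encoding gene's mRNA (OLS with intercept
over complete pairs) and the scan is repeated on the residuals. A fully
mediated effect — genotype → mRNA → protein — vanishes in the residuals
(exactly, in the zero-noise construction; residuals within rounding error
of zero are snapped to zero so the scan sees a truly degenerate trait). A
direct effect survives. When the transcript is undetected in more than
half the samples (threshold configurable), or unmapped, or constant,
adjustment is impossible; the centred protein values are scanned instead
and every output row carries the `unadjusted_mrna_missing` label — the
situation of a protein whose mRNA is detected in only 3 of 68 lines is
represented this way, with the handful-of-detections default equal to 3.
This is a regression device, not formal mediation analysis; no Sobel test
or causal claim is made.

**A boundary fact worth knowing:** at n = 68 and flagging threshold
p ≤ 10⁻⁴, a direct effect explaining 21% of protein variance has
noncentrality ≈ 4.25 against a critical value ≈ 4.14 — detection power is
~0.5, not high. Effects of this size sit on the significance boundary at
this sample size; the acceptance suite measures this honestly rather than
overstating the power.

## Synthetic cohorts

The generator produces data with exactly the structure the analysis
assumes, plus a ground-truth record.

* **Genotypes.** Independent SNPs are two Bernoulli(MAF) allele draws
  (HWE by construction). LD blocks share a latent equicorrelated Gaussian
  (a Gaussian copula) whose uniforms are thresholded at the HWE
  genotype-class boundaries — marginal HWE preserved, within-block dosage
  correlation ≈ 0.91 at latent ρ = 0.99. Real LD is empirical and
  non-stationary; any stationary block model suffices to exercise the
  pruner and the enrichment matcher, which is all that is claimed.
  Dosages are oriented to minor-allele copies at construction.
* **Effect scaling.** A planted effect with variance fraction v on a
  trait with generating variance T gets slope `β = sign·√(vT / 2f(1−f))`
  against the *population* dosage variance 2f(1−f), not the realized
  sample variance; realized in-sample R² therefore fluctuates around v,
  as effect sizes do in real cohorts, while the recorded population
  quantities reproduce v to 10⁻¹² (tested). Multiple effects on one trait
  must keep Σv < 1; the noise SD absorbs the remainder.
* **Proteins.** Mediated: protein = a·mRNA + noise with a = √(v_p/v_g),
  so the genotype association exists only through the transcript
  (requires v_p ≤ v_g and a planted gene effect). Direct:
  protein = b·dosage + noise. Isoform pairs (e.g. a monomer and a
  multimer band of one gene) are constrained to opposite-sign genotype
  coefficients; planting one side of a pair auto-plants the mirrored
  effect, and same-sign configurations are rejected at validation.
* **Undetected transcripts** are explicit missing values in all but a
  configurable handful of samples (default 3) — not zeros — so the
  conditional module must make a real adjustment decision.
* **Dose–response.** True log2 IC50 = mean + Σβ·dosage + noise, with the
  phenotype SD defaulting to 0.45 log2 units (CV ≈ 31% on the µM scale,
  consistent with the dispersion implied by a 68-line panel with mean
  176.5 µM and SEM 6.6). Survival is the 4PL evaluated on the grid plus
  Gaussian noise (default SD 5% survival), truncated at 0 but not at
  100% — no-drug-normalised readouts do exceed control.
* **Determinism.** Every generator is a pure function of (config, seed);
  the cohort convenience wrapper derives per-stage seeds from one root
  seed in a fixed order, so adding a stage never perturbs earlier ones.

What passing tests on these cohorts shows: the estimators recover planted
truth, the scans are calibrated under the null, the permutation machinery
is exact in its matching and honest in its p-values, and the pipeline is
deterministic. What they do not show: robustness to population structure,
empirical LD, imputation dosage uncertainty, batch effects, or
non-Gaussian expression noise — none of which the generator attempts to
mimic.

## The planted-overlap enrichment study

The headline validation (`cytoqtl.workflows.eqtl_enrichment_study`, also
run by `scripts/acceptance.py`) asks the machinery to detect a strong
planted dQTL–eQTL overlap at n = 68 with 5,000 SNPs. One phenotype cannot
carry ~100 independent detectable effects (their variance fractions would
have to sum far past 1), so the overlap is built the way real GWAS hits
present: two 50-SNP LD blocks whose causal SNPs each explain 36% of
phenotype variance, making every block member a dQTL tag, with the same
causal SNPs each driving three genes (30% variance each) so the blocks
are eQTL-tagged too; 5% of the remaining universe carries one background
eQTL each. Phenotypes go through the full noisy-curve → IC50 → log2 path.
Per-block power analysis at design time put the chance of a block
contributing no dQTLs at ~3%; with two blocks carrying the overlap the
study is robust to either one underperforming. The enrichment is computed
on the unpruned dQTL set — pruning would collapse each block to a single
SNP by design, and the question posed is about the detected set. The
expected outcome is an observed eQTL count far above every one of the
1,000 matched null sets, i.e. the floor empirical p of 1/1001.

## Numerical and degenerate-input policy

* Constant dosage/trait → flagged degenerate result, p = 1.
* Constant or absent mRNA → unadjusted residual path with a warning.
* p = 0 entering Q–Q → clipped to the smallest positive float, warned.
* Empty SNP panel after filtering → warning and empty downstream tables,
  not an error; empty trait matrices → empty results.
* VCF ingestion: multiallelic records skipped (counted), SNPs with > 5%
  missing genotypes dropped, remaining missing dosages mean-imputed;
  HWE is computed from observed hard calls before imputation; positions
  are 1-based throughout.
* TSV readers parse floats in round-trip mode, so write-then-read is
  bit-exact and pipeline reruns from files reproduce in-memory runs.
* The run manifest contains no wall-clock fields; timestamps go to the
  log. This is what makes "rerun ⇒ byte-identical outputs" achievable.

## Known limitations

* No covariates, kinship, or structure correction; applying the scans to
  related samples or mixed populations will inflate test statistics.
* The residual device conditions on a noisily measured mRNA; measurement
  error in the transcript leaves a mediated effect partially visible.
  The synthetic checks quantify this only at the noise levels simulated.
* The 4PL fit assumes a monotone-decreasing response; strongly biphasic
  curves fall back to first-crossing interpolation, which is a summary,
  not a model.
* Exact per-bin MAF matching requires every target-occupied bin to be
  populated in the universe; tiny universes can make matching infeasible
  (reported as an error naming the bin, never silently relaxed).
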