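# Methods

## The problem and the model

Prostate cancer separates into molecular subclasses defined by early,
recurrent somatic lesions (ETS fusions, *SPOP* mutations, *FOXA1*
mutations).  The hypothesis behind this package is that some inherited
regulatory variants act as "triggers": by modulating the expression of
DNA-repair and hormone-regulated genes in benign tissue, they predispose
carriers to a specific early somatic event.  The pipeline operationalizes
that hypothesis in stages:

1. **Functional-variant selection** (`regions`).  Candidate variants are
   restricted to putative active enhancers: positions inside the
   cross-cell-line consensus of H3K4me1 and H3K27ac ChIP-seq peaks and
   outside the H3K4me3 consensus.  A mark's consensus keeps peaks with
   enrichment signal strictly above 5 that are covered over at least half
   their length by peaks of the same mark from other cell lines, then
   merges survivors into disjoint intervals.  Completely dependent
   variants (pairwise D' = 1 and r² = 1) are collapsed to one
   representative.
2. **Trigger scoring** (`expression`, `trigger`).  Expression is
   log2(RPKM+1), quantile-normalized.  For each variant, the expression of
   every eligible panel transcript (normalized value ≥ 1 in at least one
   sample) is regressed on the coded genotype under up to three models:
   dosage (0/1/2 minor-allele count; requires all three genotype classes),
   dominant (carrier indicator), and recessive (minor-homozygote
   indicator), the latter two requiring at least 3 % of samples per coded
   class.  P-values receive a Benjamini–Hochberg adjustment within each
   (variant, model) family; transcripts with FDR ≤ 5 % count as
   associated.  The model with the highest associated percentage defines
   the variant's DnaRep (DNA-repair) and HormReg (hormone-regulated)
   counts, and the trigger score is

       score = ln(DnaRep × HormReg + 1).

   Variants in the top tertile of the positive-score distribution proceed.
   Tissue specificity is assessed by recomputing scores on 100 random
   63-sample subsamples of a non-prostate panel; a variant with no
   positive resampled score is "non-global".
3. **Genotype/phenotype association** (`assoc`).  Variants passing an
   85 % call-rate filter are tested against binary lesion phenotypes by
   logistic regression (allelic/dominant/recessive codings) adjusted for
   age and PSA.  The discovery/validation scheme splits the cohort into
   two status-stratified halves 200 times; a nomination requires BH
   FDR ≤ 20 % in the discovery half and P ≤ 5 % with a concordant effect
   direction in the validation half.  Somatic burden (length-weighted
   genome fraction with |log2 tumor/normal| > 0.15) is compared between
   carriers and non-carriers by Mann–Whitney tests, and ancestry is
   assigned by convex hulls of labeled reference groups in PC1–PC2 of
   variant-standardized dosages.
4. **Regulatory characterization** (`network`, `motif`, `hic`).  The
   variant's associated genes are projected onto a merged interactome
   (edge confidence strictly above 0.7; unscored whitelisted sources kept)
   and the relative size of the largest connected component is compared
   with three resampling nulls; annotation enrichment uses add-one
   permutation P-values.  Allele-specific PWM scans compare best log-odds
   matches (La) against the motif's maximum (Lm) and an empirical null —
   exhaustive over all 4^N sequences for motif length N ≤ 6, otherwise
   10,000 unique random sequences — at a strict (P < 0.001, La/Lm > 0.75)
   or relaxed (P < 0.005, La/Lm > 0.6) tier.  Hi-C "links" are bins with
   anchor contact signal strictly above the 90th percentile; concordance
   between link membership and transcript deregulation (|log2 ratio| ≥ 1
   after flooring sub-1 RPKM values) is tested by Mann–Whitney against
   same-class comparisons and against random same-size gene sets.

## Synthetic data: what it emulates and what it does not

Protected cohort genotypes and expression are replaced by the `synthdata`
generators, whose defaults encode the study conditions: a 63-sample
benign-tissue expression panel; 300 candidate variants with MAF uniform
on [0.05, 0.5] and Hardy–Weinberg genotypes; a 539-patient cohort with
12.1 % lesion incidence and a dominant-model odds ratio of 4.83 at the
planted variant; a planted trigger complement of 14 DNA-repair and 15
hormone-regulated genes whose log2 expression shifts additively with the
planted variant's dosage (default effect −1 log2 unit per allele — the
minor allele downregulates, matching the direction convention); age
~ N(62, 8²) years and PSA ~ N(8, 4²) ng/ml as typical screening-cohort
covariates, with small positive log-odds contributions (0.02/year,
0.01/(ng/ml)).  The logistic intercept is calibrated by root finding so
the mean simulated prevalence equals the target incidence.

Each generator draws from per-entity substreams spawned from one root
seed (`numpy.random.SeedSequence`), so enlarging a simulation never
perturbs earlier entities and identical spec + seed reproduces
byte-identical outputs.

Deliberately absent from the generators: linkage-disequilibrium structure
beyond chance correlation (variants are drawn independently),
read-level sequencing noise, batch effects, population stratification in
the cohort, and non-additive eQTL architectures.  Passing tests therefore
demonstrate that the statistical machinery recovers planted effects and
is calibrated under exchangeable nulls — not that the pipeline is robust
to confounding present in real cohorts.  Notably, even without planted
LD, strong confined eQTL effects occasionally leak into chance-correlated
genotype vectors (small recessive classes are the usual culprits), which
is why planted-variant recovery is stated as a ≥95 %-of-seeds guarantee
rather than a certainty.

## Numerical choices

* **Quantile normalization**: columns are replaced by cross-sample means
  of order statistics; tied values within a sample receive the mean of
  the reference values of their tied rank block.  Note that some
  expression-array workflows call this step "quintile" normalization;
  there is no established quintile-based procedure, and this package
  implements the standard quantile normalization throughout.  "Single-column"
  matrices pass through unchanged (the reference is the column itself).
* **OLS eQTL scan**: vectorized per (variant, model) across transcripts;
  constant transcripts get slope 0 and P = 1; missing genotypes are
  dropped pairwise per variant; P-values are floored at 1e-300.
* **Model tie-break** when two genotype models reach the same associated
  percentage: dosage > dominant > recessive.
* **Logistic regression**: own IRLS implementation (tolerance 1e-8 on the
  maximum coefficient change, 100 iterations), with (quasi-)separation
  flagged when any |coefficient| exceeds 20; such fits are reported
  non-estimable rather than emitted silently.  Agreement with a standard
  maximum-likelihood fit is enforced by test.
* **Proportion tests**: two-sample and one-sample z-tests use the pooled
  variance and a Yates continuity correction, matching the corrected
  chi-square on the equivalent table.
* **Haplotype EM** for D'/r²: only the double heterozygote is
  phase-ambiguous; its cis/trans split is iterated to a log-likelihood
  change below 1e-10 (cap 1000 iterations).  D' = |D|/Dmax; monomorphic
  partners are skipped.
* **Empirical P-values** use the add-one convention (never zero) for all
  sampled nulls; exhaustive motif nulls use the exact count over 4^N.
* **Percentile threshold** for Hi-C links uses linear interpolation
  between order statistics, with strictly-above membership, so link sets
  are invariant under monotone transforms of the signal.
* **PWM scanning**: log-odds in bits against a uniform 0.25 background
  with a pseudocount of 1 % of the column total; both strands scanned;
  windows containing ambiguous bases are skipped.  Only La/Lm ratios and
  empirical ranks feed the filters, so the log base is immaterial.
* **Tertile rule**: the threshold is the empirical 2/3-quantile (linear
  interpolation) of strictly positive scores; zero scores never enter the
  quantile.

## Open design points and how they were resolved

* The ≥50 % consensus-overlap requirement is evaluated against the
  *union* of other-cell-line intervals (total covered bases), which
  handles multi-peak overlap without double counting.
* The BH family for the trigger scan is per (variant, model) — matching
  the per-variant percentage computation; a global family is possible by
  pooling the returned P-values but is not the default.
* The percentage denominator is all eligible transcripts of the combined
  two-panel universe; DnaRep/HormReg counts are split afterwards.
* Discovery/validation partitions use a 50/50 status-stratified split
  without replacement (exposed as a parameter) and additionally require
  direction concordance at validation to exclude sign-flip artifacts.
* Ancestry assignment: targets inside exactly one hull take its label;
  inside several, the nearest group centroid decides; outside all, the
  nearest hull boundary (nearest reference point for degenerate,
  collinear groups).
* Motif nulls draw uniform random sequences rather than genome-resident
  regions; a genome-backed null can be added by scoring windows from a
  supplied FASTA, but uniform composition is the neutral default.
* The reference proportion for the downregulated-majority test is 0.5,
  configurable.

## Problem sizes used in the automated checks

The test and acceptance runs use desk-scale instances chosen as the
package's own verification sizes: 100 simulated cohorts of n = 2000 for
odds-ratio recovery, 100 seeds of a 20-variant / 63-sample panel for
top-rank recovery, one 1000-sample cohort with 200 partitions for the
attribution share, 200 null seeds for each calibration check, and
brute-force oracles on instances small enough to enumerate.  Full-scale
inputs (hundreds of thousands of peaks, 21k variants, 16k-node
interactomes) stream through the same code paths.

## Known limitations

* The empirical-FDR guarantee is verified under a global null; under
  partial alternatives BH still controls FDR but the per-variant
  "positive score" rate depends on effect structure.
* The LCC proportion and enrichment-overlap statistics are discrete, so
  their empirical P-values are super-uniform under the null; uniformity
  is verified on the continuous Hi-C deregulation statistic.
* `specificity_flags` rescans only the supplied records' variants, so
  its runtime grows linearly in resamples × records.
* The minimal VCF writer emits synthetic coordinates and GT fields only;
  it is a fixture format, not a general-purpose VCF emitter.
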