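# triggerscan

Nomination of inherited "trigger" variants that predispose to early
recurrent somatic mutations, with prostate cancer's *SPOP*-mutant
subclass as the motivating case.

Prostate tumors carry early, recurrent, largely mutually exclusive
somatic lesions (ETS fusions, *SPOP* mutations, *FOXA1* mutations).
`triggerscan` implements a complete analysis for asking whether an
inherited regulatory polymorphism predisposes to one of these lesions by
modulating DNA-repair and hormone-regulated transcription in benign
tissue.  It is written for statistical geneticists and computational
biologists who want to run, stress-test, or extend this kind of analysis
on their own cohorts — and, because the original cohorts are protected,
it ships a first-class synthetic-data module so every stage runs at desk
scale.

## The statistic at the core

For a candidate variant *v*, expression of each panel transcript is
regressed on the coded genotype (dosage 0/1/2, dominant, or recessive
coding; each model has genotype-class requirements), with a
Benjamini–Hochberg adjustment within each (variant, model) family at
FDR ≤ 5 %.  Taking the model with the highest fraction of associated
transcripts gives the counts DnaRep (associated DNA-repair transcripts)
and HormReg (associated hormone-regulated transcripts), combined into the
**trigger score**

    score(v) = ln(DnaRep · HormReg + 1)

which is zero unless the variant touches *both* programs and grows with
each count.  Variants in the top tertile of the positive-score
distribution go forward to a 200-fold discovery/validation logistic
association scheme (BH FDR ≤ 20 % to discover, P ≤ 5 % with concordant
direction to validate, cohort splits preserving lesion incidence), and
candidate loci are characterized through protein-interaction connectivity,
allele-specific binding-motif scans (La/Lm log-odds ratios with empirical
nulls — exhaustive over all 4^N sequences for motif length N ≤ 6), and
Hi-C contact/deregulation concordance.

## Worked example

The end-to-end demo simulates a 63-sample expression panel and a
539-patient cohort with one planted trigger variant (`var0000`: a
confined eQTL effect on 14 DNA-repair + 15 hormone-regulated genes, and a
dominant-model odds ratio of 5 for the lesion phenotype), then runs every
stage:

```sh
triggerscan run-all --seed 5 --out demo/
```

or in Python:

```python
from triggerscan import cli
cfg = cli.PipelineConfig(seed=5, n_partitions=10, sim={
    "n_variants": 12, "n_dnarep_genes": 25, "n_hormreg_genes": 30,
    "n_background_genes": 10, "eqtl_effect": -2.0, "noise_sd": 0.5,
    "planted_or": 5.0, "incidence": 0.15, "maf_range": (0.15, 0.4)})
summary = cli.run_pipeline(cfg, "demo/")
```

The summary JSON this prints (abridged):

```json
{
  "trigger": {
    "n_positive_scores": 1,
    "top_variant": "var0000",
    "top_score": 5.420534999272286
  },
  "association": {
    "n_with_signal": 9,
    "leading_variant": "var0000",
    "leading_variant_share": 1.0,
    "whole_cohort_or": 3.2873281659003584,
    "whole_cohort_p": 9.192298308649085e-06
  },
  "network": {"lcc_proportion": 1.0, "lcc_empirical_p": 0.001996},
  "motif": {"n_gain_calls": 1},
  "hic": {"n_links": 20, "concordance_p": 6.795615128173358e-08}
}
```

Reading this: the planted variant tops the trigger ranking with score
ln(15·15+1) ≈ 5.42 (the counts overshoot the planted 14/15 slightly —
that is the FDR at work); 9 of 10 cohort partitions produce an
association signal and every one of them attributes it to the planted
variant; the whole-cohort dominant-model odds ratio is 3.3 with
P ≈ 9e-06 (a single draw of a noisy estimator whose median across
cohorts sits at the planted 5); the planted interaction module is fully
connected against a resampling null; the minor-allele window gains a
binding-site call; and transcripts in high-contact Hi-C bins are
significantly more deregulated than the same-class contrast.

Each stage is also exposed as a subcommand over TSV/VCF/FASTA/BED files —
`simulate`, `consensus`, `select-variants`, `ld`, `normalize`, `deg`,
`eqtl`, `score`, `specificity`, `assoc`, `partition-cv`, `burden`,
`ancestry`, `ppi-merge`, `lcc`, `enrich`, `motif-scan`,
`hic-concordance` — see `triggerscan --help`.

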