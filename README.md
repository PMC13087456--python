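# minorsplice

Analysis toolkit for minor-spliceosome disease cohorts: recessive ultra-rare
variant discovery, U12 intron-retention testing, weighted co-expression
module analysis, reference-based immune-cell deconvolution, and clinical
cohort summaries — together with a synthetic-data module that generates every
input with ground truth, so the whole chain is testable without any
controlled-access download.

## Modules

| Module | Purpose |
| --- | --- |
| `minorsplice.simulate` | Synthetic variant cohorts, intron counts, block-correlated expression, and methylation mixtures, each with a truth record |
| `minorsplice.clinical` | Clinical table schema, bundled two-cohort fixtures, and every printed summary statistic (medians/IQR, positivity rates, feature fractions, IUGR rule, distinct alleles, transcript↔genomic coordinate anchors) |
| `minorsplice.variants` | Ultra-rare filtering (strict MAF < 1e-5; missing AF kept), bi-allelic calling (homozygous / compound het in trans / phase-unknown), cross-proband gene intersection, panel screening |
| `minorsplice.intron_retention` | PSI = retained/(retained+spliced), Welch t on logit-PSI with coverage-aware pseudocount, BH adjustment, gene-level calls, two-cohort × known-U12 classification |
| `minorsplice.coexpression` | Signed correlation-power adjacency, topological overlap, average-linkage modules (static cut), eigengenes, Bonferroni module–trait correlation, hypergeometric GMT enrichment |
| `minorsplice.deconvolution` | Constrained least squares (w ≥ 0, Σw = 1) cell-fraction estimation and per-cell-type group comparison |
| `minorsplice.formats` | Minimal VCF 4.2, BED6, TSV matrices, GMT, sample sheets, JSON reports (byte-idempotent round trips) |
| `minorsplice.pipeline` | Stage orchestration with per-stage JSON manifests and full determinism under one seed |

## CLI

```bash
minorsplice simulate --seed 1 --out run/                   # all synthetic inputs + truth
minorsplice prioritize run/simulate/variants.vcf \
    --gene-class noncoding --probands case_000,case_001,case_002 --out prio.json
minorsplice ir-test run/simulate/intron_counts.tsv run/simulate/introns.bed \
    --min-coverage 10 --alpha 0.05 --min-effect 0.05 --out ir.tsv
minorsplice modules run/simulate/expression.tsv --power 6 \
    --cut-height 0.9 --min-module-size 20 --out modules.tsv
minorsplice deconvolve run/simulate/methylation_beta.tsv \
    --reference run/simulate/methylation_reference.tsv --out fractions.tsv
minorsplice clinical --out clinical_summary.json           # bundled cohort tables
minorsplice run --seed 1 --out run/                        # all six stages + manifests
```

Rerunning any command with the same inputs and seed is byte-identical; each
pipeline stage writes a `manifest.json` with parameter values and SHA-256
digests of its outputs.

## Conventions

- VCF positions are 1-based; BED intervals are 0-based half-open; transcript
  n. positions are 1-based on the snRNA.
- TSV missing sentinel is `.`; the clinical CSV distinguishes `N/A`
  (not applicable) from `N/R` (not recorded), and neither is ever imputed.
- PSI is oriented as retention by default (flag to flip).
- All randomness flows through explicit integer seeds expanded into named
  substreams, so adding a generator never perturbs existing streams.
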