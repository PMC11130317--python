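# crosstrait

Cross-trait analysis of GWAS summary statistics between a focal trait and a
set of outcome traits:

* **sumstats** — reading, QC ("munging"), allele harmonisation and regional
  filtering of summary statistics (duplicates, palindromic and non-SNP
  variants removed; optional reference-SNP restriction; MHC exclusion with
  default `chr6:28477797–33448354` or extended `chr6:25–34 Mb` bounds,
  GRCh37, 1-based inclusive).
* **globalrg** — SNP heritability and global genetic correlation by LD
  score regression with free (unconstrained) intercepts, two-step
  heteroscedasticity weights, and 200-block jackknife standard errors.
* **localrg** — per-LD-block genetic correlation: eigendecomposition of the
  local LD matrix truncated at 99% cumulative variance, chi-square
  univariate screening (both traits, P < 0.05), a Monte-Carlo bivariate
  test with 95% CI, explained variance r² = ρ², the "completely shared"
  flag (r² CI upper bound reaching 1), and Bonferroni labelling.
* **mr** — bidirectional two-sample Mendelian randomisation: instrument
  selection (P < 5×10⁻⁸, greedy clumping at r² < 0.001 in 10 Mb, F > 10),
  frequency-aware harmonisation, IVW (multiplicative random effects),
  MR-Egger with intercept pleiotropy test, weighted median with bootstrap
  SE, Cochran's Q, leave-one-out, a PRESSO-style outlier
  global/outlier/distortion procedure, and multivariable MR for
  conditional exposure effects.
* **overlap** — gene-level overlap statistics: overlap counts at nominal
  significance over a shared gene universe, one-sided exact binomial test
  of observed vs expected overlap proportion, Fisher's combined P
  (chi-square, 4 df), three-category shared-gene classification plus a
  sentinel-shared label, and multi-trait intersections.
* **simulate** — generators for every input: AR(1) block-LD panels and LD
  scores, paired summary statistics in moment mode (LDSC moment structure,
  with a sample-overlap intercept term) and effect mode (bivariate
  polygenic effects with real block LD and per-locus correlation
  overrides), gene P-value tables with a configurable shared fraction, and
  instrument-level MR datasets with known causal effect, pleiotropy mode
  and injected outliers.  Everything is seeded and bit-reproducible.

All deliverables are plain text; no reference data downloads are needed.

## CLI

```bash
# QC one summary-statistics file (column aliases auto-detected; YAML config
# may supply a dialect map and a per-file N)
crosstrait munge mystats.tsv --out munged.tsv --exclude-mhc

# generate a synthetic paired dataset with known genetic correlation
crosstrait simulate --out-prefix sim --rg 0.3 --seed 1

# global genetic correlation
crosstrait rg --sumstats1 sim.trait1.tsv --sumstats2 sim.trait2.tsv \
    --ldscores sim.ldscores.tsv

# per-locus correlation, bidirectional MR, gene overlap
crosstrait localrg --sumstats1 sim.trait1.tsv --sumstats2 sim.trait2.tsv
crosstrait mr --exposure exp.tsv --outcome out.tsv --bidirectional
crosstrait overlap --discovery genes1.tsv --target genes2.tsv --fcp
```

Gene tables are tab-delimited `GENE CHR START STOP NSNPS P`; locus files
are `LOC CHR START STOP`; LD score tables are `SNP L2`.

## Conventions

* Coordinates are GRCh37, 1-based, inclusive at both ends.
* Effect sizes are log-odds throughout; OR columns are converted at read
  time; signed-Z files are accepted (beta = Z, unit SE).
* Causal estimates are reported as OR with 95% CI `exp(theta ± 1.96·se)`.
* All thresholds are strict (`<`); duplicated variant ids are removed
  entirely rather than adjudicated.
* Every stochastic routine takes an explicit seed; simulation outputs
  record their generative parameters in a YAML truth file.
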