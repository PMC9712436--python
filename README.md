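# digenic

Statistical assessment of digenic (two-locus) variant combinations from
population sequencing data. The core idea: a truly pathogenic pair of
variants should show a *deficit of co-carriers* — individuals carrying the
alternate allele at both sites — in a healthy cohort, relative to the
count expected under two-locus Hardy-Weinberg equilibrium.

The package provides:

- **`digenic.hwe`** — the two-locus HWE genotype model: carrier
  frequencies, the nine genotype classes, expected counts for the four
  collapsed categories (co-carriers, single carriers of each variant,
  non-carriers). Linkage equilibrium between the pair is assumed; do not
  test pairs in strong LD.
- **`digenic.gof`** — the depletion test: Pearson chi-squared
  goodness-of-fit between observed and HWE-expected category counts
  (collapsed 4-category / 1 df, or full 9-class / 6 df), a
  minimum-expected-co-carrier testability rule (default 5), and
  Benjamini-Hochberg / Bonferroni adjustment across pairs.
- **`digenic.power`** — a Monte-Carlo power simulator: build the HWE
  population, deplete co-carrier classes by the penetrance, renormalize,
  draw a multinomial cohort, re-estimate allele frequencies, test, and
  report the rejection rate over many iterations (with grids over
  frequency, penetrance and cohort size, and optional power-curve plots).
- **`digenic.cohort`** — carrier counting for variant pairs directly from
  a multi-sample VCF (plain or bgzipped), with pairwise exclusion of
  samples missing either genotype, and batch screening of candidate pair
  lists.
- **`digenic.synth`** — a synthetic diploid cohort generator (VCF + JSON
  truth sidecar) with known frequencies and optional co-carrier
  depletion, used throughout the test suite.

## CLI

```bash
# depletion tests from summary rows: freq1  freq2  N  observed  [label]
digenic test pairs_summary.tsv --out report.tsv

# screen variant pairs against a cohort VCF
# pair list columns: chrom1 pos1 ref1 alt1 chrom2 pos2 ref2 alt2 [label]
digenic screen cohort.vcf pairs.tsv --adjust benjamini-hochberg --out screen.tsv

# power simulation over a grid (flags repeatable; YAML config supported)
digenic power --q 0.06 --penetrance 0.3 --n 38341 --iterations 1000 \
    --seed 1 --out power.tsv --plot power.png

# synthetic cohort with a planted depleted pair
digenic simulate --n 38341 --q1 0.05 --q2 0.05 --penetrance 0.6 \
    --seed 1 --out cohort.vcf
```

Every subcommand is deterministic given `--seed`. Exit codes: 0 success,
1 usage/input error, 2 internal error. Reports star significant pairs
(`*` for p below alpha) and flag untestable ones with the reason.

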