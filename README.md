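# ssrkit

Toolkit for fingerprinting clonally propagated cultivars from codominant
microsatellite (SSR) genotypes. Given a table of diploid allele-size
calls (sample, cultivar, locality, sex, two integer fragment lengths per
locus) it computes:

- **Diversity indices** per locus and per group: observed/expected
  heterozygosity, the unbiased small-sample correction, fixation index,
  effective allele counts, polymorphic-locus percentage, and a
  fixed-allele accounting (alleles for which a cultivar is entirely
  homozygous).
- **Genotypic distances**: half-squared-Euclidean distances between
  additive genotype dosage vectors (single-locus values 0–4, summed over
  loci), a cultivar-level summary (between-cultivar means, mean
  within-cultivar dissimilarity on the diagonal), principal coordinates
  analysis, an AMOVA-based PhiPT with a label-permutation test, and a
  permutation screen for pairwise linkage disequilibrium.
- **Identification keys**: the smallest locus subset whose cultivar
  consensus profiles are pairwise distinct, with alleles relabeled
  a1…, b1…, c1… by ascending size.
- **Likelihood assignment** of unknown (male) trees to cultivars via
  per-locus LOD scores with a genotyping-error model, and Monte-Carlo
  calibration of the best-minus-second-best delta criterion at strict
  (95%) and relaxed (80%) confidence.
- A **synthetic-data generator** that emulates clonal cultivars
  (single heterotic founders, variant clones, mislabels, a
  seed-propagated exception, male seed offspring) with ground-truth
  records, so every stage is testable end to end.

## CLI

The `ssrkit` entry point exposes one subcommand per stage:

```sh
ssrkit simulate --config sim.json --out demo        # demo.csv + demo_truth.csv
ssrkit validate demo.csv
ssrkit diversity demo.csv --group-by cultivar
ssrkit distance demo.csv --level cultivar
ssrkit pcoa demo.csv
ssrkit phipt demo.csv --group-by locality --n-perm 999 --seed 1
ssrkit ld demo.csv --n-perm 999 --seed 1
ssrkit key demo.csv --max-size 4
ssrkit assign demo.csv --error-rate 0.01 --n-sim 10000 --seed 1
ssrkit run demo.csv --out-dir out --seed 1          # full pipeline + manifest
```

Input dialects: `tidy` (default; columns
`sample_id,cultivar,locality,sex,<locus>_1,<locus>_2`, missing = empty
pair) and `genalex` (the GenAlEx codominant CSV layout, missing = 0).
Exit codes: 0 ok, 1 usage error, 2 data error, 3 internal error.

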