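# rxsex

Chromosomal sex identification from low-coverage shotgun sequencing, using
per-chromosome alignment counts (`samtools idxstats` tables).

For each sample the tool computes, over every autosome *i*, the
length-normalized depth ratio between the shared sex chromosome (X in XY
systems, Z in ZW systems) and that autosome:

```
r_i = (m_X / L_X) / (m_i / L_i)
```

The statistic is the mean of the `r_i`; its 95% CI is `mean ± 1.96·SE`, where
SE is the sample standard deviation of the ratios over √n. With two copies of
the shared sex chromosome the expectation is ~1.0, with one copy ~0.5. A
sample is called:

- **heterogametic** (XY male / ZW female) if the CI upper bound is strictly
  below 0.60,
- **homogametic** (XX female / ZZ male) if the CI lower bound is strictly
  above 0.80,
- **unassigned** otherwise.

A coverage-sufficiency check regresses per-autosome mapped counts on
chromosome length (sufficient when the regression F-test has p < 0.001).
Companion tools simulate synthetic count tables for known-sex individuals
(noise-free or multinomial), subsample counts to an exact read total
(multivariate hypergeometric), and sweep read depth to measure CI broadening.

## CLI

```sh
# Build a karyotype config from a FASTA index
rxsex make-karyotype --fai ref.fa.fai --shared-sex chrX \
    --autosomes 'chr([1-9]|1[0-9]|2[0-7])' --system XY --out elephant.karyo.tsv

# Identify sex for one or many samples
rxsex rx --idxstats sample1.idxstats --idxstats sample2.idxstats \
    --karyotype elephant.karyo.tsv --out results.tsv
rxsex rx --indir idxstats_dir/ --karyotype elephant.karyo.tsv --out results.tsv

# Simulate a known-sex sample, subsample it, sweep depth, plot
rxsex simulate --sex heterogametic --reads 1000000 --seed 1 --out sim.idxstats
rxsex subsample --idxstats sim.idxstats --target 10000 --out sub.idxstats
rxsex sweep --karyotype elephant.karyo.tsv --sex heterogametic \
    --depths 100000,10000,1000 --replicates 25 --out sweep.tsv
rxsex plot --indir idxstats_dir/ --karyotype elephant.karyo.tsv --out fig.png
```

Results TSV columns: `sample_id, rx, se, ci_low, ci_high, n_autosomes, call,
sufficient_coverage, p_value`. Exit codes: 0 success, 1 usage error, 2 data
error.

Karyotype config format: a `#system<TAB>XY` header line, then one
`name<TAB>length<TAB>role` row per chromosome, where role is one of
`autosome`, `shared_sex`, `limited_sex`, `excluded`.

## Python API

```python
from rxsex import (
    elephant_like_karyotype, SimSpec, Call,
    simulate_idxstats, join_counts, compute_rx,
)

karyo = elephant_like_karyotype()          # 27 autosomes + X
spec = SimSpec(karyotype=karyo, true_sex=Call.HETEROGAMETIC,
               total_reads=500_000, seed=1)
result = compute_rx(join_counts(simulate_idxstats(spec), karyo))
print(result.rx, result.ci_low, result.ci_high, result.call_label)
```

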