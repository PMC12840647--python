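# codonblosum

Codon-aware neutral modelling of somatic missense mutation severity.

## The problem

In a tumour cohort, are the missense mutations observed in a gene more
*evolutionarily radical* (or more conservative) than random mutagenesis
would produce? Amino-acid-level severity scores such as BLOSUM62 ignore
which substitutions a single nucleotide change can actually reach, while
nucleotide substitution spectra ignore biochemical severity. `codonblosum`
combines the two: the null distribution of substitution severity is built
from the gene's own coding sequence, one nucleotide change at a time.

It is aimed at cancer-genomics analysts who have, per gene, a coding
sequence (FASTA), a cohort mutation table (a "MAF-lite" TSV with case id,
gene, HGVSp-style protein change, variant class), a 12-entry base
substitution signature, and optionally a protein domain map.

## The model

For a CDS of L codons `c_1..c_L` with translation `a_i = T(c_i)`, every
codon has 9 single-nucleotide neighbours. Dropping synonymous and STOP
neighbours leaves the neutral missense event set **E** of size J. Event
*j* (base change b→b′ turning A_j into A′_j) gets

- raw weight `p̃_j = w_{b→b′}` from the substitution signature,
- probability `p_j = p̃_j / Σ_m p̃_m` (normalised over the whole table),
- BLOSUM62 score `S_j = B(A_j, A′_j)`,
- radical flag `R_j = 1{S_j ≤ 0}`.

The observed cohort of N validated missense events gives
`μ_obs = mean(S_i^obs)` and the radical fraction
`r_obs = mean(1{S_i^obs ≤ 0})`. M Monte Carlo replicates (default 7600)
each draw N events i.i.d. from Categorical(p_1..p_J) and yield `μ_s`,
`r_s`; the one-sided empirical p-values

```
p_mean = (1/M) Σ_s 1{μ_s ≤ μ_obs}       p_rad = (1/M) Σ_s 1{r_s ≥ r_obs}
```

test whether the cohort is more radical than neutral expectation (both
opposite tails are always reported, so conservative shifts — the oncogene
pattern — are visible too). Domain-level burden is compared through
enrichment ratios (observed/neutral fraction per domain) and chi-square /
likelihood-ratio G goodness-of-fit tests across domains.

## Worked example

Generate a synthetic gene and a radically-shifted cohort (selection tilt
β = −1 up-weights low-BLOSUM events), then run the full test:

```
$ codonblosum demo --seed 7 --beta -1.0 --out-dir demo_out
demo gene: N=150 mu_obs=-2.240 r_obs=0.9933 p_mean=0.0000 p_rad=0.0000
```

`demo_out/summary.tsv` holds the cohort row:

```
gene     N    nonsense  M     seed  mu_obs  r_obs   neutral_mu_mean  neutral_mu_sd  neutral_r_mean  neutral_r_sd  expected_mu  expected_r  p_mean    p_rad     p_mean_opposite  p_rad_opposite
TOYGENE  150  10        7600  7     -2.240  0.9933  -0.808           0.134          0.7655          0.0343        -0.807       0.7650      0.000000  0.000000  1.000000         1.000000
```

Reading it: the cohort's mean BLOSUM score (−2.240) sits far below the
neutral replicate mean (−0.808 ± 0.134) and its radical fraction (0.993)
far above neutral (0.766 ± 0.034), so none of the 7600 neutral replicates
is as extreme — `p_mean = p_rad = 0.0000`: the simulated cohort is
detected as strongly radical-shifted, as built. `domains.tsv` shows
per-domain enrichment near 1 (0.95–1.06): the tilt changes severity, not
location, and accordingly the chi-square test across domains in `gof.tsv`
is null (χ² = 0.33, p = 0.95).

Library use mirrors the CLI: `load_cds` → `read_maf_lite` →
`build_cohort`/`summarize` → `enumerate_events` → `simulate`/`p_values` →
`build_domain_table`/`goodness_of_fit`; `run_pipeline(PipelineConfig(...))`
composes the whole chain and writes the report bundle plus a JSON manifest
(seed, M, weights digest, version) for bit-identical reruns.

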