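# Methods

## Model and assumptions

The null hypothesis is that missense mutations accumulate by a
position-independent single-nucleotide process: at each considered codon,
each of the 9 single-base neighbours arises with probability proportional
to the signature weight of its base change, and selection plays no role.
The model is deliberately minimal:

- **Single-base events only.** Multi-nucleotide substitutions, indels and
  splice variants are outside the event space; the observed cohort is
  likewise restricted to missense (scored) and nonsense (counted only)
  calls.
- **No sequence context.** Weights are a 12-entry map w(b→b′); a
  trinucleotide-context signature model would change the event weights but
  not the machinery downstream of `p_j`.
- **Coding strand as written.** Weights apply to the plus-strand base
  change; no reverse-complement symmetrisation is performed, since the
  single-base signature gives no strand model. Users with strand-resolved
  spectra should symmetrise before supplying weights.
- **Severity via BLOSUM62.** The score is an evolutionary-conservation
  log-odds, not a direct functional readout. The radical rule is
  `S ≤ 0` — inclusive at zero — with the threshold exposed
  (`RADICAL_THRESHOLD` / the `radical_threshold` arguments) because the
  boundary convention is a genuine choice; a strict `< 0` variant is
  `threshold = -1`.

Two event-space modes exist because both are defensible nulls: the default
restricts E to codons carrying observed missense mutations (the null then
asks "given where mutations landed, how severe should they be?"), while
`whole-cds` uses every codon (the null also randomises location, which is
what the domain-level tests need). The pipeline uses the observed-codon
mode for the severity test and always enumerates the user-selected mode
consistently for the domain table.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| weights | `uniform` | 12-entry base-substitution signature. Presets: `uniform` (all equal) and `titv` (transitions κ:1, κ = 2.0 — a textbook-scale transition excess). Both are placeholders for a cohort-derived spectrum, which users should supply when available. |
| M | 7600 | Monte Carlo replicates; the convergence grid ends here, and `convergence_check` flags successive estimates differing by > 3 pooled MC standard errors. |
| radical threshold | 0 (inclusive) | Scores ≤ threshold count as radical. |
| add_one | off | Optional (1+count)/(M+1) p-value correction; the default plain fraction can legitimately report 0. |
| on_mismatch | error | Cohort validation behaviour when a label's wild-type residue disagrees with the CDS; `skip` logs and drops (mixed transcript isoforms are common in public tables). |
| dedup | per (case, variant) | Identical calls for the same case (paired biospecimens) collapse to one event; recurrence across cases is kept, because cohort frequency carries the selection signal. `per_biospecimen` disables the collapse. |

Domain boundaries are configuration (TSV/YAML, 1-based closed intervals);
residues outside every interval form the reserved `Other` domain. Domain
partitions of real proteins should come from curated feature annotations.

## Statistics

- `p_mean` and `p_rad` are plain one-sided empirical fractions with
  non-strict inequalities (ties count as extreme), so `p + opposite ≥ 1`
  on ties and the estimator is conservative (super-uniform) on the lattice
  induced by N and M. Both opposite tails are always reported rather than
  auto-flipping the direction: a conservative-shifted cohort shows
  `p_rad ≈ 1` with a small opposite tail, and silently flipping would turn
  a one-sided test into an undisclosed two-sided one.
- The domain goodness-of-fit renormalises the neutral fractions over the
  tested categories before forming expected counts (χ² needs a proper
  multinomial null; the renormalisation is logged). Zero-observed domains
  stay in the test and contribute `E_d` to χ² and 0 to G (`0·ln 0 = 0`).
  Any zero expected count is an error instructing category merging.
- P-values are written in scientific notation; `0.0` appears only below
  double-precision underflow.

## Synthetic data generator

`make_toy_gene` draws a random CDS (ATG start, no internal STOPs);
`make_cohort` draws N missense events from the whole-CDS neutral table
tilted by `q_j ∝ p_j exp(β S_j)` and injects nonsense calls at a
configurable rate (default 0.1, the order seen in tumour-suppressor
cohorts). The exponential tilt is the minimal one-parameter family that
produces both a radical shift (β < 0, the tumour-suppressor-like pattern)
and a conservative shift (β > 0, the oncogene-like pattern); it is a test
fixture, not a model of how selection acts on tumours. What the generator
does **not** emulate: positional hotspots and domain-concentrated burden
(the tilt is position-blind, so generated cohorts exercise the severity
test but give near-null domain enrichment), transcript-isoform noise,
sequencing artefacts, and context-dependent mutational signatures.
Passing tests on synthetic cohorts therefore demonstrate calibration and
direction recovery of the severity test, not hotspot detection on real
tumours.

## Numerical and design choices

- Probabilities are normalised once over the whole event table; scaling
  all weights by a positive constant leaves every `p_j` unchanged
  (property-tested). Zero-weight events are retained with `p_j = 0` so J
  is a property of the sequence alone. A table whose total raw weight is
  zero is an error.
- Sampling uses one named generator (`numpy.random.default_rng(seed)`);
  every randomised entry point takes a mandatory seed and the pipeline
  manifest records it, making output bundles byte-identical across reruns.
  `convergence_check` spawns independent child streams per grid point via
  `SeedSequence`.
- Report rounding is fixed (fractions 4 d.p., enrichment 2 d.p., means
  3 d.p.) so the TSV bundle is stable; recomputing an enrichment ratio
  from rounded fraction columns can differ from a ratio printed alongside
  them by up to half an ulp of the printed precision plus the propagated
  input rounding — the worked-example test applies exactly that bound.
- Degenerate inputs: empty position sets, cohorts with zero missense
  events, N or M below 1, overlapping domain intervals, non-increasing
  convergence grids and zero expected counts all fail fast with named
  errors; a domain with observed events but zero neutral mass is flagged,
  not fatal.
- Calibration checks compare the empirical p-value distribution to
  Uniform(0,1) with a lattice-aware critical value: the KS critical
  distance plus the largest attainable p-value atom (the modal mass of
  Binomial(N, ρ)/N, ρ the neutral radical fraction), since a discrete
  super-uniform p-value cannot beat its own lattice.

## Problem sizes

Default test and acceptance runs use desk-scale sizes chosen to keep the
whole suite fast while leaving Monte Carlo error well below the tested
margins: toy genes of 60–500 codons, cohorts of 50–200 events, 100-run
direction checks, 500-trial calibration at N = 50, M = 500, and full
M = 7600 runs for determinism and convergence. Real cohort-scale inputs
(thousands of cases, full-length genes) run through the same code paths;
the event table grows linearly in L and sampling linearly in M·N.

## Known limitations

- The severity null conditions on observed mutated codons but not on the
  per-codon mutation counts; strongly recurrent single sites therefore
  pull both the observed statistics and the null's position set.
- BLOSUM62 conflates evolutionary conservation with functional impact;
  domain context modulates the latter, which the per-domain means only
  partially capture.
- Nonsense mutations are counted but unscored; a cohort dominated by
  truncations will look underpowered in the severity test even when the
  truncations themselves are strongly selected.
- The signature presets are placeholders; conclusions about real cohorts
  require a cohort-appropriate substitution spectrum.
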