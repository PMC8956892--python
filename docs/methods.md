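# Methods

## Scope and data model

The package analyses Y-STR haplotype datasets: `n` males typed on a
declared locus panel. Built-in panels are the nested marker systems
Minimal (9 locus slots), PowerPlex Y12 (12), Yfiler (17) and PowerPlex
Y23 (23). The duplicated locus DYS385a/b is modelled as one locus name
carrying an unordered pair of allele calls; it counts as two slots when
sizing a panel and its haplotype identity is order-insensitive.
Micro-variant alleles are `(repeats, extra_bases)` pairs rendered in the
forensic convention `24.1`; a fractional designation whose suffix is not
a single digit (e.g. `.15`) is malformed, not a value. Amelogenin-Y
deletion status is sample metadata and never enters a statistic.

Profiles with any uncalled panel locus are *partial* and are excluded
from analysis by `filter_complete`, which partitions the input and
reports both counts — real datasets of ~100 samples typically lose a
handful of profiles this way, and the run manifest always records
`n_input = n_complete + n_excluded`.

Parsing applies sanity bounds of 5–45 repeats (observed forensic alleles
sit well inside this); out-of-range calls are logged and treated as
missing by default, or rejected under `strict_bounds`. This favours
recoverable datasets over hard stops for what is usually a typo.

## Forensic parameters

Per locus, with allele frequencies `p_i` from `n` observations (`2N` for
DYS385a/b, `N` otherwise):

- gene diversity `GD = n/(n−1)(1 − Σp_i²)` (Nei's unbiased estimator,
  clipped to [0, 1]);
- `PIC = 1 − Σp_i² − (Σp_i²)² + Σp_i⁴` (Botstein's form);
- match probability `PM = Σp_i²`; power of discrimination `PD = 1 − PM`.

At the haplotype level, `HD = n(1 − Σp_i²)/(n−1)` over haplotype
frequencies — algebraically identical to the fraction of unordered
sample pairs carrying different haplotypes, which the test suite
exploits as an independent oracle — and `DC = h/n` with `h` the distinct
haplotype count. The report also carries singleton counts, the mean
per-locus GD with its standard error (sample SD across loci divided by
√#loci), and the distinct-allele total divided by the panel's slot count.

**Display convention.** Internally all values are kept at full floating
precision and JSON reports round-trip exactly. Human-readable tables
truncate toward zero at 4 decimals, so a proportion is never overstated:
`94/95 = 0.98947…` prints as `0.9894`. This matches how such values
appear in published forensic population reports.

## Distances, AMOVA and Rst

The molecular distance between two complete haplotypes is the sum over
loci of squared differences in repeat counts. Conventions, all
switchable:

- DYS385a/b is **excluded by default** (standard practice for the
  duplicated locus in Rst analyses); when included, the unordered pair
  contributes the minimum over its two copy-to-copy pairings.
- Micro-variants map to `repeats + extra_bases/10`, preserving allele
  ordering with a small explicit weight; the alternative of excluding
  micro-variant loci can be had by subsetting the panel.
- DYS389II is used as typed; optional subtraction of the embedded
  DYS389I stretch is available (`dys389_subtract`).

One-level AMOVA on K populations (sizes `n_k`, total N): with `d_ij` the
squared distances, `SSD_total = Σ_{i<j} d_ij / N` and
`SSD_within = Σ_k Σ_{i<j∈k} d_ij / n_k`; `σ²_w = SSD_within/(N−K)`;
`σ²_a = (SSD_among/(K−1) − σ²_w)/n̄` with `n̄ = (N − Σn_k²/N)/(K−1)`;
`Φst = σ²_a/(σ²_a + σ²_w)` (0 when the denominator is not positive —
the degenerate all-identical case). Pairwise Rst is Φst of each
two-population AMOVA. Negative estimates are legitimate finite-sample
outcomes and are reported as computed; they are clamped to 0 only when
the matrix is fed to MDS. For an exact duplicate of a population the
estimator is slightly negative, vanishing with sample size — tests
assert |Rst| < 0.05 at n = 50 rather than 0.

The permutation test shuffles individual-to-population labels
(seeded NumPy generator, seed recorded in the result); the p-value is
`(b+1)/(m+1)` with the observed statistic included, which keeps the null
distribution of p stochastically valid at any permutation count. Default
`n_perm = 1000`. Under a random split of a single population, the
rejection rate at α = 0.05 is calibrated (tested at 2–8% over 500
replicates with `n_perm = 200`).

## Classical MDS

Torgerson scaling: `B = −½ J D² J` with `J = I − 11ᵀ/n`, eigendecomposed
symmetrically; coordinates are the top-`dims` eigenvectors scaled by
√eigenvalue. Only positive eigenvalues (relative tolerance 1e-9) are
embedded; negative ones — non-Euclidean input, common for Rst matrices —
are reported and logged, and if fewer positive eigenvalues exist than
requested dimensions, fewer columns are returned with a warning. On
exact Euclidean distance matrices the embedding reproduces the input to
1e-9 up to rigid motion.

## Haplogroup assignment

A naive-Bayes product classifier over loci:
`posterior(g) ∝ prior(g) · Π_locus f_g(allele)`, log-domain, normalised
across haplogroups. Unseen alleles are floored at ε = 1e-3 (configurable)
before scoring, so a single unobserved allele penalises rather than
vetoes a haplogroup; with ε = 0 an all-zero likelihood yields an explicit
`unclassifiable` call, never an exception. Priors default to uniform.
DYS385a/b contributes both observations against the single per-locus
distribution. Population spectra are percentages over classified
samples (unclassifiable counted separately). The package ships only the
table *format* plus synthetic fixtures; real per-haplogroup frequency
tables are user-supplied.

## Synthetic data generator

The generator emulates the structure of a single endogamous population
sample on a 23-locus panel under a **star genealogy**: each sampled male
descends independently from the modal haplotype of his haplogroup.
Defaults are study-scale: `n = 100` males; a haplogroup mixture
dominated by R1a (0.57), H (0.15) and L (0.13) with seven minor lineages;
per-locus mutation count Poisson(μ·t) with μ = 2e-3 per locus per
generation (the typical Y-STR order of magnitude) and depth t = 600
generations; ±1-repeat steps with fair-coin direction, reflecting at the
5/45 repeat bounds; micro-variants injected as a separate event (rate
0.02) only at DYS481, DYS576 and DYS390, the loci where incomplete-repeat
alleles occur on this panel; and 4 samples degraded to partial profiles.
At these settings a sample yields the singleton-dominated spectrum of
real data (DC ≥ 0.9, nearly all haplotypes unique). All randomness flows
from one recorded seed; config and per-sample truth (haplogroup,
mutation count) are serialised beside every dataset.

`simulate_divergent_pair` evolves each population's founders
`divergence_t` generations independently from shared ancestors before
the usual within-population drift, so among-population variance grows
with `divergence_t` (per-branch time; total separation is twice that).
Median Rst across seeds is strictly larger at t = 500 than t = 50 at the
default μ and n = 50 per population.

What the generator does **not** emulate: coalescent genealogy within
haplogroups (no shared internal branches, so haplotype sharing between
samples is rarer than under a true Wright–Fisher model), locus-specific
empirical mutation rates, multi-step mutations, and linkage of
micro-variant lineages. Passing tests therefore demonstrate correctness
of the statistics on data with realistic marginal structure, not
demographic realism.

## Numerical and design choices

- Frequency normalisation is checked to 1e-12 (report invariants) and
  1e-9 (haplogroup tables); AMOVA SSD additivity holds to 1e-9 relative.
- AMOVA is validated against an explicit double-loop brute-force oracle,
  exhaustively over one-locus two-group configurations up to N = 8
  (allele alphabets {10,11,12} for N ≤ 6, {10,11} for N = 7, 8).
- Haplotype identity keys compare DYS385 as a sorted pair; ties in the
  classifier are broken by posterior sort order (deterministic).
- Problem sizes in the test suite (n = 30–100 samples, 500 calibration
  replicates, 200 permutations, 1000 classifier draws) are chosen as the
  smallest scales at which the distributional claims are sharp.

## Known limitations

- Only one-level AMOVA is implemented; hierarchical (regional) designs
  are out of scope.
- Haplogroup calls are only as good as the supplied frequency table;
  the bundled fixtures are synthetic and for testing.
- HD and DC are descriptive statistics of the sample; no small-sample
  confidence intervals are provided.
- The completeness filter is all-or-nothing per profile; locus-wise
  analyses of partial profiles are not attempted.
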