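# Methods

## The measurement problem

A pool of *N* homozygous strains is starved in one culture and sampled on
fixed days; each sample is allowed to recover on food and sequenced. A
strain's representation in the sequenced DNA reflects the joint effect of
surviving starvation, resuming development, and reproducing — a single
integrated fitness readout. Because sequencing is reduced-representation,
only a strain's **unique SNVs** (sites where it alone carries the
alternative allele among the panel) are informative about its frequency.

## Frequency estimator

At a unique SNV of strain *s* in library *(replicate r, day d)*, the
alternative-allele read fraction `alt/(ref+alt)` is an unbiased estimate of
the strain frequency `f_s(r, d)` under uniform sampling of genomes. The
strain-level estimate is the **unweighted mean** of these per-SNV fractions
over the strain's markers with at least `min_total_reads` (default 1)
total reads. Choices worth making explicit:

- *Unweighted, not coverage-weighted*: every marker contributes equally,
  matching the error model below, which averages per-SNV estimates. A
  coverage-weighted pooled estimator (`sum alt / sum total`) is available
  (`weighted=True`) but off by default.
- *Zero-coverage markers are excluded*, not treated as frequency 0: `0/0`
  is undefined, and exclusion is the convention consistent with per-SNV
  averaging. The `min_total_reads` knob exposes the alternative.
- *No renormalization*: per-library frequencies are not rescaled to sum
  to 1. On complete panels with expectation-valued counts they sum to 1
  automatically; on sampled counts the deviation is itself informative.
- Estimates from fewer than 16 usable markers are flagged
  `low_confidence` (see the error model for where 16 comes from).
- A strain with no usable marker in a library is *missing* there, never 0.

## Trait value

For each replicate, the ordinary least-squares slope (with intercept) of
frequency against day of starvation is computed over that replicate's
sampled days; the **trait value** is the unweighted mean of the replicate
slopes (units: frequency per day). Defaults mirror the emulated design:
replicate 1 samples days {16, 21} (a two-point slope, exactly Δf/Δd),
replicate 2 days {1, 7, 14, 21, 24}. Replicates are averaged unweighted
despite unequal timepoint counts. Libraries where a strain is missing are
dropped from that regression; a strain with no computable slope anywhere is
omitted with a warning. The regression is on raw frequencies, not log
frequencies — the trajectory need not be linear for every strain, and the
slope is used as a simple, comparable summary of direction and magnitude,
not as a dynamical model.

`export_gwas_traits` emits the two-column (strain, value) mapping for
association tools, dropping listed strains (e.g. redundant isotype
representatives).

## Measurement-error model

Read sampling is modelled as Poisson. For a strain at frequency *f* with
*n* unique SNVs at expected per-SNV total coverage λ, each simulation draws
`alt_i ~ Poisson(λ f)` for *i = 1..n*, estimates `f̂ = mean(alt_i)/λ`, and
the **mean proportional error** is `mean(|f̂ − f|)/f` over `n_sim = 4000`
simulations. The per-SNV total is held at the constant λ by default,
mirroring an error analysis that varies only the strain-specific read
count; a `random_total` mode (total `~ Poisson(λ)`, alt binomial given
total) is provided as a sensitivity check and agrees in the normal regime.

Since `Var(f̂) = f/(nλ)`, the normal approximation gives the half-normal
mean `E|f̂−f|/f ≈ √(2/(π n λ f))`: the error depends on (n, λf) only, falls
as `1/√n`, and at the design point (λ = 1691, f = 0.01) crosses 5 % at
n ≈ 16 markers — the origin of the `low_confidence` threshold. Strains with
only 1–2 markers need frequencies of roughly 0.08–0.15 before reaching the
same precision. `error_grid` tabulates the surface (per-cell seeds derived
as `seed + cell_index` so a singleton grid equals a direct call) and
`minimum_requirements` inverts it.

## Synthetic experiments

The generator produces the statistical structure the analysis assumes, with
ground truth retained for parameter-recovery tests.

**Dynamics.** Deterministic infinite-population selection:
`f_s(d) ∝ w_s f_s(0) exp(−m_s d)`, renormalized each day. The mortality
rate `m_s` acts per day of starvation; the recovery weight `w_s` is a
single day-independent multiplier collapsing recovery growth and fecundity
into one fitness term. Determinism is justified by the scale being emulated
(millions of larvae); read sampling, not drift, dominates the error budget.

**Defaults** (chosen once to match the emulated experiment's printed
structure, and treated as the study conditions):

| parameter | default | rationale |
|---|---|---|
| `n_strains` | 96 | panel size |
| `unique_snv_counts` | log-normal, median 33, σ_log ≈ 0.83, floor 1 | matches the observed median and quartile spread (22/67) of markers per strain |
| `mean_total_coverage_per_snv` | 1691 reads | observed median per-SNV coverage |
| `sample_days_per_replicate` | ({16, 21}, {1, 7, 14, 21, 24}) | the two emulated replicates |
| `initial_frequencies` | Dirichlet, concentration 3 | day-1 median near 1/96 ≈ 0.01 with substantial founder dispersion (CV ≈ 0.6); the true founder dispersion is not published, so this is a free parameter, not an inference |
| `mortality_rates` | log-normal, median 0.10/day, σ_log 0.6 | spans ~0.03–0.3/day, enough heterogeneity to drive the observed qualitative pattern: rising cross-strain variance and an order-of-magnitude fall of the median frequency by day 24 |
| `recovery_weights` | log-normal, σ_log 0.25 | modest recovery-fitness variation |
| `read_noise_model` | `poisson_split` | independent Poisson alt/ref per SNV, consistent with the error model; `binomial_given_total` provided for sensitivity |

All randomness flows from explicit seeds (parameter draws and read
sampling use separate child streams of `SimConfig.seed`); there is no
global RNG state. `simulate_count_table(expected=True)` replaces draws by
their expectations, giving the noise-free oracle on which inference must be
exact to 1e-9 — the backbone of the correctness tests.

**What the generator does not emulate:** library-prep artifacts (PCR
duplicates, mapping bias, restriction-site dropout), density-dependent
survival interactions between strains, drift, genotyping error in the
panel, and non-exponential survival kinetics. Passing tests therefore
demonstrate correctness of the estimator chain under the stated sampling
model, not robustness to these real-data effects.

## Survival assay analysis

Percent survival on day *d* is `alive/plated`. A three-parameter logistic
`S(d) = U/(1 + exp(k (d − t50)))` is fitted per strain × replicate by least
squares weighted by the number plated (`sigma = 1/√plated`). **Median
survival time means the fitted t50** — the day the curve reaches half its
*upper asymptote* — which differs from an absolute-50 % crossing when
U < 1. The asymptote is estimated by default (`upper="fit"` within (0, 1]);
it can be pinned to the earliest-day survival proportion (`"fixed"`) or any
constant, since assay conventions differ on this point. Fits where survival
never falls near half the asymptote in the observed window, or where t50
lands far beyond the last scored day, are flagged `converged=False` rather
than raising; flagged fits are excluded downstream.

Strain comparisons follow a pooled-variance design: Bartlett's test on the
per-strain sets of replicate t50s (strains with one replicate excluded with
a warning); if variances are homogeneous, every pairwise t statistic uses
the variance pooled across *all* strains with `Σ(n_i − 1)` degrees of
freedom — more powerful than pairwise Welch tests when replicate counts
are small (3–5). If Bartlett rejects, the tests are still reported with a
warning. Degenerate cases are defined explicitly: zero mean difference →
t = 0, p = 1; zero pooled variance with nonzero difference → p = 0.

Recovery assays (total/early brood, body length) after 8 days of
starvation are normalized by the same strain's 1-day mean per assay, so
1-day values average exactly 1 and 8-day values read as proportional cost.
`correlate_trait_with_survival` regresses per-strain mean t50 on the trait
value and reports R²; in end-to-end simulations with strong, mortality-only
selection this exceeds 0.5, but the synthetic benchmark is not a substitute
for real-assay concordance.

## Association scan

`marker_scan` is deliberately naive: per-marker OLS of trait on the 0/1
allele indicator across homozygous strains, two-sided t test, minor-allele
count filter (`maf_min · n`), Bonferroni line at `−log10(0.05/M)`. Output
carries a "no population-structure correction" note because wild-isolate
panels are strongly structured and a mixed model (kinship-corrected) is the
appropriate instrument for real data; this scan exists for synthetic
benchmarks and sanity checks. P-values are clipped to the smallest positive
double so perfect separation yields a finite `−log10 p`.

## Numerical conventions

- Quantiles: linear interpolation between order statistics (numpy default /
  R type 7) throughout.
- Coverage standard errors: sample SD (ddof = 1) over all owned SNVs ×
  libraries, divided by √count; undefined (NaN) for a single observation.
- TSVs: UTF-8, tab-delimited, '.' decimal, `%.10g` floats, deterministic
  row order; pipeline outputs are a pure function of (config, seed) and the
  run manifest records seeds, SHA-256 checksums and row counts.
- Problem sizes in the test suite are scaled for quick feedback (12–48
  strains, 100–8,000 Monte-Carlo replicates) while keeping the acceptance
  checks at their stated sizes (4,000 error simulations, 96-strain
  reference table).

## Known limitations

- Frequencies of strains absent from a library are missing, which biases
  naive cross-library summaries if treated carelessly; distribution
  summaries count exclusions explicitly.
- The trait value conflates founder abundance with selection when founder
  frequencies vary; the slope is comparable across strains only to the
  extent founder effects are mild (they enter the slope multiplicatively).
- The logistic fit assumes independent binomial sampling per day from an
  unchanging cohort; the manual assay samples the same tube repeatedly,
  which mildly violates independence.
- No multiple-testing machinery beyond Bonferroni, and no linkage-aware
  interval logic, is provided for the scan.
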