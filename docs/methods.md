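# Methods

## Survival model and the logrank sweep

Patients enter as right-censored observations: `days_to_death` supplies
an event time (event = 1), `days_to_last_followup` a censoring time
(event = 0); patients with neither are dropped at load time, and
annotation phrases such as "Prior malignancy" (configurable, not
hard-coded) remove patients whose clinical history could confound the
analysis.

Kaplan–Meier estimation and the two-group logrank test are implemented
from first principles. At each distinct death time t_j with d_j deaths,
n_j at risk overall and n_1j at risk in the low group, the low group's
expectation and variance increments are

```
E_1j = d_j · n_1j / n_j
V_j  = n_1j n_2j d_j (n_j − d_j) / (n_j² (n_j − 1))
```

and the statistic (ΣO_1j − ΣE_1j)² / ΣV_j is referred to χ²(1). Censored
observations tied with deaths at t remain at risk at t (the standard
convention; the tie rule matters and is fixed here once). A sweep with
zero total variance returns p = 1 with a degenerate flag.

The threshold scan sorts patients by abundance, breaking ties by patient
id under a stable sort — this makes results deterministic and
permutation-exchangeable — and evaluates the split "k lowest vs rest"
for every k in ⌊l·s⌋ … ⌊h·s⌋. Percentiles are realized as rank counts,
not interpolated quantiles, matching the binomial index range of the
partition-count formula. Floor arithmetic adds 1e-9 before truncation to
guard against binary-float artifacts in products like 0.85·20.

### The sweep engine

Evaluating the logrank at every split afresh would cost O(s²) per
ordering. Instead, all split-invariant quantities are precomputed per
cohort (death times, d_j, n_j, the cumulative E-increment
Σ_{t_j ≤ t} d_j/n_j per patient, and the variance factor
c_j = d_j(n_j − d_j)/(n_j²(n_j − 1))), after which O_1(k), E_1(k) and
the per-death-time low-group at-risk counts n_1j(k) are cumulative sums
along the candidate ordering; V(k) = Σ_j c_j · n_1j(k)(n_j − n_1j(k)).
Batches of orderings are processed as one (batch × s × J) array. One
20,000-sweep null at s = 300 takes well under a minute on one CPU.

## Null construction and calibration

Each null simulation draws one uniform-random ordering and sweeps all
allowed k within it — one permutation per simulation, not an independent
permutation per split, because the observed statistic is also a minimum
over one nested sweep. Orderings are materialized as argsorts of iid
uniforms so the output is a pure function of (cohort, l, h, N, seed),
independent of internal batch size.

The calibrated p-value uses, by default, (r+1)/(N+1) with
r = #{null ≤ min_p}: the standard conservative permutation estimator,
strictly positive so BH is always defined. The method's original
estimator r/N is available as mode "plain" (r = 0 is reported as 1/N and
flagged). Both are monotone in min_p, so feature ranking never depends
on the null realization — only significance calls do.

Eligibility: a feature enters the screen only if its fraction of
patients with TPM strictly greater than zero is at least 1 − l
("expressing" is read as TPM > 0, matching the zero-inflation concern
that motivates the filter). Constant features are additionally dropped:
every split of a constant feature yields identical groups under the tie
rule, so no informative minimum exists.

Null-size planning: with m features and N = multiplier · m simulations,
adjacent sorted calibrated p-values are distinct with probability
≈ 1 − m/N; the helper returns the exact product (callers may round up).
A Schoenfeld-approximation helper (`min_low_group_for_power`) estimates
the smallest low-group allocation with adequate logrank power for a
given hazard ratio; it is explicitly approximate and only informs the
choice of l — the calibration itself never uses it.

### Numerical choices

- Variance totals below 1e-12 are treated as degenerate (statistic 0,
  p = 1).
- χ² survival probabilities are floored at the smallest positive double
  so p ∈ (0, 1] always holds.
- On p ties within a sweep, the smallest k wins (first occurrence under
  an ascending scan).
- The hazard ratio is the O/E ratio estimator, not a Cox fit; when
  either group has zero observed deaths, 0.5 is added to all four O/E
  tallies and the result flagged. Years are 365/730/1825 days
  (configurable).

## Robustness harness

Re-running the screen on fewer patients changes every p-value for sample
size reasons alone, so stability is judged on feature *ranks* by raw
minimum p. Each simulation removes ⌊fraction·s⌋ patients uniformly at
random, re-sweeps every feature on the reduced cohort, and ranks
(average ranks on ties); the summary is the mean Spearman correlation
against the full-data ranking. fraction = 0 reproduces the observed
ranking exactly (an identity check the test suite asserts).

## Multi-granularity graphs

The cascade, with per-stage counts logged: (1) expand gene-level
physical, within-taxon interactions to all ordered isoform pairs; (2)
keep pairs whose left isoform is survival-significant and
protein-coding; (3) keep pairs where some domain of the left isoform
(present, gained or ghost) and some domain present on the right isoform
form a cataloged DDI; (4) keep paths through gained or ghost domains
only; (5) drop left genes lacking multiple isoforms. "Gained" = present
on the significant isoform and absent from *all* insignificant siblings;
"ghost" = present in *at least one* insignificant sibling and absent
from the significant isoform (the union-based set algebra implements
both readings of "not found in the insignificant splice variants"
consistently; gained ∩ ghost = ∅ by construction). Partner-side
significance is deliberately not required — only the left isoform
carries the survival claim. Isoforms of a multi-significant gene are
classified against the truly insignificant subset only. The default
domtblout inclusion rule keeps rows with independent per-domain E-value
≤ 0.01 (configurable); Pfam accession version suffixes are stripped.
Identifier namespaces are the user's own; no translation service is
embedded.

## Mutational signatures

Consensus records are the exact intersection of (patient, chromosome,
position, ref, alt) across all required callers. Only single-base
substitutions enter profiling; purine-reference SNVs are
reverse-complemented into the pyrimidine convention and binned into the
96 classes (6 substitutions × 16 flank contexts, substitution-major
order). Contributions are nonnegative least squares against a 96 × K
signature matrix whose columns sum to 1 (supplied as TSV; no network
fetch — the synthetic generator provides a clearly-labeled synthetic
stand-in, and a real COSMIC-layout file can be dropped in).

Mood's median test counts values strictly above versus not-above the
pooled median (ties count as not-above — a fixed convention the original
description leaves open), applies the 2×2 chi-square without continuity
correction, and falls back to Fisher's exact test when any expected cell
is below 5, which keeps small or heavily tied tables deterministic. All
patients are retained, including zero contributions. Confounder tests
dispatch by declared variable kind: Welch t (metric), Wilcoxon rank-sum
with normal approximation and tie correction (integer), two-sample
proportion test with continuity correction (binary). The enrichment test
is the one-sided exact binomial tail P(X ≥ k); its background
probability is a required user parameter.

## Synthetic data: what it emulates, and what it does not

`simulate_cohort` draws exponential survival against uniform (0, C]
censoring; C is solved from the closed form
P(event) = 1 − (1 − e^{−λC})/(λC) so the realized event fraction matches
the target (defaults: λ = 1e-3 per day, event rate 0.35, sized after a
mid-size tumor cohort with a few years of follow-up; calibration and
power runs in the tests use a 50% event rate). Planted expression
effects designate a random patient fraction as "high", redraw their
survival with the hazard multiplied by the planted ratio (reusing the
latent censoring times carried in `cohort.extras`), and assign the
largest log-normal abundance draws to the designated set so the rank
split encodes the designation exactly. Coupling is via a binary
designation rather than a continuous dose–response, matching the
dichotomized hypothesis the screen tests. A shared-cohort mode (one
designation driving one cohort, required for multi-feature power runs)
and a per-feature mode (private cohort copies) are both provided; the
perturbed cohorts travel inside the returned truth object.

The interactome generator keeps background DDIs on a decoy domain
vocabulary never assigned to isoforms and gives each planted path a
fresh reserved accession pair, so the expected path set equals the
cascade output exactly — the generator is the oracle. The mutation
generator draws per-patient multinomial counts from the mixed 96-class
profile, materializes records with consistent contexts on both strands,
and applies independent per-caller dropout.

What passing tests therefore show: the statistics are correctly
calibrated and powered *under proportional hazards with exponential
baselines, independent log-normal abundance noise, and exact rank
encoding of planted splits*. Real RNA-seq brings count noise,
inter-feature correlation, batch structure and non-proportional hazards
that these fixtures deliberately omit; genomic coordinates are valid but
not realistic beyond their trinucleotide contexts.

## Problem sizes used in tests and the acceptance script

Calibration: 200 null features, n = 120, N = 20,000 (KS < 0.1, 5%-tail
within [0.02, 0.09], raw-minimum mean < 0.3). Exact-null check: s = 8,
all 8! = 40,320 orderings enumerated (covering the 246 admissible
partitions with their permutation multiplicities) against 100,000
Monte-Carlo draws, sup-distance ≤ 0.02. Power: 20 planted HR-3 features
among 480 nulls, n = 300, N = 20,000 (≥ 18 detected at FDR 0.1, optimal
split within ±10% of the plant for ≥ 90% of detections). Robustness: 60
features, 20 simulations at 5% removal. Signatures: 30 patients × 5,000
mutations over 5 synthetic signatures with 5% caller dropout (weight MAE
< 0.05); Mood's empirical size over 2,000 null replicates within
[0.03, 0.07]. Logrank cross-validation: 1,000 random cohorts of size
10–50 against lifelines, agreement to 1e-8. These sizes were chosen as
the smallest at which the properties are statistically sharp; the
defaults of the library itself (e.g. N = 1,000,000 null sweeps for a
production screen) remain the recommended production settings.

## Known limitations

- The screen tests a single dichotomization per feature; continuous or
  covariate-adjusted effects (Cox models, stratified logrank) are out of
  scope by design.
- The O/E hazard ratio is biased toward 1 relative to a Cox estimate
  when follow-up is short; it is reported as a descriptive effect size.
- Calibration assumes exchangeability of patients under the null; strong
  cohort substructure would require a stratified null, which is not
  implemented.
- The MGG cascade is only as complete as its inputs (interactome, DDI
  catalog, domain calls); absence of a path is not evidence of absence
  of rewiring. Protein–DNA/RNA/ligand interactions are not modeled.
- With an extreme, fully separated split and an all-censored group, the
  optimal k can sit a step or two past the true boundary (the O−E
  imbalance keeps growing while the variance shrinks); with interior
  signal the optimal split concentrates at the planted boundary, as the
  power checks verify.
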