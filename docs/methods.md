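# Methods

## The model

`cnvdn` infers integer copy numbers (CN) and de novo copy-number mutation
events from replicated, real-valued CNV measurements (e.g. qPCR ΔCt-derived
predicted copy numbers) in two-generation (nuclear) families, and tests
CNV–disease association.

For family *i*, member *j*, marker *l*, the observed replicate *k* is

    R*_ijl,k ~ Normal(R_ijl, σ_l²),   k = 1..n_ij

around a latent integer copy number. A founder's CN is the sum of two
latent haplotype copy numbers, `a1 + a2`, each with an independent Poisson
prior (mean `allele_prior_mean`, default 1.0, truncated at `max_allele`,
default 4, and renormalized). An offspring's CN is composed from the
parental haplotype pairs:

    R = k_f·min(a_f) + (1−k_f)·max(a_f)
      + k_m·min(a_m) + (1−k_m)·max(a_m)
      + θ_ins − θ_del

with fair-coin inheritance indicators `k_f, k_m ~ Bernoulli(0.5)` and rare
mutation indicators `θ_ins, θ_del ~ Bernoulli(μ)`. No mutation is allowed
in the parental generation. States whose raw CN would be negative are
excluded (prior weight zero) rather than clamped; the simulator clamps at
zero, which only matters in configurations that carry no posterior mass
under the defaults.

The mutation prior default follows the reciprocal-of-sample-size rule:
`μ = 1 / (number of genotyped offspring)` unless set explicitly. Markers
are modeled independently given the family.

Disease enters through a logistic regression on the binary collapsed
coding `C_ij = 1 − Π_l I{R_ijl = 2}` (1 iff any marker deviates from
diploid), or on a single marker's indicator:

    logit P(y_ij = 1) = α + β·C_ij + γ·X_ij + b_i,   b_i ~ Normal(0, τ²)

Only offspring phenotypes enter the likelihood by default (recruited
parents of a late-onset disease cohort are a biased sample of the parental
generation). Priors for the continuous block: α, β, γ ~ Normal(0, 10²);
σ_l and τ ~ Half-Normal(0, 1).

## Exact enumeration

For a nuclear family at one marker the latent space factorizes: unordered
founder pairs (15 per parent at `max_allele = 4`) × 16 indicator
combinations per offspring, with offspring conditionally independent given
the parents. `enumerate_family_posterior` sums this space exactly,
returning per-member CN mass functions, posterior means, and per-offspring
mutation probabilities, plus the family's log marginal likelihood. The
measurement SD can be fixed, marginalized over a 25-point log-spaced grid
with Half-Normal prior weights (weights include the log-spacing Jacobian),
or plugged in as the pooled within-individual replicate SD.

Two conventions coexist and both are reported: `p_ins`/`p_del` are the raw
indicator marginals (used for threshold calls and family flags, matching
the "posterior probability of θ exceeds the threshold" rule with strict
`>`), while `p_gain`/`p_loss` exclude the simultaneous gain+loss state,
which cancels in R and carries negligible mass at realistic priors.

### A structural property worth knowing

For Poisson haplotype priors, P({0,2}) = 2·p₀·p₂ = p₁² = P({1,1}) for
*every* Poisson mean. A child measured at 3 with both parents at 2 is
therefore explained about half by a de novo gain and half by an inherited
route (a parent with haplotypes {0,2} transmitting the 2, with the
sibling's fit repaired by one mutation — the same single mutation factor
the de novo route pays). Posterior mutation probabilities for clean
single-event families consequently plateau near 0.55 rather than 1, and
family detection at thresholds above ~0.55 collapses. This is a property
of the stated model, not of the implementation: the enumeration is
validated against an independent brute-force sum (ordered allele tuples ×
explicit indicator products through the elementary model functions) to
1e-12, and the MCMC sampler against the enumeration to ±0.02. Detection
thresholds at or below 0.5 are the operating regime this model supports.

## MCMC

`run_detection_mcmc` / `run_association_mcmc` implement
Metropolis-within-Gibbs with *enumerated* discrete full conditionals.
Founder pair updates are partially collapsed: the 16 indicator
combinations of each offspring are summed out when sampling a pair (they
are resampled immediately after), which bridges the strongly coupled
(pair, indicators) modes that trap uncollapsed single-site samplers. The
collapse exploits the factorized transmission structure, reducing to
eight weighted gathers on a zero-padded likelihood table per offspring.
Continuous parameters move by random-walk Metropolis (σ and τ on the log
scale); a joint (b, τ) scaling move decorrelates the random-effect
funnel. All updates are vectorized across families in a canonical order
(families and offspring sorted by ID), so permuting input order changes
nothing even at a fixed seed. Split-R̂ above 1.05 on any monitored scalar
triggers a warning; draws are still returned.

Defaults mirror a heavy production run (burn-in 50,000, 50,000 iterations,
thinning 10, 2 chains); tests and studies reduce these via `MCMCConfig`.
Two schedule knobs trade latent-refresh work against coefficient mixing:
`latent_update_every` refreshes the discrete latents only on every k-th
sweep (a fixed scan — still a valid sampler, useful when measurement noise
is small and the latents are nearly determined), and
`coef_updates_per_sweep` repeats the Metropolis cycle on the
posterior-correlated (α, β) pair.
`P(β>0)` is the fraction of retained draws above zero; the reported odds
ratio is `exp(posterior mean of β)`.

## Simulator

`simulate_families` draws the benchmark world: 200 families of four (two
parents, two offspring); founder haplotype CN 2 with probability 0.01
(insertion frequency, per haplotype), else 1; Mendelian transmission of
one haplotype per parent; per offspring a single categorical de novo event
(gain 0.005, loss 0.005, none 0.99) so truth labels are unambiguous, while
the inference model keeps independent indicators; measurements are true CN
plus Normal(0, SD) noise with SD ∈ {0.15, 0.20, 0.25} and 2 replicates per
individual (the first-stage design; the replicate count of the original
simulation was unstated). `apply_two_stage` implements the mean ± 3 SD
escalation rule (outlying individuals and their whole families get 4 more
replicates). Disease simulation draws the logistic model above; for
association benchmarks the insertion frequency is raised to 0.163 so the
collapsed coding has prevalence ≈ 0.3 among offspring.

What the generator does **not** emulate: systematic (non-Gaussian,
batch-correlated) measurement error, marker-to-marker dependence within a
gene, ascertainment of multiplex families, and parental mutations. Green
tests therefore establish correctness of the machinery under the stated
world, not robustness to real qPCR pathologies.

## Evaluation study

`run_study` simulates replicated cohorts per noise SD, runs the chosen
engine (`bayes-enumerate` by default — exact posteriors make 1000-class
replication counts tractable; `bayes-mcmc` behind a flag; or
`nearest-integer`), and aggregates family-level TPR/FPR at thresholds
{0.1, 0.3, 0.5, 0.7, 0.9} plus member-level rates by mutation type.
Family flags: any offspring with `p_ins > t` or `p_del > t` (strict).
Denominators: TPR over families with a true event, FPR over the rest,
pooled across replications; member-level FPR counts every non-carrier
offspring once per replication. Binomial Monte Carlo standard errors
accompany every rate.

The nearest-integer comparator rounds replicate means (half-to-even,
floored at 0) and flags a family when no joint decomposition of the two
parental totals into haplotype pairs reproduces all offspring totals
simultaneously (missing parents are unconstrained, making the check
conservative). Its detection ceiling is structural: with per-haplotype
insertion frequency 0.01, ≈4% of true mutation families are masked by an
inherited carrier configuration that renders the rounded totals
Mendelian-consistent, so no totals-based test can reach TPR 1.

## Numerical choices

- Enumeration uses log-space accumulation with `logsumexp`; family
  posteriors normalize to 1 within 1e-9 and posterior means are exact
  expectations of the reported mass functions (so `mean = 2 + P(3) − P(1)`
  holds to machine precision whenever the support lies in {1, 2, 3}).
- Rounding ties: half-to-even (measure zero under Gaussian noise).
- Discrete conditionals are sampled by Gumbel-argmax on unnormalized
  log-probabilities; excluded states carry −inf.
- Degenerate inputs: untyped individuals contribute likelihood 0 and stay
  in the model as prior-only latents; an all-diploid cohort makes β
  non-identifiable and triggers a constant-coding warning; a cohort SD of
  exactly 0 escalates nobody in the two-stage rule.

## Known limitations

- Mutations are ±1 copy only (the indicator composition permits nothing
  else); no parental or multi-copy events, no mosaicism, no X-linked
  markers.
- Only nuclear families are accepted; deeper pedigrees are rejected.
- High-threshold (>0.55) mutation calling is uninformative under this
  model's Poisson haplotype prior (see the structural property above).
- The association model assumes shared effect direction across collapsed
  markers.
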