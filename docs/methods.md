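# Methods

This note documents the statistical models implemented in `waspqg`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real assays.

## Performance indices

A standardized assay exposes 25 host larvae to one parasitoid female for a
fixed time; counts of emerged flies (*f*), emerged flies carrying at least
one encapsulated parasitoid egg (*e*, so *w = f − e* carry none) and
emerged wasps (*p*) are recorded.  Host survival fluctuates over a long
experiment, so every index is standardized by the same testing day's mean
survival of unexposed control vials, *n̄* (at least 10 vials per day).
Because *n̄* is a mean it is a real number; indices therefore use
real-valued denominators, and integer "success/failure" pairs for model
fitting are produced only by `standardized_counts`, which rounds *n̄* half
away from zero to form the trial total.

Clamping: a negative killing rate (*f > n̄*) is a sampling artifact of the
vial-level binomial noise and is floored at zero.  Attack and lethal
attack rates are clamped into [0, 100] for the same reason; since only the
killing-rate floor has an explicit protocol precedent, clamping of the
other two is flagged in the output rather than silent.  The lethal attack
rate and successful parasitism are *undefined* — not zero — when their
denominators are non-positive (no flies attacked, no flies killed): an
unobserved efficiency is not evidence of inefficiency.  Undefined values
are excluded from downstream fits and means.

Block quality control removes testing days whose control mean falls below
0.6 × the median block mean (the "about half of the other blocks" rule);
the threshold is configurable, the filter is order-independent and
idempotent, and every exclusion is reported.

## Haplodiploid relatedness

Females are diploid, males haploid (arrhenotoky): a male has a dam but no
sire and transmits his whole genome to every daughter.  The package uses a
single internally consistent convention, *a* = 2 × coancestry, where
coancestry f(i,j) is the probability that one allele drawn from each of
i and j is identical by descent and a haploid male holds a single allele
(so f(male, male-self) = 1).  The tabular recursion (parents-first):

- female i with dam d, sire s: `f(i,j) = (f(d,j) + f(s,j))/2` for earlier
  j, `f(i,i) = 1/2 + f(d,s)/2` (inbreeding enters naturally);
- male i with dam d: `f(i,j) = f(d,j)`, `f(i,i) = 1`.

Unknown parents are unique unrelated founders.  This yields the canonical
haplodiploid coefficients — full sisters 0.75, paternal half sisters 0.5,
mother–daughter 0.5 — and is validated not against textbook constants but
against an independent gene-dropping oracle that simulates allele
transmission directly (agreement within 3 Monte-Carlo standard errors at
2×10⁵ replicates, including inbred pedigrees).  Only phenotyped females
enter the likelihood, so the male diagonal convention never affects a fit;
males act purely as transmission links.  Dense linear algebra is used
throughout: at the design scale involved (~550 individuals) sparse-inverse
machinery would add complexity without benefit.

## Threshold animal model

Counts are binomial with a latent Gaussian liability per record:

    l_i = μ + a_animal(i) + d_day(i) + m_mother(i) + e_i,   e_i ~ N(0, Vr)
    successes_i ~ Binomial(trials_i, g⁻¹(l_i))

with `a ~ N(0, Va·A)` over the phenotyped females' relationship matrix,
i.i.d. day and mother effects, and Vr fixed at 1 (the residual is not
identifiable for binomial data).  One liability per *record* (not per
larva) keeps the record-level residual meaningful.  Mothers are an
unstructured i.i.d. effect, not a pedigree effect: the mother term absorbs
common maternal environment, while the genetic dam contribution already
flows through A.  Fixed effects are limited to the global intercept; day
is a random effect.

The probit link is the default and the heritability per draw is

    h² = Va / (Va + Vday + Vmother + Vr + 1),

the +1 being the probit link variance.  (A logit option replaces the +1
by π²/3.)  Applying this ratio to published posterior-mode variance
components of the half-sib study this package models reproduces the
published h² modes within ±0.05 on all eight trait rows, which is the
evidence for this reading of "total phenotypic variance"; exact equality
is impossible because the posterior mode of a ratio is not the ratio of
modes.

Priors are parameter-expanded: each effect is written u = α·ũ with
ũ ~ N(0, v·S), α ~ N(0, 1), v ~ Inv-Gamma(ν/2, νV/2), defaults V = 1,
ν = 1000, so the implied prior on the variance α²v is a χ²₁ — the prior
recommended for binomial traits because it spreads heritability nearly
uniformly.  The Gibbs cycle draws the Gaussian blocks and expansion
parameters conjugately; the genetic block is drawn in the eigenbasis of
the phenotyped submatrix of A, where its conditional covariance is
diagonal (the eigendecomposition is computed once per fit).  Liabilities
are updated by a vectorised random-walk Metropolis step whose per-record
proposal scale adapts toward 44% acceptance during burn-in only, so the
post-burn-in chain is a fixed, valid Markov chain.  Draws are bit-for-bit
reproducible given the seed.

Burn-in and thinning defaults (10,000 and thin 25 on 50,000 kept
iterations) are this package's choice; full-length runs of the published
scale (910,000 samples) are configurable.  Test and acceptance runs use
9,000 iterations (burn-in 2,500, thin 5, 1,800 retained draws), a size at
which the retained chains meet the package's own diagnostic thresholds on
the half-sib design while keeping a 60-fit recovery study inside a few
minutes; a configuration flag (`min_retained`, default 1000) enforces a
floor on retained draws.

Point estimates are posterior modes from a Gaussian KDE with Silverman
bandwidth; intervals are shortest empirical HPD intervals.  Diagnostics:
lag-1 autocorrelation of the thinned chain (< 0.1), effective sample size
by Geyer's initial-monotone-sequence estimator (> 1000), and a
Heidelberger–Welch stationarity test — the Cramér–von Mises statistic of
the Brownian bridge of cumulative sums, discarding initial 10% segments up
to 50% until it passes.  The long-run variance is estimated from the
detrended second half of the chain; without detrending a drifting chain
inflates its own variance estimate and masks its nonstationarity.  The
single-window test holds its nominal 5% level on i.i.d. chains (measured
94–95% over 400 replicates).

### Calibration and its limits

Simulation-based calibration (truths drawn from the χ²₁ prior, posterior
rank of the truth computed per fit) shows the sampler is well calibrated.
At a *fixed* truth, however, frequentist coverage of the 95% HPD depends
on the prior: at the half-sib design scale (345 daughters, 68 sires,
25-larva assays) roughly one dataset in ten generated at h² = 0.15 is
statistically indistinguishable from a null dataset, and the χ²₁ prior
then concentrates the posterior near zero.  Measured coverage over 20
fixed-seed replicates is 18/20 at h² = 0.30 and 17/20 at h² = 0.15 (the
null case yields posterior modes below 0.05 throughout).  This is a
property of the design's information content, not of the sampler; chains
3–4× longer move the interval endpoints by less than 0.01.

## Synthetic half-sib data

The generator reproduces the breeding design: 68 sires with 28/33/7
achieving 1/2/3 matings (115 dams), three daughters per dam (345 assayed
females), five testing blocks, 10 control vials per block.  (The published
totals 68/122/357 are mutually inconsistent with the published mating
distribution; the dam counts are configuration and realized totals are
reported.)  Breeding values follow haplodiploid transmission exactly:
sire value x_s ~ N(0, Va/2) (one haplotype), dam value the sum of two such
haplotypes, daughter value x_s + dam/2 + Mendelian N(0, Va/4), giving
full-sister covariance 0.75 Va and half-sister covariance 0.5 Va.

The observation channel is deliberately model-consistent, per the module's
role of generating data *with the statistical structure the analysis
assumes*: the wasp kills K ~ Binomial(25, Φ(l)) larvae; kills of larvae
that would have died anyway are not excess mortality, so the excess is
Binomial(K, s) with s the day's background survival; emergence is the
day's observed control mean (rounded) minus the excess.  The standardized
killing count then inverts to the thinned kill count exactly.  What this
omits is the vial-level emergence noise among unkilled larvae that real
assays have: that noise acts as a floor on the day-standardized index
(a female who kills nothing still shows ~4% apparent killing when ~20 of
25 control larvae emerge), and with it, all variance components — in real
data as well as in simulation — are attenuated.  Passing parameter
recovery on this generator therefore demonstrates that the sampler and
pipeline are correct, not that real assays are free of this attenuation;
heritability estimated from real vial counts is best read as a lower
bound.

Day effects are drawn fresh per block from N(0, Vday) and mother effects
per dam from N(0, Vmother); day-level background survival carries a small
multiplicative jitter (3% SD) around the baseline (default 0.82, the
range of observed control survival).

## Selection simulator

Genotype-explicit: 100 freely recombining additive loci per individual
(females two haplotypes, males one) approximate the infinitesimal model
while making haplodiploid Mendelian-sampling variance emerge from
transmission instead of being book-kept.  Founder allelic values are
N(0, Va/(2·n_loci)) per haplotype so founder female breeding values have
variance Va (defaults Va = 1.077, Vday = 0.345, Vmother = 0.001, the
posterior modes of the standardized killing-rate fit; base mean liability
−1.31 gives a starting mean killing rate near 24%).

Each generation: every female is assayed (liability → per-larva kill
probability → counts, as in the generator), the top 50 of 100 by
standardized killing rate are selected (ties broken uniformly at random;
control lines pick 50 at random), each selected mother contributes eight
pupae sired by one random male of the line's current pool, offspring are
pooled and sexed at ratio 0.5, 100 daughters form the next assayed cohort
and all sons the next male pool.

Two points follow from this protocol rather than from textbook selection
theory, and the tests treat them accordingly:

- **Single-parent selection.**  Only mothers are phenotyped and selected;
  sires are sons of the previously selected mothers.  The latent
  realized-heritability slope therefore approaches (2/3)·Va/Var(l), not
  Va/Var(l) — a daughter takes half her genome from her selected dam and
  all of her sire's genome, itself one selected-dam gamete one generation
  late.  The test suite checks the simulator against the deterministic
  transmission recursion `m_{t+1} = (m_t + bS)/2 + μ_t`,
  `μ_{t+1} = (m_t + bS)/2` rather than against the naive breeder's
  equation.  For the same reason the realized-heritability regression is
  *not* equivalent to a parent–offspring regression on the same data
  (truncation also restricts the variance of selected mothers).
- **The host-fitness confound.**  The experiment's host colony adapted to
  the laboratory over the year: baseline survival rose ~30% from F2
  onward, and killing performance fell after F4 despite selection.  A
  survival trend alone cannot reproduce this in simulation — the
  day-standardization cancels it exactly — so the drifting host fitness
  has two components here: baseline survival rising linearly from F2 to
  1.3× at F7, and a host-resistance shift subtracted from the liability
  (quadratic from F2, matching the convex survival trend the study
  observed), default 1.9 liability units at F7, calibrated once so that it
  cancels the expected cumulative genetic gain — the "killing rate back
  near its start by F7" outcome.  With these defaults the pooled realized
  heritability is ≈ 0.17 over P–F4 and ≈ 0 over P–F7, the published
  pattern.

Wasp offspring success on the resistant host defaults to 0 (5 of 2070
exposed hosts in the source assays); encapsulation among surviving flies
defaults to 0.25.  Both are configurable for sensitivity analyses.

## Response analysis

S = mean of selected parents − mean of the full parental cohort;
R = offspring-cohort mean − full parental-cohort mean, both on the
day-standardized killing-rate percent scale.  Realized heritability is the
slope of the regression of cumulative R on cumulative S forced through the
origin: slope = ΣS_cum·R_cum / ΣS_cum², with SE, F(1, n−1), p and
*uncentered* adjusted R² following no-intercept conventions (verified
against a generic least-squares solver).  Pooled ("average") fits
concatenate the three lines' cumulative points into one regression, which
reproduces the degrees-of-freedom pattern of the per-interval report
(e.g. F(1,11) over P–F4 from 3 lines × 4 intervals).

Selection intensity is i = φ(z)/p with z the upper-tail standard-normal
quantile of the retained fraction p; i(0.5) = 0.798.  The
breeder's-equation projection R = i·σₐ·√h² is computed on the liability
scale; because no canonical mapping from liability gain to observed
percentage exists, the mapping is a strategy option: unit probit
(`p_t = Φ(Φ⁻¹(p₀) + t·R)`, default), total-SD-scaled probit, or a local
linearisation.  Under the default mapping, i = 0.79, σₐ = √1.077,
h² = 0.281 and a 24% start give 99.0% after seven generations; published
projections of this kind (97.25% under unstated scaling) fall inside the
bracket the mapping options span, and no single mapping is asserted to
reproduce them.

## Numerical choices and degenerate inputs

- Rounding of control means: half away from zero (a day mean of 20.5
  becomes 21 trials).
- Eigenvalues of the phenotyped relationship submatrix are clipped at
  1e−10 after verifying none is below −1e−8 (else the fit aborts).
- A variance draw exceeding 1e10 aborts the sampler with the iteration
  index (divergence).
- Ties in truncation selection are broken uniformly at random from the
  seeded generator, so selection is exchangeable among equals.
- Empty datasets, cyclic pedigrees, males with sires, counts violating
  their invariants, and missing headers are rejected with messages naming
  the offending row.

## Known limitations

- The generator's observation channel omits vial-level emergence noise
  (see above); real-data heritabilities are attenuated relative to the
  latent truth.
- The threshold model fits one trait at a time; genetic correlations
  between indices (e.g. attack vs killing) are out of scope.
- The simulator does not model superparasitism, handling time, or
  within-vial behavioral dynamics; the host-resistance trend is a
  phenomenological calibration, not a host-evolution model.
- Realized-heritability inference assumes the generation means are
  measured on a common standardized scale; systematic day-standardization
  errors propagate directly into S and R.
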