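# waspqg

Quantitative genetics of parasitoid host-killing performance.

`waspqg` is a toolkit for analysing standardized host-exposure assays of
parasitoid wasps on a novel, highly resistant host — the setting of
*Leptopilina heterotoma* attacking the invasive fruit pest *Drosophila
suzukii*, where wasps readily attack and kill host larvae but almost never
produce offspring from them.  It is written for researchers evaluating
whether such "nonreproductive host killing" is heritable and whether
selective breeding can improve it for biological control.

The package covers the full workflow:

1. **Performance indices** (`waspqg.indices`) — from vial-level counts
   (larvae exposed, flies emerged *f*, encapsulated survivors *e*, wasp
   offspring *p*) it computes four day-standardized indices, each
   corrected by the same-day control survival *n̄*:
   attack rate `100(n̄−w)/n̄`, killing rate `100(n̄−f)/n̄` (floored at 0),
   lethal attack rate `100(n̄−f)/(n̄−w)`, and successful parasitism
   `100p/(n̄−f)`; plus block-level quality control and the integer
   success/failure pairs used for model fitting.
2. **Haplodiploid relatedness** (`waspqg.pedigree`) — the additive
   relationship matrix `A = 2 × coancestry` under haplodiploid
   transmission (diploid females, haploid males; a daughter inherits her
   sire's entire genome), validated against a gene-dropping Monte-Carlo
   oracle.
3. **Threshold animal model** (`waspqg.animal_model`) — a Bayesian
   liability-threshold model for binomial counts: per-record liability
   `l = μ + a + d + m + e` with `a ~ N(0, Va·A)`, i.i.d. testing-day and
   mother effects, fixed residual variance `Vr = 1`, probit (default) or
   logit link, and parameter-expanded χ²₁-type priors on the variance
   components.  Heritability per posterior draw is
   `h² = Va / (Va + Vday + Vmother + Vr + 1)` (the +1 is the probit link
   variance).  Posterior modes (KDE), shortest 95% HPD intervals, and
   convergence diagnostics (lag-1 autocorrelation, effective sample size,
   Heidelberger–Welch stationarity) come with it
   (`waspqg.mcmc_diagnostics`).
4. **Selection simulator** (`waspqg.selection`) — a genotype-explicit
   forward simulation of a 7-generation truncation-selection experiment
   (3 selection + 3 control lines of 100 females, top-50 selection on
   killing rate, 8 pupae per mother), including a drifting host
   environment: baseline host survival rising 30% and a matching gain in
   host resistance that masks the genetic response.
5. **Response analysis** (`waspqg.response`) — selection differentials S
   and responses R, realized heritability as the slope of the no-intercept
   regression of cumulative R on cumulative S, truncation selection
   intensity `i = φ(z)/p`, and breeder's-equation projections
   `R = i·σₐ·√h²` with configurable liability-to-percent mappings.
6. **Synthetic data** (`waspqg.synthetic`) — half-sib assay datasets
   (68 sires × up to 3 dams × 3 daughters over 5 testing blocks) with the
   exact statistical structure the analysis assumes and full ground-truth
   records for parameter-recovery testing.

## Worked example

Generate a half-sib dataset at the study's design scale, fit the
threshold animal model to the killing rate, and summarise:

```python
from waspqg import (
    HalfSibDesign, generate_halfsib, trait_dataset_from_tables,
    haplodiploid_amatrix, ModelConfig, fit,
    posterior_mode, hpd_interval, selection_intensity, breeders_projection,
)
from waspqg.pedigree import pedigree_from_table

design = HalfSibDesign()          # 68 sires, 115 dams, 345 assayed daughters
pedigree, trials, controls, truth = generate_halfsib(design, va=1.077, seed=0)
print(f"true heritability of the generated data: {truth.h2:.3f}")

data = trait_dataset_from_tables(trials, controls, trait="killing")
A = haplodiploid_amatrix(pedigree_from_table(pedigree))
samples = fit(data, A, ModelConfig(n_samples=20_000, burn_in=4_000, thin=10, seed=1))

lo, hi = hpd_interval(samples.h2, 0.95)
print(f"h2 posterior mode {posterior_mode(samples.h2):.3f}, "
      f"95% HPD [{lo:.3f}, {hi:.3f}]")
print(f"Va posterior mode {posterior_mode(samples.va):.3f}")

i = selection_intensity(0.5)      # top 50% of females selected
proj = breeders_projection(i, 1.077**0.5, 0.281,
                           start_mean_percent=24.0, generations=7)
print(f"selection intensity (top 50%): {i:.3f}")
print(f"projected killing rate after 7 generations: "
      f"{proj.percent_trajectory[-1]:.1f}%")
```

prints

```
true heritability of the generated data: 0.315
h2 posterior mode 0.317, 95% HPD [0.081, 0.465]
Va posterior mode 0.989
selection intensity (top 50%): 0.798
projected killing rate after 7 generations: 99.1%
```

The fitted mode recovers the generating heritability (0.317 vs 0.315; the
additive variance mode 0.989 vs the generating 1.077), the intensity of
top-half truncation selection is ≈ 0.80, and under idealized constant
conditions the breeder's equation projects killing rates in the high
nineties within seven generations — far above what a drifting host
environment allows (run `waspqg simulate-selection` to see the masked
response).

A command-line interface mirrors the library:

```
waspqg simulate-halfsib --seed 1 --out data/
waspqg indices --trials data/trials.csv --controls data/controls.csv --out perf.csv
waspqg amatrix --pedigree data/pedigree.csv --out A.csv --females-only
waspqg fit-animal-model --trait killing --trials data/trials.csv \
    --controls data/controls.csv --pedigree data/pedigree.csv --out fit/
waspqg simulate-selection --seed 1 --out sim/
waspqg realized-h2 --means sim/means_selection.csv --out h2.csv
waspqg predict-response --i 0.79 --sigma-a 1.038 --h2 0.281 --start 24
```

Every run writes a JSON manifest (command, config hash, seed, input and
output digests) from which the outputs can be regenerated bit-identically.

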