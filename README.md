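# epibayes

Fast Bayesian genome-wide estimation of **additive, dominance and pairwise
epistatic marker effects**, together with the forward-in-time livestock
population and trait simulator needed to study it.

## The problem

Genomic prediction usually models markers as purely additive. Real gene
action includes intra-locus interaction (dominance) and inter-locus
interaction (epistasis); modelling them can improve the prediction of total
genetic values and reveals how genetic variance is partitioned across
sources. But with `m` markers there are `4·m(m−1)/2` pairwise epistatic
effects — millions even for a modest chip — which puts MCMC samplers out of
reach. This package implements the *iterated conditional expectation* (ICE)
alternative: each effect has an analytically known posterior mean under a
point-mass/Laplace mixture prior, and the estimator cycles over all effects
until the estimate vector stabilizes. One fit touches every pair effect a
few dozen times and finishes in seconds to minutes instead of months.

It is aimed at quantitative geneticists studying non-additive architecture
in livestock or model populations, and at methodologists who need a
reproducible simulation benchmark for such estimators.

## Model

Phenotypes follow `y = 1μ + X_a g_a + X_d g_d + Σ_s X_s g_s + e` with
`s ∈ {aa, ad, da, dd}` and `e_i ~ N(0, σ_e²)`. Marker genotypes are coded
with the NOIA orthogonal decomposition built from observed genotype-class
frequencies (no HWE assumption), standardized to unit frequency-weighted
variance; epistatic covariates are element-wise products of the
standardized main-effect columns, e.g. `X_aa,j,k = X_a,j · X_a,k`. Models:
**M0** (additive), **M1** (additive + dominance), **M2** (M1 + all four
pair sources).

Each effect has the prior `g_s,j ~ L*(γ_s, λ_s)`: zero with probability
`1−γ_s`, otherwise Laplace with rate `λ_s = √(2 m_s γ_s)` (unit total prior
variance per source). The posterior mean given the corrected phenotypes is
a closed-form mixture of truncated-normal means; see `docs/methods.md` for
the formulas, the scale translation of simulated effects, and every
numerical choice.

The simulator emulates a dairy-cattle population: 52,273 SNPs on a
30 Morgan genome, effective size 100, 400 generations of mutation–drift
(mean SNP heterozygosity ⅓, adjacent-marker LD r² ≈ 0.12), then half-sib
training generations (2 × 50 families × 20 offspring, n = 2,000 phenotyped)
and matching unphenotyped test generations. Traits place 23 or 230 QTL
with gamma-distributed substitution effects, normal degrees of dominance
and optional epistatic pairs, and calibrate `σ_e²` to a chosen broad-sense
heritability.

## Worked example

Run a desk-scale replicate set of the 23-QTL scenario *with* simulated
epistasis at broad-sense heritability 0.5, fitting the additive+dominance
model M1 (i.e. deliberately ignoring the simulated interactions):

```python
from epibayes import ScenarioConfig, run_scenario

cfg = ScenarioConfig.scaled(n_qtl=23, epistasis=True, h2=0.5,
                            models=("M1",), n_replicates=5, seed=11)
frame, _ = run_scenario(cfg)
ok = frame[frame["converged"]]
print(f"{len(ok)}/{len(frame)} fits converged "
      f"(median {int(ok['n_iter'].median())} iterations)")
print(f"accuracy (test generations):      {ok['accuracy'].mean():.3f}")
...
```

which prints

```
5/5 fits converged (median 15 iterations)
accuracy (test generations):      0.788
estimated sigma_a^2 (under LE):   1.225   true: 1.382
estimated sigma_d^2 (under LE):   0.191   true: 0.240
estimated additive ratio:         0.866   true: 0.617
realized narrow-sense h^2:        0.308
```

Reading the numbers: predicted and true total genetic values of the
unphenotyped test animals correlate at 0.79 even though the model ignores
epistasis; the additive and dominance variance components are mildly
underestimated (the sum-of-squares components are an approximation under
linkage disequilibrium); and because the epistatic variance that M1 cannot
see leaks into its main-effect estimates, the additive share of genetic
variance is overestimated (0.87 vs the true 0.62) — fitting M2 instead
recovers this ratio far better. The realized narrow-sense heritability of
0.31 is what a broad-sense heritability of 0.5 implies once a quarter of
the genetic variance is epistatic.

A shell interface mirrors the library:

```bash
epibayes simulate --seed 1 --out sim/                      # VCF/TSV/pedigree
epibayes fit --geno sim/dosage.tsv --pheno pheno.tsv --model M2 --out fit/
epibayes scenario --profile ci --seed 1 --out study/       # replicated study
```

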