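# Methods

## Statistical model

Phenotypes of `n` genotyped individuals are modelled as a linear combination
of genome-wide marker effects,

    y = 1 mu + X_a g_a + X_d g_d + sum_s X_s g_s + e,    e_i ~ N(0, sigma_e^2)

with one additive and one dominance effect per biallelic marker and,
optionally, four pairwise epistatic sources s in {aa, ad, da, dd} with one
effect per ordered marker pair (j < k).  Three nested models are exposed:
M0 (additive only), M1 (additive + dominance), M2 (M1 + all four pair
sources).

Genotypes enter through two codings:

* **F-infinity coding** — the additive covariate is -1/0/+1 for the rare
  homozygote / heterozygote / frequent homozygote and the dominance
  covariate is the heterozygote indicator.  Trait simulation is defined on
  this scale because its effects (allele substitution effect `a_j`,
  dominance deviation `d_j`) are the quantities with direct biological
  meaning.
* **Orthogonal (NOIA "statistical") coding** — a genotype-frequency-
  dependent recoding (Alvarez-Castro & Carlborg style) in which the
  additive column is the centered count of the frequent allele and the
  dominance column is `(-2 p12 p22, 4 p11 p22, -2 p11 p12) / v` with
  `v = p11 + p22 - (p11 - p22)^2`, evaluated per genotype class 11/12/22.
  Both columns have zero frequency-weighted mean and are mutually
  uncorrelated for arbitrary (non-HWE) genotype frequencies; under HWE the
  coding reduces to Cockerham's orthogonal contrasts.  Estimation operates
  on this scale so additive and dominance contributions are variance-
  orthogonal at every locus.

Each orthogonal column is additionally divided by its own frequency-
weighted standard deviation.  The printed source for this step is ambiguous
about the dominance divisor; we standardize each column by its own sd
(additive: sqrt(2pq) under HWE, dominance: 2pq under HWE) because only
unit-variance columns make (i) the unit-total-prior-variance rule below and
(ii) the agreement between sum-of-squares and empirical variance components
in linkage equilibrium come out right.  Epistatic covariates are
element-wise products of the standardized main-effect columns; they are
never materialized genome-wide (peak storage is O(n m), not O(n m^2)).

Markers that are monomorphic under the coding frequencies are kept as
*inert* columns (all-zero covariate, effect pinned at 0) rather than
dropped, so marker indices remain stable across training and prediction.

## Prior and estimator

Every effect of source s carries the mixture prior L*(gamma_s, lambda_s):
a point mass at zero with probability 1 - gamma_s, otherwise a zero-mean
Laplace distribution with rate lambda_s, so Var(g) = gamma_s 2/lambda_s^2.
The rate is fixed by requiring unit total prior variance per source,
m_s gamma_s 2 / lambda_s^2 = 1, i.e. lambda_s = sqrt(2 m_s gamma_s).
Defaults encode prior knowledge of the simulated architectures:
gamma_a = gamma_d = 0.005 (23-QTL scenario) or 0.05 (230-QTL scenario) and
gamma = 1e-6 for each epistatic source.

Estimation is by **iterated conditional expectation** (ICE): effects are
processed source by source (a, d, aa, ad, da, dd; within a source in index
order, pairs in row-major upper-triangle order), and each effect is set to
the analytic posterior mean given the phenotypes corrected for all other
current estimates (Gauss-Seidel: a running residual reflects every update
immediately).  For one effect with least-squares summary
Y = (X'X)^-1 X'y_corr and sigma^2 = (X'X)^-1 sigma_e^2, writing
Y± = Y ± lambda sigma^2, the posterior mean is

    E[g | Y] = (T1 ThetaU(0; Y-, s2) + T2 ThetaL(0; Y+, s2)) / (T1 + T2 + T3)

    T1 = exp(-lambda Y) P(N(Y-, s2) > 0)
    T2 = exp(+lambda Y) P(N(Y+, s2) < 0)
    T3 = 2 (1 - gamma) / (gamma lambda) exp(-lambda^2 s2 / 2) phi(Y; 0, s2)

where ThetaU/ThetaL are the means of the zero-truncated normals.  T3 (the
point-mass term) follows from the Laplace-normal convolution; the
implementation is verified against brute-force quadrature of the exact
posterior.  All three terms are computed in the log domain (log-ndtr /
complementary error function with an asymptotic tail expansion beyond 37
standard deviations) because exp(lambda |Y|) overflows double precision at
routinely occurring effect sizes.

Phenotypes are centered once up front.  Optional fixed covariates (the
real-data hook) are removed by ordinary least squares on the running
residual at the start of every outer iteration and are never shrunk.  The
residual variance is re-estimated once per outer iteration as
RSS / (n - 1).  Iteration stops when

    ||g(k) - g(k-1)||^2 / ||g(k)||^2 <= L

(squared Euclidean norms; the 0/0 case counts as converged) or at k_max.
Defaults: L = 1e-8, k_max = 1000 for M0/M1; L = 1e-6, k_max = 200 for M2.
Non-convergence is reported via a flag, not an error; replicates that fail
to converge are excluded from scenario averages and counted.
Initialization is g = 0 with sigma_e^2 = Var(y); the running residual is
recomputed from scratch every 10 iterations as a drift guard.

The direct genetic value of an individual is DGV_i = sum_s (X_s g_s)_i,
with per-source parts retained (the additive part is the breeding-value
proxy).  Variance components are reported two ways: the linkage-
equilibrium approximation sigma_s^2 = sum_j g_s,j^2 (exact only for
uncorrelated columns) and the empirical variances of the per-source
predicted values in the validation set, with the four epistatic parts
pooled into one component.

## Population simulator

The generator emulates a dairy-cattle-like population: 52,273 SNPs on a
30 Morgan genome (30 chromosomes x 1 Morgan; marker positions uniform),
effective size Ne = 100, discrete generations, random mating.  All
founders are homozygous for the same allele; variation accumulates over
400 generations through symmetric per-gamete flip mutation at rate
u = 2.5e-3 per locus per transmitted copy and recombination (crossovers
per chromosome Poisson with mean equal to the map length, positions
uniform, no interference — Haldane model; realized recombination fractions
are tested against the Haldane map function).

With these values 4 Ne u = 1, whose stationary allele-frequency
distribution is uniform, so the expected SNP heterozygosity at
mutation-drift balance is 1/3 — the simulator reproduces the target mean
heterozygosity of 0.33 without any tuning.  Mean adjacent-marker LD comes
out near r^2 = 0.12 on the full panel and 0.07 at one-tenth density.  A
property of this mutation model worth knowing: recurrent symmetric
mutation keeps almost every locus segregating, so only about 1% of loci
are monomorphic at any one time.  A scenario that simultaneously expects
heterozygosity 1/3 and a large (~10%) fixed fraction is not attainable
under this model: one-way mutation raises fixation to ~30% but drops
heterozygosity to ~0.23.  We keep the symmetric model because
heterozygosity and LD — which the estimator actually depends on — are the
calibrated quantities.

Training and test sets are paternal half-sib families: per generation, 50
sires (drawn without replacement from the previous generation's males)
each produce 20 offspring with 20 distinct dams (drawn without replacement
per family; dams may recur across families, which the data design leaves
open).  Two training generations (phenotyped, n = 2,000) are followed by
two test generations (unphenotyped), all genotyped.  Sexes alternate
deterministically so both sexes are always available.

## Trait architectures

Either 23 or 230 QTL are drawn from the analysis-panel markers with
MAF > 0.02 in the base generation (sampling QTL on the analysis grid
guarantees the fitted panel contains the causal positions).  Allele
substitution effects are |a| ~ Gamma(shape 0.42, rate 2.619) for 23 QTL or
rate 8.282 for 230 QTL, with random sign; the *rate* reading of the second
parameter is deliberate — it yields a mean simulated additive variance
near 0.76 (23 QTL), whereas the scale reading inflates the genetic
variance roughly fifty-fold.  The dominance deviation is |a| times a
N(0.193, 0.312^2) degree of dominance.  Optionally, per epistatic source,
6 (23-QTL) or 57 (230-QTL) QTL pairs are drawn (independently across
sources) with effects N(m_s, tau_s^2): m = 0.2 and tau^2 = 0.3/0.3/0.2/0.1
for aa/ad/da/dd in the 23-QTL scenario, m = 0.02 and
tau^2 = 0.03/0.03/0.02/0.01 in the 230-QTL scenario — sized so epistasis
contributes roughly a quarter of the genetic variance.

The residual variance is calibrated per replicate as
sigma_e^2 = Var(G) (1 - H2) / H2 with Var(G) the empirical variance of the
*total* genotypic values (epistatic part included) among the training
individuals, so the configured broad-sense heritability H2 in {0.5, 0.3,
0.1} is realized exactly.  The population mean is 0 (the estimator centers
phenotypes anyway).

True effects on the estimator's scale are obtained by exact change of
basis per locus, (mu, g_a, g_d)' = S_A^-1 S (mu, a, d)', and per pair via
the Kronecker transform (S_A,k^-1 ⊗ S_A,j^-1)(S ⊗ S) applied to the
9-vector (mu, a_j, d_j, a_k, aa, da, d_k, ad, dd)'.  Main-effect truths
are *marginal*: each interaction's transform is evaluated with main
effects zeroed and its additive/dominance components at both loci are
accumulated onto the participating QTL.  A single F-infinity epistatic
effect generally spreads over all four orthogonal epistatic components, so
pair contributions are accumulated per orthogonal source rather than only
into the source that generated them.  Finally every effect is multiplied
by the standardization factor of its column.  The reconstruction identity
(F-infinity genotypic values equal the orthogonal reconstruction up to a
constant) is enforced by test at 1e-8 relative for random architectures.

Coding frequencies, the frequent-allele orientation and the
standardization factors are estimated from the **training individuals
only**, frozen, and reused for test individuals and for the truth
translation — prediction never peeks at validation genotype frequencies.
QTL eligibility (MAF > 0.02) is judged in the base generation, where the
architecture is defined.  QTL positions and effects are redrawn every
replicate.  Realized narrow-sense heritability is reported as
H2 * sigma_a,true^2 / sum_s sigma_s,true^2.

## Evaluation

Accuracy is the Pearson correlation of predicted and simulated total DGV
in the test generations.  Top-10% accuracy selects the ceil(0.1 n) test
animals with the best *predicted additive* value and correlates predicted
with true additive values within the selection (truth and prediction are
additive parts only, matching the breeding-value use case).  The true
additive-to-total ratio uses the LE-style sums of squared true
standardized effects.

## Problem sizes and profiles

The `full` profile simulates the full 52,273-SNP genome and analyses
every 10th marker (5,227; MAF <= 0.01 removed).  The `scaled` profile
simulates 5,227 markers on the same 30 Morgan map directly — identical
marker density, hence essentially identical allele-frequency and LD
structure to the thinned panel — and skips the thinning step.  Replicated
scenario results in the test suite use the scaled profile with 10
replicates; the acceptance script uses 20 fitted replicates per variant
and, for the trait-only quantities (true additive variance, realized h²,
additive ratio), four additional architecture draws per simulated
population (100 draws in total): the simulated additive variance is
heavy-tailed (replicate sd ~0.58 around a mean of ~0.76, driven by the
gamma effect draws), and extra trait draws cut its Monte-Carlo error
without any refitting.  M2
is refused up front when a panel implies more than 1e9 pair effects
(memory), which rules out the full 52,273-marker panel; epistasis-recovery
tests run M2 on a 300-marker sub-panel, where planted pairs are expected
among the top-10 |estimate| pairs.

## Numerical choices

* Convergence criterion uses squared norms; an all-zero denominator with
  zero numerator counts as converged (prevents 0/0 at the null fit).
* Posterior-mean evaluation: log-domain mixture weights; truncated-normal
  means via exp(log phi - log Phi) Mills ratios, accurate to |mean|/sd of
  30 and beyond; antisymmetry in Y holds to ~1e-12.
* Orthogonality/standardization tolerances: 1e-10 on weighted moments;
  columns with weighted sd <= 1e-12 are inert.
* Degenerate loci in the truth translation (monomorphic under training
  frequencies, possible only in aggressively down-scaled configurations)
  are skipped: their standardized truth is zero and they carry no
  representable variation.
* Ties in the frequent-allele orientation (p = 0.5) resolve to allele 1.
* All randomness flows from one seed per replicate through independent
  named child streams (population / main effects / epistasis / noise), so
  with- and without-epistasis runs of the same master seed share the
  population and main effects, mirroring the paired design of the
  simulation study.

## Known limitations

* The LE variance-component formula is approximate under LD; in dense or
  many-QTL settings the empirical and LE components diverge (exposed side
  by side for exactly this reason).
* The fixed-fraction property of the mutation model discussed above.
* The estimator underestimates dominance variance when many small QTL
  segregate; no bias correction is attempted.
* No missing-genotype handling in the core (mean imputation available
  behind an explicit flag in the loaders); no multiallelic markers, sex
  chromosomes, selection, or higher-order interactions.
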