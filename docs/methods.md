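# Methods

## Setting

`ramsel` estimates breeding values in populations with the data structure
typical of layer-chicken breeding programs: discrete generations, every
sire and dam genotyped on a dense SNP panel, and large numbers of
phenotyped female progeny that are never genotyped. Selection candidates
(young genotyped birds, often males) have no phenotype of their own; their
merit must be predicted from relatives and markers.

## Reduced animal model

For a single trait the model is

    y = X b + (P + 1/2 Q S + 1/2 Q D) a + e

where `a` holds breeding values **only** for genotyped individuals with
Var(a) = K sigma_a^2, `b` is the hatch-within-generation fixed effect,
`P` indicates records on genotyped individuals, and `S`, `D` place each
non-genotyped individual's record on its sire and dam columns. A record on
a non-genotyped individual thus carries its parent average; the Mendelian
sampling deviation joins the residual, giving the heterogeneous residual
variances

* sigma_e^2 for records on genotyped individuals,
* sigma_e^2 + 1/2 sigma_a^2 for records on non-genotyped individuals.

The 1/2 ignores parental inbreeding in the Mendelian sampling variance
(exactly 1/2 (1 - (F_s + F_d)/2) sigma_a^2). This is deliberate: with
matings avoiding close relatives, parental inbreeding stays near zero and
the approximation is numerically negligible; with non-inbred parents the
reduced model reproduces the full animal model *exactly*, which is the
package's central structural test.

`K` is either the pedigree numerator relationship matrix `A` restricted to
genotyped individuals (PBLUP) or the marker-based matrix
`G = ZZ'/(2 Σ p_j(1-p_j))` with `Z` the dosage matrix centered at twice the
allele frequency of all genotyped animals (GBLUP, VanRaden method 1).
Because all non-genotyped individuals are non-parent progeny, the only
pedigree relationships used are parent-offspring ones, whose expectation
(0.5) is the same under `A` and `G`; pedigree and genomic information can
therefore be mixed without the rescaling a general single-step method
needs.

EBV for non-genotyped individuals are recovered by backsolution:
`a_i = PA_i + k (y_i - x_i'b - PA_i)` with
`k = (sigma_a^2/2) / (sigma_a^2/2 + sigma_e^2)`, or `PA_i` alone without a
record.

### Numerical treatment

* MME are solved densely by Cholesky up to 5,000 equations and by
  Jacobi-preconditioned conjugate gradients (tolerance 1e-10) above.
* The centered `G` is always singular (the all-ones vector is in its null
  space, and rank is bounded by the animal count). Rather than ridging the
  diagonal — which perturbs solutions at the size of the ridge — the
  animal equations are premultiplied by `K` (Henderson's form for singular
  covariance), which is exact; the singularity and solver branch are
  logged.
* Fixed effects use cell-means coding of the combined
  generation-by-hatch factor. The combined factor's full dummy matrix has
  full column rank, so no identifiability constraint is needed and all
  estimable contrasts agree with any constrained parameterization.
* Missing genotype calls surviving QC are mean-imputed (2 p_j).

## SNP quality control

Markers are kept when minor allele frequency > 0.025, missing-call
proportion < 0.05, and the parent-offspring opposing-homozygote rate
< 0.05 — opposing homozygotes (0/2 pairs) being impossible under Mendelian
transmission without error. The same opposing-homozygote statistic,
aggregated genome-wide per declared parent-offspring pair, serves as a
genotype-only parentage verification that flags (never drops) suspect
pairs.

## Variance components: EM-REML

For both the full animal model and the reduced model, the marginal
covariance of the records is `Var(y) = K_y sigma_a^2 + I sigma_e^2`, with
`K_y` the relationship among phenotyped animals (full model) or
`W K W' + 1/2 diag(non-genotyped)` (reduced model; `W = P + (QS + QD)/2`).
The response is projected once onto an orthonormal basis of error
contrasts (the complement of the fixed-effect column space) and the
projected `K_y` eigendecomposed; in that basis each EM-REML iteration
costs O(n). Iteration stops when both components change by < 1e-6
relative, or flags non-convergence after 500 iterations (never an
exception; EM is slow near the sigma_a^2 = 0 boundary). Because the basis
depends only on `X` and `K_y`, replicated datasets on a shared pedigree
reuse it, which keeps 20-replicate recovery studies at n = 2,000 records
in seconds.

## Bayes-C-pi

Each SNP effect is zero with probability `pi` and otherwise N(0,
sigma_alpha^2) with a **common** variance; priors are uniform(0,1) on `pi`
and scaled inverse chi-square on sigma_alpha^2 (nu_a, S_a^2) and
sigma_e^2 (nu_e, S_e^2). The Gibbs cycle per iteration: intercept; for
each SNP in fixed order the inclusion indicator from its marginal
likelihood ratio (effect integrated out, computed in log space) and, if
included, the effect from its normal full conditional with
weighted residual precision; then sigma_alpha^2 from
scaled-inv-chi^2(nu_a + m, ...) over the m included effects; sigma_e^2
from its weighted full conditional; and `pi ~ Beta(n_snp - m + 1, m + 1)`.
Posterior means accumulate over every post-burn-in iteration; thinned
samples (default every 10th) are stored for diagnostics. The kernel is
numba-compiled with one seeded generator; identical configurations give
bit-identical chains.

Training units are of two kinds:

* genotyped phenotyped individuals: own centered genotype, residual
  weight 1;
* parent-pair families of non-genotyped phenotyped progeny: the average
  parental genotype `(g_s + g_d)/2` (the expected progeny genotype)
  carries the family mean of pre-adjusted phenotypes, with residual weight

      w_p = p (1 - h^2) / (1 - 0.5 h^2),

  so a record's residual variance is sigma_e^2 / w_p. At p = 1 this
  equals sigma_e^2 + 1/2 sigma_a^2 — exactly the reduced model's
  non-genotyped residual class, which is the identity that pins down the
  formula's reading (the algebraically ambiguous alternative
  `1 - h^2(1 - 0.5 h^2)/p` is available behind `literal=True` for
  comparison). A per-progeny mode (one weighted record per non-genotyped
  daughter) is available behind a flag.

Phenotypes entering the sampler are pre-adjusted by subtracting the fixed
-effect solutions of a full animal model fitted with pedigree
relationships.

The prior scale defaults: nu_a = nu_e = 4.2; S_a^2 is set so the prior
mean of the total marker variance, `(1 - pi_0) Σ_j var(z_j) E[sigma_alpha^2]`,
matches the supplied additive variance at the starting `pi_0`, and S_e^2
likewise matches the supplied residual variance. These are conventional
weakly-informative choices; all four are exposed in `McmcConfig`.

Convergence of `pi` is assessed with two independent chains started at
0.1 and 0.99; posterior means differing by more than their pooled
posterior SDs flag a flat posterior (typical of highly polygenic traits).
Diagnostic switches (`fix_pi`, `fix_effect_variance`, `fix_indicators`)
freeze parts of the sampler; with `pi` fixed at 0 and the common variance
matched to sigma_a^2/(2 Σ p(1-p)) the sampler is a Monte Carlo ridge
regression whose GEBV must agree with GBLUP — a cross-model identity used
in the tests.

## Validation

Generation-forward: train on earlier generations, predict genotyped
final-generation females. Metrics: accuracy
`cor(EBV, y*) / sqrt(h^2)` against phenotypes corrected by the
fixed-effect solutions of a full-data animal model; the bias slope of
`y*` on EBV (1 = unbiased); mean squared deviation of slopes from 1
across traits; the mean corrected phenotype of the top-k (default 30)
individuals by EBV with an explicit direction of merit per trait (ties
broken by stable id order); parent-average EBV `PA = (EBV_s + EBV_d)/2`
to separate parental from Mendelian-sampling information; and a nested
regression `y* ~ GEBV` vs `y* ~ GEBV + PA` with a partial F-test for the
increment (a bootstrap alternative is provided; predictors correlated
beyond 0.9999 are flagged and the p-value suppressed). Accuracies are
reported unclamped: sampling noise may push them past 1 and hiding that
would misstate precision.

Two scenarios mirror the breeding timeline: *early* selection trains
without any final-generation phenotypes; *late* selection adds the
final-generation records of non-genotyped full sisters of the validation
animals, with the validation set unchanged.

## Simulator

`simulate_population` produces the structure the analysis assumes:

* a generation-0 founder parent set (all genotyped) and `n_generations`
  progeny cohorts; hierarchical matings (each sire with several dams)
  avoiding full-sib pairs; sexes alternate within family so both sexes
  always exist;
* founder haplotypes drawn at Uniform(0.05, 0.95) frequencies, either
  independently per locus or from a small ancestral haplotype pool
  (default 50) that induces linkage disequilibrium; transmission by
  Haldane recombination (Poisson crossovers per Morgan; length 0 =
  independent segregation);
* trait truth from `n_qtl` SNPs with normal effects rescaled so the
  expected founder additive variance equals sigma_a^2 exactly;
* phenotype = hatch effect + TBV + normal residual; hatch effects are
  drawn N(0, hatch_sd^2) per generation-hatch level and then treated as
  fixed in analysis; early traits recorded on all females, late traits
  only on selected females;
* truncation selection on the early-trait phenotype for females and on
  full-sib-family means for males (sib-based male selection), or random
  selection; all parents are genotyped, plus a configurable fraction of
  final-generation females (the validation set);
* optional genotyping-error and missing-call injection to exercise QC.

Defaults follow the emulated study design: 5 generations, 30 sires × 300
dams with 9 progeny per dam (~2,700 records per generation), 5 hatches
per generation, moderate heritability (0.4 early / 0.3 late), 5,000 SNPs
in 10 chromosomes of 1 Morgan. Tests and the reproduction script state
their own smaller sizes explicitly as the fixture they analyze.

What the simulator does **not** emulate: a realistic chicken genome map,
mutation, crossover interference, overlapping generations, genotype
platform artifacts beyond uniform random error, non-additive gene action,
and maternal or cage effects. Passing tests therefore demonstrate the
estimators' internal correctness and their behavior under the assumed
generative model, not performance on any real dataset.

`simulate_polygenic_tbv` additionally provides marker-free infinitesimal
breeding values down a pedigree (founders N(0, sigma_a^2), progeny =
parent average + Mendelian deviation), used for large variance-component
recovery studies where markers are irrelevant.

## Design choices and limitations

* Unknown parents are treated as unrelated non-inbred founders; no
  genetic groups or phantom parents.
* Ids are opaque strings; dense indices follow topological order.
* The relationship-comparison regression (G elements on A elements) uses
  off-diagonal pairs by default; diagonals can be included by flag.
* EBV reliabilities/PEV are not reported; multi-trait models, dominance,
  weighted-G variants and low-density panels are out of scope.
* The RAM requires both parents of every non-genotyped phenotyped
  individual to be genotyped; violations raise with the offending id
  rather than silently degrading to a single-step approximation.
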