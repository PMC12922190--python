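# Methods

`breedsim` is a forward-in-time stochastic simulator of a closed breeding
program, together with the machinery needed to compare selection strategies
that manage genetic diversity: GBLUP genomic evaluation, allele-frequency
weighting of SNP effects, kinship-penalised selection indices,
Mendelian-sampling-variance (MSV) indices, mating avoidance, optimum
contribution selection (OCS), and an evolutionary optimiser over whole
breeding-program designs. This note describes the model, the defaults and
why they were chosen, the numerical choices, and what the simulations can
and cannot say about real programs.

## Genome, trait and founders

The genome is `n_chr = 10` chromosomes of `chr_length = 2.5` Morgan, each
carrying 2,500 equidistantly spaced biallelic SNPs (spacing 0.001 Morgan;
25,000 SNPs total). A random subset of `n_qtl = 1,000` SNPs acts as
additive QTLs; effects are drawn i.i.d. standard normal and then rescaled
once so that the founder cohort's true-genetic-value standard deviation is
exactly 1. This makes the raw trait scale coincide with the founder
genetic-standard-deviation (gSD) unit; reported genetic gains are
additionally re-anchored to the first post-burn-in cohort (below).

Founders are `n_founders = 1,000` individuals with randomly sampled
genotypes. The founder allele-frequency spectrum matters a great deal for
long-horizon fixation behaviour, and two spectra are supported:

* **`freq="uniform"` (default):** a per-locus frequency `p_j ~ U(0, 1)`,
  alleles i.i.d. Bernoulli(`p_j`). Loci that start near 0 or 1 fix within a
  few dozen generations of drift, so roughly 60% of SNPs are fixed by
  generation 50 of the evaluated program — the behaviour the package's
  baseline is calibrated to reproduce.
* **`freq=0.5` (or any float):** all loci at the same frequency. The
  maximum-heterozygosity spectrum roughly halves the generation-50 fixation
  share and raises early genetic variance; it is retained for sensitivity
  analysis.

Environmental variance is calibrated once on the founders,
`sigma_e^2 = var(g_founders) (1 - h2) / h2` with `h2 = 0.3`, and then held
fixed: as genetic variance erodes under selection, the realised
heritability declines — intentionally, as in any closed program with a
fixed measurement error.

## Meiosis and identity-by-descent

Meiosis follows the Haldane model: per chromosome, a Poisson(`length in
Morgan`) number of crossovers at i.i.d. uniform positions, no interference,
with a Bernoulli(0.5) starting haplotype. Internally the source haplotype
along the genome is the parity of a single toggle array (one toggle per
crossover plus a per-chromosome reset), which makes gamete formation a pair
of vectorised blend operations over whole cohorts.

Every founder haplotype carries a distinct integer label, and meiosis
propagates labels alongside alleles. Realised inbreeding of an individual
is the fraction of SNPs at which its two haplotypes carry the same founder
label; this is exact identity-by-descent relative to the founder
generation, not a pedigree expectation. Segment views (`ibd_segments`)
derive half-open intervals from label runs on demand.

## The baseline breeding program

A replicate consists of:

1. founder sampling;
2. `burnin_generations = 10` cycles of phenotypic selection (top 40 males /
   100 females on own phenotype, pairing uniform with replacement, 1,000
   offspring) to build up linkage and family structure;
3. 50 evaluation generations. Each cycle: all 1,000 candidates are
   genotyped and phenotyped; GBLUP EBVs are computed from the current
   generation (or the last `training_window` generations pooled); the
   configured selection criterion ranks candidates; the top `n_males = 40`
   and `n_females = 100` are selected (or OCS allocates contributions); the
   next 1,000 candidates are bred. Selected parents contribute equally
   (largest-remainder rounding of 1000/40 and 1000/100) with random
   sire-dam assignment, unless a mating-avoidance rule is active, in which
   case matings are sampled uniformly over the allowed sire-dam pairs —
   accepting mildly uneven contributions, which is the behaviour the
   avoidance strategies are defined with.

Genetic gain is read off a separate **production cohort**: 1,000
individuals bred each generation from the top 40/100 candidates by plain
EBV under its own throwaway pedigree, so the diversity-managed breeding
line is not contaminated. Gain is reported in gSD units:
`(mean g_production - mean g_gen1) / sd(g_gen1)`, where generation 1 is the
first post-burn-in candidate cohort of the same replicate.

Per generation the pipeline records: production-cohort gain (raw and gSD),
candidate-cohort mean, realised IBD inbreeding, genetic variance, SNP/QTL
fixation shares (and the share of fixed QTLs fixed for the favorable
allele), and the EBV and MSV prediction accuracies.

## Genetic evaluation

**GBLUP.** The animal model `y = 1 mu + g + e` with `var(g) =
sigma_g^2 G` (VanRaden method-1 `G`, genotypes centred by allele
frequencies estimated from the training cohort) is solved in the
variance-ratio parameterisation: `g_hat = G (G + lambda I)^{-1} (y - 1
mu_hat)` with GLS mean, via one Cholesky factorisation per cycle.

**Variance ratio.** `variance_estimation="he"` (default) re-estimates the
heritability captured by `G` each cycle with a Haseman–Elston regression of
off-diagonal phenotypic cross-products on relationship coefficients,
clamped to `[0.02, 0.98]`. Re-calibration matters: with `lambda` frozen at
the founder `h2` the shrinkage is an order of magnitude too weak by
generation 50, which depresses both accuracy-driven response and
co-selection-driven drift (final inbreeding ~0.55 instead of ~0.67).
Full REML would gain little precision at the cost of an eigendecomposition
per cycle; a `"fixed"` mode retains the frozen ratio. Note that under
selection any G-based variance estimate (HE or REML) targets the
relationship-predicted variance, which the Bulmer effect holds below the
realised cohort variance; this is a property of the estimation problem a
real program faces, not an artefact.

**SNP effects.** Criteria that weight per-marker effects need `a_hat` even
though GBLUP returns individual EBVs. The minimum-norm back-solution
`a = M'(MM')^{-1} g_hat` is used; inside the pipeline it reduces
algebraically to `a = M' V^{-1}(y - 1 mu) / denom` (no second solve), and
the standalone function guards near-singular `MM'` with an escalating ridge
starting at `1e-8 tr(MM')/n`.

**MSV.** The standard deviation of an individual's gamete breeding values
is computed analytically: with `v_j = a_j (h1_j - h2_j)/2`, the gamete
variance is `sum_jk v_j v_k (1 - 2 r_jk)`, where `1 - 2 r_jk =
exp(-2 |d_j - d_k|)` under Haldane within a chromosome and 0 across. The
exponential kernel makes the quadratic form a pair of prefix sums, O(m) per
chromosome instead of O(m^2). The "true" MSV used for the accuracy metric
evaluates the same formula with the true QTL effects at the QTL positions.
Prediction accuracies (EBV and MSV) are Pearson correlations per
generation, averaged over generations and replicates; MSV accuracy is
computed on standard deviations.

**Pedigree kinship** uses the tabular method on the pedigree truncated 7
generations above the target cohort, with boundary ancestors treated as
unrelated and non-inbred. Because only selected parents reproduce, the
truncated ancestor set stays small (~2,000 individuals at full scale).

## Selection criteria

All criteria are computed per candidate; only per-sex rankings matter.
Frequencies `p_j` of the *beneficial* allele (sign of the estimated effect)
are taken from the current candidates; fixed loci get weight 1 since their
term is constant across candidates. Available weightings: the theoretically
optimal arcsine form, `p^-1/2`, `p^-1/3`, `p^-1/4`, `min(5, p^-1/2)`, and
the `d + (1-d) p^-1/2` blend. The kinship index standardises both EBVs and
mean kinships (to the cohort, or to the top-EBV 40/100 set) before
combining with weight `w_f`. MSV indices add `sqrt(2) x_p sigma` or
`sqrt(2) i_p sigma` with the sex-specific selection proportion. The
combined criterion standardises each of its five components before applying
weights `x1..x4` (residual weight on the plain EBV score); weights are not
clamped, since optimised designs can push them outside [0, 1]. Truncation
ties are broken by lower id for determinism.

## Mating control and OCS

Expected offspring inbreeding of a sire-dam pair is their pedigree kinship;
expected offspring kinship to the cohort is the mean of the parents' mean
kinships. Quantile avoidance excludes pairs strictly above the empirical
(type-7) q-quantile of those pair values; sib avoidance excludes shared-
parent pairs at the full- or half-sib level. Active rules intersect, and an
empty intersection is an error rather than a silent fallback.

Deterministic OCS fixes the pre-selected dams at uniform contributions and
maximises the contribution-weighted merit of all male candidates subject to
`c >= 0`, `sum c_m = 0.5` and the group-coancestry cap `c'Kc <=` current
mean kinship `+ delta_kin` (offspring self-kinship terms ignored, standard
group-coancestry OCS). The solver is SLSQP with analytic gradients, an LP
corner shortcut when the cap is slack, and a minimum-coancestry fallback
(flagged `feasible=False`) when the cap is unattainable. Constraint
tolerance is 1e-6 on the quadratic form; contributions are clipped at 0 and
renormalised.

Evolutionary OCS selects equal-contribution parent sets (40 males, 100
females at baseline) by a (mu+lambda) evolutionary algorithm (population
50, 5 elites, swap mutation with occasional double swaps, 10% random
immigrants, at most 1,000 iterations, stop after 50 without improvement).
Gain and group coancestry are min-max normalised against the pure-gain
(truncation) and pure-diversity corner solutions and combined as
`cos(theta) gain - sin(theta) coancestry`; `theta = 0` reduces exactly to
truncation selection.

## Design optimisation

A breeding-program design is a 9-parameter vector:
criterion weights `x1..x4`, the selection-proportion scale `x5` (males
`round(40 x5)`, females `round(100 x5)`, preserving 2:5), avoidance
quantiles `x6` (expected inbreeding) and `x7` (expected kinship), the OCS
kinship-increase cap `x8`, and the binary OCS switch `x9`. The target
function combines cumulative candidate-cohort mean genetic values (weight
2/3, scaled 1/25), the final genetic SD (1/6, scaled 9/200) and final
inbreeding (-1/6, scaled 3/10); the shorter-term variant discounts gain by
3% per generation and rescales by 1/10. The published scalings are applied
verbatim; note the diversity term uses the genetic *standard deviation*
as printed in the defining formula.

The optimiser is a generational EA: uniform initialisation over the
initialisation ranges (`x9` Bernoulli(0.5)), evaluation by simulating the
decoded scenario for `k` replicates (default 3) and averaging the target,
top-25% parents, Gaussian perturbation with per-parameter scale annealing
geometrically from 10% of the initialisation range to a 0.5% floor, binary
flips with probability 0.1, and retention of the incumbent best. Evolution
may drift outside the initialisation ranges but is clipped to an evaluable
domain (quantiles in (0, 1], positive cohort sizes, non-negative caps).
Reduced-scale base configurations are the intended way to keep design
search affordable; the search structure is scale-free.

## Problem sizes used in tests and reproduction

The shipped acceptance run uses the full study conditions (25,000 SNPs,
1,000 candidates, 10 + 50 generations) at 3 replicates, which completes in
minutes per replicate on one core. The test suite exercises strategy
contrasts at a reduced scale chosen once (5 chromosomes x 1 Morgan, 1,500
SNPs, 150 QTLs, 250 candidates, 10/25 parents, 5 burn-in + 15 evaluation
generations, 6 paired replicates) — large enough that every
diversity-managing strategy shows its inbreeding reduction with paired
seeds, small enough to run in seconds per replicate. Unit oracles
(exhaustive gamete enumeration, simplex grid search, recursive kinship,
mixed-model equations) run on toy instances where exact comparison is
feasible.

## Known limitations

* The simulated trait is purely additive and highly polygenic; no
  dominance, epistasis, inbreeding depression or new mutation. Inbreeding
  harms the program only through variance depletion.
* Generations are discrete and non-overlapping; sexes are assigned 1:1
  stochastically; there are no sex chromosomes and the genetic map is
  equidistant.
* The synthetic founders carry no linkage disequilibrium; all LD is built
  by the burn-in. Real populations start with ancestral LD, so absolute
  accuracies and long-horizon gains should be read as scenario contrasts,
  not forecasts.
* Two reported baseline statistics resist exact reproduction and are
  documented as such: the per-generation normalised inbreeding rate
  (~2.1%/generation here; the published level/endpoint pair itself implies
  ~2.2%, while the often-quoted "about 1.5%" matches the raw mean
  difference), and the mean EBV accuracy (~0.48 here vs 0.53), with the
  MSV accuracy (~0.15 vs 0.17) marginal. Gain, final inbreeding, genetic
  variance, fixation shares and the favorable-fixation share reproduce
  within replicate noise at 3 replicates.
* Deterministic OCS replicates the optimisation problem, not any specific
  solver's internals; the evolutionary OCS is a weighted-sum surrogate of
  angle-targeted mate-selection tools (no within-litter mate allocation).
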