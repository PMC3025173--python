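# Methods

## Model and likelihood

A diallelic locus with putative risk allele 2. Genotypes count copies of
allele 2; the child's genotype is recorded maternal-then-paternal ("21" =
risk allele inherited from the mother). The penetrance model is
multiplicative on the risk scale:

    P(dis | g_m, ordered g_c) = alpha * R_{g_c} * S_{g_m} * Im^[maternal 2] * Ip^[paternal 2] * gamma_{g_m, g_c}

with all eleven factors defaulting to 1 and `alpha` (the penetrance of the
all-low-risk configuration) required only when actual penetrances are needed
— it cancels from every retrospective likelihood.

Conditioning on an affected child and applying Bayes' theorem, the 16
ordered trio cells (mother x father x ordered child) have probabilities
`risk_k * mu_{mt(k)} / Sigma`. The `mu` parameters here absorb both the
ordered parental-pair frequency and the Mendelian transmission factor, which
is constant within each of the six exchangeable mating types; this is what
makes every observable structure an exact margin of one 16-cell table.
`Sigma` is implemented as the literal sum of the 16 raw weights (exact by
construction, no closed form needed), and the population prevalence is
`K = alpha * Sigma` when the `mu` are on the probability scale. The
observable trio table has 15 cells (the double-heterozygote cell is the sum
of its two ordered components, whose parental origin is not observable);
case/mother duos collapse to 7 cells, a case alone to 3, parents of a case
to the 6 mating types. Control-side structures (unrelated controls, parents
of controls, control/mother or control/father duos) are the same margins of
the *null* table — a population sample carries no risk information, only
allele-frequency / mating-type information. Controls are treated as
population samples of unknown disease status; genuinely unaffected controls
are acceptable only for a rare disease, and no common-disease correction is
implemented.

Nuisance regimes, in decreasing order of assumption strength:

| regime | free nuisance parameters | notes |
|---|---|---|
| `hwe_rm_fixed_af` | none | allele frequency fixed externally |
| `hwe_rm_free_af` | `A2` (logit scale) | HWE + random mating |
| `pae` | `mu1, mu2, mu3=mu4, mu5` (log; `mu6=1`) | parental allelic exchangeability |
| `mating_symmetry` | `mu1..mu5` (log; `mu6=1`) | exchangeable mating types only |

The likelihood depends on the `mu` only up to scale, so `mu6` is fixed at 1
during optimization and reported values are rescaled so the implied null
table is a probability distribution. Under HWE + random mating the implied
weights are `(p^4, p^3 q, p^2 q^2, p^2 q^2, p q^3, q^4)` with `p = A2`,
which satisfies the `mu3 = mu4` exchangeability identity.

## Parameterization dialects

Published models of the same penetrance family differ in where they place
the baseline and what they call an "effect". The `params` module holds exact
maps between them: the original imprinting coding (the factor follows the
allele's origin everywhere) vs. the later one (the factor applies only to
heterozygous children; its homozygote risk equals `R2 * I` of the original
coding — verified numerically by table equality); the maternal-fetal
genotype incompatibility (MFG) parameterizations 1A/1B (`rho, eta, mu0,
mu2`), whose incompatibility parameters map to `gamma01`-/`gamma21`-style
interactions (`mu0 = 1/gamma11` etc. under the identification
`gamma12 = gamma21 = 1`); the matching model (`mu = gamma11`); a log-scale
additive/dominance coding with a heterozygote parent-of-origin term and a
mismatch term (both solved exactly against the collapsed table, since that
dialect is saturated); a saturated per-cell table; and an
`Rm/Rp` coding where testing imprinting is testing `Rm = Rp`. Every
conversion is verified by a cell-by-cell round trip at relative tolerance
1e-10; dialects that only constrain the 7 observable cells (saturated,
log-scale) are checked on the collapsed table with the double-heterozygote
mixture weight. The relations among imprinting codings were derived here
and validated against the numerical table-equality oracle rather than
transcribed.

Identifiability bookkeeping: from trios, seven relative-risk parameters are
estimable; the canonical convention fixes `Ip = gamma12 = gamma21 = 1` and
estimates `{R1, R2, S1, S2, Im, gamma11, gamma22}` (a mirror convention
fixing `Im` is selectable). Each reported parameter carries the composite it
represents if the fixing assumption fails (e.g. "R2" is really
`R2*gamma12`). Duo-only data support at most six free parameters in total.

## Fitting

Direct maximization (L-BFGS-B) of the joint log-likelihood over
log-transformed risk parameters and transformed nuisance parameters
(logit-`A2` or log-`mu`), gradient tolerance 1e-9, up to three seeded random
restarts on non-convergence. The null model (all risk factors 1, nuisance
profiled) is fitted alongside; if the optimizer leaves a full model below
its nested null the full fit is re-polished from the null optimum. Standard
errors come from the inverse observed information, computed by central
finite differences on the transformed scale. A fit is flagged
non-identifiable when the information-matrix condition number exceeds 1e10
**or** when the free-parameter count reaches the total multinomial degrees
of freedom — a saturated retrospective fit reproduces the observed cell
frequencies exactly, so its parameters are separated only by model curvature
(this is how an allele frequency "estimated" from duos alone with a full
five-parameter model manifests: the fit converges, the condition number is
~1e8, and the estimates are meaningless). Cells with fitted probability
approaching 0 are floored at 1e-300 inside logarithms solely to keep the
optimizer finite; a zero-probability cell with a nonzero count reports a
log-likelihood of -inf rather than raising.

Method presets (duos unless noted): 0 = prospective logistic regression of
case vs. control duos (an IRLS/Newton fit implemented in-package, with
cell-level covariates coded from the chosen parameterization; the ambiguous
double-heterozygote imprinting covariate uses the fractional weight `A1`
plugged in from the control duos); 1 = fixed allele frequency; 2/2a = free
allele frequency (2b: free `mu`, trios); 3/4 = controls / parents of
controls under HWE+RM; 5/6 = parents of controls under PAE / mating
symmetry; 7/8/9 = control-mother duos under the same three regimes.
Likelihood-ratio tests use the difference in free *risk* parameters as df
(nuisance profiled under both hypotheses); model sequences are compared by
`AIC = 2k - 2 loglik` with `k` counting free risk plus free nuisance
parameters, ties breaking toward the earlier model in user order.

## Apparent relative risks and power

`grr.apparent_grr` enumerates the joint distribution of (mother, father,
ordered child, disease) under HWE + random mating and returns the genotype
relative risks a naive comparison would estimate — conditioning on the
child's genotype (cases vs. controls) or the mother's (mothers of cases vs.
mothers of controls). Enumeration is used instead of closed forms; it makes
the key identities exact: a maternal imprinting effect produces *identical*
apparent risks in both analyses, a paternal imprinting effect is invisible
in the mothers, and child-only effects attenuate in the mothers (for
multiplicative-to-dominant models; a strongly recessive child model instead
shifts the mothers' pattern toward dominance and can raise their
heterozygote risk above the child's). `grr_power` is a Pearson 2-df genotype
test power approximation via the noncentral chi-square with the
noncentrality evaluated at expected genotype frequencies; it approximates
dedicated genetic power calculators and was validated against a Monte-Carlo
rejection rate.

## Synthetic data

`simulate` draws parental genotypes under HWE + random mating, transmits
alleles by Mendel with recorded origin, and ascertains case-side structures
by rejection: a family enters the sample with probability equal to the
child's ordered-origin penetrance. The generator's defaults are the study
conditions used throughout: ten scenarios A–J, all with `A2 = 0.3` and
baseline risk `alpha = 0.1`, child effects `(1.5, 2.25)`, maternal effects
`(1.5, 2.25)`, imprinting `1.8` and interactions `0.5` in the combinations
listed by `scenario_table()`; the largest cell penetrance across scenarios
is `0.1 * 2.25 * 2.25 * 1.8 = 0.911`, validated ≤ 1. Population
stratification mixes two subpopulations (default 50/50, a choice made here
since the mixing proportion is otherwise unspecified; baseline risks
0.1/0.05 and allele frequencies 0.3/0.15 in the standard configuration) by
*joint* rejection across the mixture, so higher-risk strata are
automatically over-represented among case families — fixing per-stratum
counts at the mixing proportions would erase exactly the confounding the
design exists to study. What the generator does **not** emulate: genotyping
error, missing genotypes within a collected structure, linked loci / LD,
X-linkage, non-random mating within strata. Passing tests therefore
demonstrate correctness of the estimator under its own sampling assumptions,
not robustness to those artefacts.

## Evaluation harness and problem sizes

`evaluate.run_study` repeats simulate-and-fit over seeded replicates
(replicate r uses `base_seed + r`) and reports per-parameter means/SDs of
log-estimates, rejection proportions at 0.05/0.01/0.001 with binomial
Monte-Carlo SEs, and the total estimated SE (set to 0 when a parameter or
its variance was inestimable — such replicates are reported, never silently
dropped). `misspecification_study` adds the deterministic reference for
"expected estimates under the wrong model": the analysis model fitted to the
exact expected cell probabilities of the generating model.

Problem sizes used in the shipped studies: 500 units per structure (the
standard design), 200 replicates for parameter-recovery summaries and 2,000
for type-I-error and stratification-robustness checks, chosen to give
binomial Monte-Carlo SEs of about 0.005 at the 0.05 level. The acceptance
script reruns these sizes end-to-end.

## Numerical choices and limitations

* Cell orderings are frozen, documented constants (trio cells "1"–"15" in
  the standard row order; duo cells from (22,22) down to (11,11)); count
  files must follow them.
* The double-heterozygote mixture weight defaults to `A1` under HWE +
  random mating and to 0.5 where no allele frequency is in scope.
* The logistic comparator's design matrix is checked for full column rank;
  collinear covariate sets (e.g. `Im + Ip` together with `R1, R2`) raise an
  identifiability error.
* Finite-sample 4-df LRTs at n=500 duos show a very slight anticonservatism
  (empirical level ≈ 0.051–0.057 at nominal 0.05), consistent with
  chi-square asymptotics.
* Covariate adjustment and principal-component stratification correction
  are out of scope (covariates do not enter a multinomial likelihood
  naturally); only the mating-symmetry trio analysis is robust to
  population stratification, and no duo-based method is.
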