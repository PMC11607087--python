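# Methods

`matriline` partitions repeated measurements of a quantitative behavioural
phenotype — here the isotopic trophic position of female brown bears —
into the sources that can make individuals differ for life: social
learning of the mother's diet, shared environment, additive genes,
maternal identity, and permanent individual effects. This note documents
the models, the estimators, the synthetic-data generator and the numerical
choices, in enough detail to re-derive every computation in the package.

## Trophic position

A hair sample's δ15N (‰ vs. AIR) is converted to a dimensionless trophic
position against a strict-herbivore baseline consumer (moose hair):

    TP = (δ15N_bear − mean(δ15N_baseline)) / TEF + λ

with TEF = 3.4 ‰ per trophic level (the canonical nitrogen enrichment
factor) and λ = 2, the trophic level of a primary consumer. The baseline
mean and sample SD (n−1 denominator) are estimated from the baseline
table at ingest; downstream code only ever sees the TP column. TP is
affine in δ15N, so tissue-offset corrections of the baseline (hair vs.
meat) would shift all values equally without changing their distribution;
none is applied. No bounds are enforced on TP — observed ranges are data,
not constraints.

## The mixed model and its sampler

All inference runs through one Gaussian hierarchical model,

    y = Xβ + Σ_k Z_k u_k + ε,   u_k ~ N(0, σ²_k K_k),   ε ~ N(0, σ²_R I),

where each random term k groups observations by a factor and may carry a
known level covariance K_k:

* **individual** — identity, K = I; permanent between-individual variance V_I;
* **genetic** — identity with K = A, the additive relationship matrix from
  the pedigree (tabular method over a topologically sorted pedigree,
  unknown parents treated as unrelated founders; the pedigree is pruned to
  phenotyped individuals plus their ancestors before A is built, and A is
  then subset to the phenotyped individuals — a valid marginal of the
  multivariate normal); variance V_A;
* **maternal** — mother identity, K = I; variance V_M;
* **environment / spatial** — identity with K = E or S, a similarity
  matrix over home ranges (below); variance V_E or V_S.

Continuous covariates are centred and divided by their sample SD;
second-order polynomials square the scaled covariate; interactions
multiply the scaled parents. The hybrid animal model's fixed effects are
a quadratic in time since family breakup (tag "Age") and, for the social
learning term (tag "SL"), the mother's posterior trophic position plus
its interaction with the first-order time term (a quadratic interaction
is available as an option but off by default, since the decay of the
maternal influence is adequately captured at first order).

**Priors.** β ~ N(0, (10·sd(y))²); every SD (each random term and the
residual) has a half-Student-t(3, 0, 2.5·sd(y)) prior. These are the
package's defaults and are configurable through the prior scale constants
in `matriline.model`.

**Sampler.** A blocked conjugate Gibbs sampler, exact for this model
family. Structured effects are whitened (u_k = L_k v_k with L_k the
Cholesky factor of K_k) and each half-t SD is expanded multiplicatively:
σ_k = |ξ_k|·φ_k with ξ_k ~ N(0, (2.5·sd(y))²) and φ²_k ~ InvGamma(3/2, 3/2),
which reproduces the half-t(3) prior exactly while decoupling the
funnel-shaped dependence between a variance and its levels. Per iteration:

1. all Gaussian locations (β and every whitened block) are drawn jointly
   from their multivariate-normal full conditional when the stacked
   dimension is ≤ 400; above that, blocks are drawn sequentially with an
   interweaved (ASIS) recentering move that exchanges a location shift
   between the intercept and each random term, and the joint draw is
   refreshed every tenth iteration;
2. φ²_k and the scalar ξ_k are drawn from their conjugate conditionals;
3. σ²_R is drawn via the inverse-gamma mixture representation of its
   half-t prior, floored at 1e−8·var(y) so exactly-interpolating inputs
   cannot collapse the location precision.

Defaults follow the study's reported run lengths: 4 chains × 6000
iterations, 3000 warmup, thinning 10 → 1200 retained draws. R-hat and
bulk effective sample size come from `arviz`; `summary()` refuses to
report when any R-hat ≥ 1.01 or any ESS ≤ 400 (draws remain accessible
for diagnosis). Per-observation Gaussian log densities feed
PSIS-LOO (`arviz.loo`); a model is preferred over a simpler one only when
its elpd advantage exceeds 4.

## Similarity matrices

Habitat features per home range are the proportion of mature forest, the
proportion of disturbed forest, and the Simpson diversity 1 − Σp² of the
habitat class fractions. Each feature is z-scored (making the matrix
invariant to affine rescaling of any input), pairwise Euclidean distances
d are taken in that space with equal feature weights, and similarity is
1 − d/max(d), so identical ranges score 1 and the most dissimilar pair
scores 0. The spatial variant applies the same transform to Euclidean
distances between home-range centroids (planar km; the study extent of
~170 km does not warrant geodesics). The linear distance-to-similarity
map is a documented choice — a min–max on distances followed by inversion
would deny near-identical pairs a similarity of 1 — and is structurally
parallel between the E and S variants; an exponential-decay kernel would
be a reasonable alternative and can be swapped in by callers.

Because 1 − d/dmax is not guaranteed positive semi-definite, matrices are
projected before use: eigenvalues clipped at 1e−8, the matrix rebuilt and
rescaled to a unit diagonal; an already-PSD matrix passes through
unchanged. The model constructor rejects non-PSD covariances rather than
projecting silently.

## Variance decomposition

Per posterior draw, the fixed-effect variance is the variance of the
population-level fitted values Xβ across observations; each random term
contributes its σ²; V_P is the sum of all components plus σ²_R. The fixed
variance is split between term groups ("SL" vs. "Age") by semi-partial
contributions — the drop in fitted-value variance when a group's
coefficients are zeroed — rescaled to sum exactly to the full
fixed-effect variance (commonality-style partitioning; negative
semi-partials under suppression are clipped at zero first, and if every
semi-partial vanishes while the fixed variance is positive, each group's
own predictor variance is used as the weight). Proportions are summarized
by posterior median and mean with 89% equal-tail intervals (5.5th–94.5th
percentiles); a component is *inconclusive* when its lower limit falls
below 0.001. Repeatability is V_I/(V_Age + V_I + V_R) from the basic
model; because the denominator choice matters, the variant without V_Age
is always reported alongside. Nakagawa's marginal and conditional R² are
V_fixed/V_P and (V_fixed + ΣV_random)/V_P per draw.

**Known limitation — dilution of the residual share.** At the emulated
study size (~70 individuals, ~220 samples) the genetic and environmental
scales are weakly identified, and the half-t prior keeps their posteriors
away from zero; the summed V_P is therefore slightly inflated and the
residual proportion is diluted by roughly 0.08 on average in recovery
experiments, while the structural components (genetic, maternal,
environment, individual) are recovered with 89%-interval coverage at or
above their nominal level. This is a property of the estimator family,
not of this implementation; it should be kept in mind when reading the
residual row of any decomposition at small sample sizes.

## Social-learning analyses

Mother–offspring correlations are Pearson correlations of offspring
trophic position against the mother's posterior trophic position within
closed integer bands of years since separation (1–2, 3–4, 5+; the upper
band unbounded). Sample pairs are the rows, so repeated measures of one
offspring each count once (df = n − 2), matching how the field reports
them; an individual-averaged variant is provided as a sensitivity output.
The sex-specificity analysis fits {maternal TP, maternal TP + sex,
maternal TP × sex} with an individual random intercept on both-sex
samples from the first two years after separation and compares them by
PSIS-LOO with the elpd > 4 rule, preferring the simplest adequate model.
The paternal analysis regresses offspring TP on the father's posterior TP
the same way against an intercept-only null. Parental posterior trophic
positions come from a population-wide per-sex model (quadratic age +
individual intercepts); each parent's value is the posterior median of
(population intercept + their random intercept).

## Permutation test for V_A

The reduced "basic animal model" (intercept, individual, genetic,
residual) is fitted to the observed data; the statistic is the posterior
mean of σ²_A/(σ²_I + σ²_A + σ²_R). Dam–sire pairs are then randomly
reassigned to sibships — preserving the pair multiset and sibship sizes
while breaking the phenotype–pedigree link — and the model is refitted on
each permuted pedigree (shortened single-chain MCMC by default, since
only a point summary is needed). The headline p-value is the raw
proportion of permuted statistics ≥ the observed one; the (b+1)/(m+1)
variant is reported alongside. Non-converging permuted fits are counted
and excluded. Two practical notes: (i) for calibration studies the
observed statistic should be computed with the same shortened settings as
the permuted ones, keeping the statistic exchangeable under the null;
(ii) when every individual carries repeated measures and most variance is
between individuals, σ²_A and σ²_I form a posterior ridge and the
statistic loses power — single-measure designs isolate the pedigree
signal much more sharply.

## Synthetic-data generator

The generator emulates the study's sampling design; its defaults are the
study conditions and are not tuned per experiment:

| parameter | default | meaning |
|---|---|---|
| `n_mothers` | 33 | founder mothers |
| `daughter_count_probs` | median 2, range 1–6 | daughters per mother (~71 total) |
| `obs_count_probs` | median 3, range 1–11 | annual samples per daughter (~220 total) |
| `sigma2_a, m, e, i, r` | 0.0012, 0.0044, 0.0020, 0.0036, 0.0236 | variance components (3/11/5/9/59% of 0.04) |
| `beta_sl`, `t_star` | 1.0, 5 y | social-learning weight at separation, linear decay horizon |
| `grand_mean_tp` | 2.9 | population mean trophic position |
| `extent_km` | 95 | study extent (median pairwise distance ≈ 49 km) |
| `dispersal_median_km` | 8.56 | daughter settlement distance from the natal range |
| `habitat_range_km` | 12 | e-folding range of habitat autocorrelation |
| baseline | 1.8 ± 1.26 ‰, n = 21 | moose δ15N distribution |

Pedigree: each mother mates with up to two sires from a 20-male pool,
producing full and paternal half-sibs; sons are optional (for the
sex-specificity analysis) and are sampled only in their first two years
of independence. Environment: mother centroids are uniform over the
extent; daughters settle at a log-normal distance (median 8.56 km,
log-SD 0.55) in a uniform direction; two latent Gaussian fields with
exponential covariance exp(−d/12 km) are pushed through a softmax to give
the three habitat class fractions, from which Simpson diversity is
computed with the package's own function. Phenotypes follow the
generative animal model; the maternal phenotype transferred by social
learning is the mother's own latent trophic position (grand mean + her
breeding value + environmental + permanent effect), weighted by
max(0, β_SL(1 − t/t*)) at t years since separation (an exponential decay
is available). δ15N values are back-computed by inverting the trophic
formula so the isotope module is exercised end to end, and mothers and
sires receive their own repeated samples so the population-wide parental
model can be fitted. A ledger stores every latent value and reconstructs
each observation exactly.

What the generator does not emulate: bear demography and survival,
movement within home ranges, temporal change of habitat composition,
measurement batch effects, and non-Gaussian diet distributions. Passing
tests therefore demonstrate the statistical machinery under the model's
own assumptions, not robustness of the field inferences to violations of
them.

**True proportions.** The ledger's "true" proportion of a component is
its nominal σ² over the nominal total plus the realized variance of the
social-learning contribution across the generated observations (the age
contribution is structurally zero). Realized finite-sample variances of
the latent draws fluctuate around the nominal values — at 33 mothers the
realized maternal variance has a CV of about 23% — which is part of what
the coverage experiments measure.

## Problem sizes used in the checks

The test suite runs everything at desk scale: the recovery experiment
uses 25 replicates of the full two-step pipeline at the emulated study
size with 4 chains × 1500 iterations (700 warmup, thin 2); the
permutation calibration uses 12 null experiments × 50 permutations with
shortened single-chain refits; the known-truth decomposition check uses
~400 observations of ~200 individuals drawn from the model's own design
matrices. `scripts/acceptance.py` re-runs the complete pipeline —
including the sex, paternal and permutation analyses (150 permutations) —
on one seeded synthetic study with 4 chains × 3000 iterations.

## Degenerate inputs and tie-breaks

Zero-variance covariates and features are rejected with the offending
name; duplicate (individual, year) sample rows, pedigree cycles and
duplicate ids are reported with row context; a single baseline value
yields an undefined (NaN) SD rather than 0; coincident home-range
centroids are allowed (distance 0) but a fully degenerate distance matrix
is not; grouping levels absent from a supplied covariance are an error
rather than being silently dropped. Model comparison prefers the simpler
model on ties by construction of the elpd > 4 rule.
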