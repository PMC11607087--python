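# matriline

Why do individuals of the same wild population eat consistently different
diets? `matriline` is a Python package for attributing lifelong individual
dietary specialization — measured as the isotopic trophic position of
repeated hair samples — to its sources: **social learning** of the
mother's diet during rearing, **environmental similarity** among home
ranges, **additive genetic** effects over a pedigree, **maternal
identity** effects, and **permanent individual** effects. It was built
around a multigenerational study design of female brown bears
(*Ursus arctos*) in which daughters are philopatric, so space, genes and
maternal influence are badly confounded and must be separated by model
structure rather than by sampling.

The package is organised the way statsmodels organises model code: a
`MixedModel` is built from a data frame and a declarative `ModelSpec`
(fixed terms, random terms with optional covariance matrices), and
`fit()` returns a `MixedModelResults` object carrying posterior draws,
convergence diagnostics, `summary()`, variance partitioning and PSIS-LOO
model comparison. Everything else — isotope conversion, pedigree
relatedness, habitat similarity matrices, the permutation test, the
synthetic-data generator and the CLI — feeds that pair.

## The model

Trophic position is computed from hair δ15N against a strict-herbivore
baseline (moose), TP = (δ15N − mean δ15N_baseline)/3.4 + 2, and modelled
with a Gaussian hierarchical "animal model":

    TP_it = β₀ + f(t_it) + β_SL·TP_mother(i) + β_SL×t·TP_mother(i)·t_it
            + a_i + m_mother(i) + u_i + p_i + ε_it

where t is years since family breakup, f is a scaled second-order
polynomial, `a ~ N(0, σ²_A·A)` are breeding values over the pedigree's
additive relationship matrix, `m` is a mother-identity effect, `u ~
N(0, σ²_E·E)` is structured by home-range habitat similarity (or spatial
proximity, the S-variant), `p` is a permanent individual effect and ε is
residual. The maternal trophic position covariate is itself estimated
from a population-wide model (quadratic age + individual intercepts) and
its fixed-effect variance is split from the age polynomial by
commonality-style semi-partial partitioning. All components are reported
as proportions of the total phenotypic variance with 89% equal-tail
credible intervals; fitting is by an exact blocked Gibbs sampler with the
parameter-expanded half-t priors described in `docs/methods.md`.

Because the original field data are restricted, the package includes a
first-class synthetic-data generator (`matriline.simulate`) that emulates
the study design — 33 mothers, 1–6 daughters each, 1–11 annual samples
per daughter, philopatric settlement with 8.56 km median dispersal,
spatially autocorrelated habitat — so every stage is verifiable by
parameter recovery.

## Worked example

```python
import matriline as ml

# a complete synthetic study under the emulated design
ds = ml.simulate_dataset(ml.SimulationConfig(seed=1, include_sons=True))

result = ml.run_study(ds, settings=ml.McmcSettings(
    chains=4, iterations=3000, warmup=1500, thin=5, seed=1))

print(result["decomposition"].summary().round(3))
```

which prints (proportions of total phenotypic variance):

```
     component  median   mean  ci_low  ci_high  inconclusive
0          Age   0.004  0.007   0.000    0.020          True
1           SL   0.018  0.027   0.001    0.078         False
2   individual   0.024  0.042   0.000    0.147          True
3      genetic   0.025  0.048   0.000    0.167          True
4     maternal   0.172  0.179   0.038    0.340         False
5  environment   0.069  0.120   0.001    0.401          True
6     residual   0.588  0.577   0.380    0.748         False
```

Read: in this generated population, maternal identity (17%) and
environmental similarity (7%) carry most of the structured variance; the
genetic share (2.5%, lower CI < 0.1%) is *inconclusive* — the data cannot
rule out zero heritability — and the social-learning fixed effect
contributes a small share whose interaction with time encodes its decay
after family breakup. `result["repeatability"]` gives the basic-model
repeatability (here 0.29 [0.16, 0.41]), and
`result["correlations"]` the windowed mother–offspring correlations.

The same analysis runs from the shell:

```bash
matriline simulate --seed 1 --out-dir study/
matriline run-all --config study/run.yaml --out-dir study/results/
matriline report --results-dir study/results/ --plots
```

`run-all` writes the decomposition, draws (columnar CSV), diagnostics,
correlation tables and a manifest (config hash, seed, version) from which
the run is exactly reproducible.

## Input formats

CSV throughout (UTF-8, header row):

* samples: `bear_id, year, d15n, age, years_since_separation, mother_id,
  father_id, sex` — one hair sample per row; empty `father_id` = unknown,
  empty `years_since_separation` = dependent offspring;
* baseline: `d15n` — one baseline-consumer sample per row;
* pedigree: `id, dam, sire` — empty cell = unknown parent;
* home ranges: `bear_id, centroid_x_km, centroid_y_km, prop_mature,
  prop_disturbed, simpson_diversity`.

See `docs/methods.md` for the statistical model, the sampler, the
generator's assumptions and known limitations.
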