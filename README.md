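# covrn — covariance reaction norms for life-history trade-offs

`covrn` fits hierarchical bivariate models in which the **correlation**
between two vital-rate traits (e.g. litter size and offspring mass) is
itself a regression on environmental covariates, on the atanh (inverse
hyperbolic tangent) link:

```
atanh(r(C)) = X3 · beta_r
```

so that a trade-off can strengthen, vanish, or flip sign across
environmental contexts (years). The package bundles:

- **`covrn.linkbias`** — the closed-form calculus relating
  observation-level, among-individual and within-individual correlations
  via trait repeatabilities (`r_obs = r_α √(R1 R2) + r_ε √((1−R1)(1−R2))`),
  including sign-bias region grids and CSV export.
- **`covrn.simulate`** — individual-based simulators: an open population
  with yearly recruitment and survival expressing two correlated traits,
  in four layouts (intergenerational quantity–quality, intraindividual
  growth–fecundity, and marmot-/sheep-style schema lookalikes with year
  random effects and ordinal fecundity). Ground truth is returned for
  recovery experiments.
- **`covrn.modelspec`** — declarative model specs for three variants
  (`full`, `non_repeated`, `hybrid`), per-trait families
  (Gaussian, Poisson-log with optional zero truncation, cumulative-logit
  ordinal), internal covariate standardization, priors, and YAML
  round-tripping; plus `marmot_preset` / `sheep_preset`.
- **`covrn.inference`** — Bayesian fitting by a built-in gradient-based
  No-U-Turn sampler over hand-derived analytic gradients (no external
  probabilistic-programming dependency), with split-chain Gelman–Rubin
  diagnostics, 50%/89% credible intervals, and prior-only sampling.
- **`covrn.postprocess`** — correlation reaction-norm curves over
  covariate gradients, posterior predictive checks, and recovery reports.
- **`covrn.io` / `covrn.cli`** — long-format CSV ingestion/validation and
  an umbrella CLI.

Latent effect pairs are parameterized non-centered; Gaussian traits with
one measurement per (individual, context) contribute their latent
deterministically (the residual *is* the latent), so only non-Gaussian
sides carry sampled latent vectors. All gradients are verified against
finite differences in the test suite.

## CLI

```bash
# generate a synthetic quantity–quality dataset + ground truth
covrn simulate --design intergenerational --seed 1 --out data/

# validate a dataset against a model spec's structural invariants
covrn validate --data-dir data/

# fit by MCMC (defaults: 3 chains, 1000 warmup, 3000 samples)
covrn fit --data-dir data/ --seed 1 --out fit/

# correlation curve along one covariate; posterior predictive checks
covrn predict-corr --data-dir data/ --covariate climate --out curve.csv
covrn ppc --data-dir data/ --out ppc.csv

# end-to-end simulate + fit + recovery report
covrn recover --design intraindividual --seed 1 --out recovery/
```

Datasets are three CSVs (`trait1.csv`, `trait2.csv`, `contexts.csv`;
UTF-8, comma-separated, header row) plus `metadata.yaml`. Model specs
serialize to YAML so any run is reproducible from config + seed alone.

## Notes

- Coefficients are reported on both the internal standardized-covariate
  scale and the raw data scale (`PosteriorResult.draws` /
  `.draws_raw`).
- For `non_repeated` and `hybrid` variants the estimated correlation is
  the *observation-level* correlation; it equals the among-individual
  correlation only up to repeatability weighting, and can even flip sign
  when among- and within-individual correlations oppose each other with
  low repeatabilities (see `covrn.linkbias.bias_grid`).
- Repeatabilities supplied to `linkbias` functions are assumed already
  adjusted for mean (fixed-effect) structure.
- Latent SDs are constant across contexts (intercept-only variance
  model); context covariates act on the correlation only.
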