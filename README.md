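# spatrisk

Small-area disease mapping for epidemiologists: standardized incidence
ratios, non-spatial Poisson regression, and Bayesian spatial smoothing of
relative risks with the Besag–York–Mollié (BYM) convolution model, fitted
by a built-in Metropolis-within-Gibbs sampler. The package ships a complete
worked application: colorectal-cancer counts for Iran's 30 (pre-2010)
provinces, 2005–2008, by sex, with a hand-encoded provincial neighbour
graph.

## The model

For area i with observed count O_i and internally standardized expected
count E_i, the crude relative-risk estimate is the standardized incidence
ratio SIR_i = O_i / E_i. Smoothed estimates come from

    O_i ~ Poisson(E_i θ_i)
    log θ_i = α + β₁ UER_i + β₂ MHI_i + u_i + δ_i

where u_i ~ N(0, σ²) is an exchangeable (unstructured) random effect and δ
is an intrinsic conditional autoregressive (ICAR) field over the neighbour
graph — δ_i given its neighbours is Normal with mean the neighbour average
and precision τ·m_i — identified by a sum-to-zero constraint. Priors:
α ~ N(0, 100), β_j ~ N(0, 1), σ ~ half-Normal(0, 1000),
τ ~ Gamma(0.5, 0.0005). Dropping u and δ gives the non-spatial Poisson
GLM (offset log E_i), fitted by IRLS. Models are compared with
DIC = D̄ + p_D, p_D = D̄ − D̂.

## Worked example

```python
import spatrisk as sp

ds = sp.load_table1_fixture()                # 30 provinces x 2 sexes + adjacency
male = sp.compute_sir(ds, "male").summary
print(f"male: n={male.total_cases} mean={male.mean:.2f} sd={male.sd:.2f} "
      f"max={male.max:.2f} min={male.min:.2f}")

cfg = sp.BymConfig(n_iterations=20_000, burn_in=2_000, seed=20080101)
sample = sp.fit_bym(ds, covariates=(), config=cfg, sex="male")
surface, params = sp.summarize_posterior(sample)
top = surface.table.nlargest(2, "rr_mean")[["area", "rr_mean", "exceedance_prob"]]
print(top.to_string(index=False))

spatial = sp.dic_from_draws(sample)
glm = sp.dic_report_from_glm(sp.fit_poisson_glm(ds, (), sex="male"))
print(sp.compare_models([spatial, glm])[["model", "dic", "p_d"]].to_string(index=False))
```

prints

```
male: n=12155 mean=1.92 sd=3.25 max=10.85 min=0.16
           area   rr_mean  exceedance_prob
east_azerbaijan 10.814788              1.0
      khuzestan 10.513637              1.0
      model          dic       p_d
    spatial   274.162254 29.677716
non-spatial 13956.170895  1.000000
```

The SIR line reproduces the published per-sex summary of these counts.
The spatial fit barely shrinks East Azerbaijan's crude SIR of 10.85 (its
expected count is large enough that the data dominate), assigns it an
exceedance probability of 1.0 (θ almost surely above 1), and the
convolution model's DIC is smaller than the intercept-only GLM's by a
factor of about fifty, because the counts are wildly over-dispersed
relative to a common-risk Poisson model.

A command-line interface mirrors the library: `spatrisk validate`, `sir`,
`fit-glm`, `fit-bym`, `simulate`, `compare`, `map` (choropleth export onto
any GeoJSON with an `area` property). See `spatrisk --help`.

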