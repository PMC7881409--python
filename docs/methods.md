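# Methods

## Problem and data

`spatrisk` estimates small-area relative risks of disease from
province-level counts. The packaged application is colorectal cancer in
Iran's 30 pre-2010 provinces (2005–2008): for each province i and sex we
have an observed count O_i and an expected count E_i from internal
standardization. The crude relative-risk estimate is the standardized
incidence ratio SIR_i = O_i / E_i; because several provinces have small
expected counts, the SIRs are noisy and are smoothed with a hierarchical
Bayesian spatial model.

The count fixture is transcribed verbatim from the published
observed/expected table, including rows that look anomalous relative to
their neighbours (West Azerbaijan's female expected count of 330.51 against
a male value of 63.80, Kermanshah's 27.99, Khuzestan's 33.52/45.71). These
are plausibly typesetting artefacts in the source, but no correction is
defensible without the original registry data, so the fixture keeps them
and the extreme SIRs they induce (Kermanshah and Khuzestan join East
Azerbaijan and Ardabil among the highest) are treated as data. The
both-sexes summary row of the source (mean 1.83, sd 3.28, max 11.11) is
not exactly reproducible from the printed per-sex counts under either
count-pooling or SIR-averaging — it was likely computed from unrounded
expected counts — so only the per-sex summaries are used as golden values.
"Both sexes" in this package always means counts pooled per area before
any ratio is taken.

The neighbour graph for the 30 provinces is hand-encoded from the 2006
administrative map (Tehran includes present-day Alborz; Tabas counted in
Yazd). Published analyses of these data never print their adjacency list,
so the fixture asserts only structural invariants (symmetry, connectivity,
no self-loops) and any edge-list or GeoJSON file can replace it.

## Standardization and SIR summaries

Internal (indirect) standardization applies the pooled study population's
stratum-specific rates to each area's stratum populations:
E_i = Σ_s n_is (O_·s / n_·s). This conserves totals, Σ E_i = Σ O_i, which
is a tested invariant (to 1e-9 relative). SIR summary tables use the
arithmetic mean and the sample (n−1) standard deviation across areas; the
sample sd is fixed by the data, being the convention that reproduces the
published dispersion values from the printed counts. Golden comparisons
round half-to-even at two decimals, matching printed precision. The crude
incidence rate per 10^5 person-years is implemented (10^5 · cases /
person-years) but needs an external person-years input; no census
denominators ship with the package.

## Non-spatial model

The non-spatial analysis is a Poisson GLM with log link and offset:
O_i ~ Poisson(E_i exp(α + β'x_i)), fitted by IRLS (statsmodels is the
engine behind `fit_poisson_glm`). Reported: MLEs, observed-information
covariance, exp(β) with Wald 95% intervals exp(β̂ ± 1.96 se), deviance,
−2 log L = −2 Σ [O_i log μ_i − μ_i − log O_i!], and a plug-in
DIC = −2 log L + 2p. Wald intervals rather than profile likelihood match
the usual presentation of such tables. Covariates are not rescaled by
default; a z-scoring option exists. Tests check the fit against closed
forms (intercept-only = pooled ratio; binary covariate = two-group rate
ratio) and against an independent iteratively-refined grid search of the
likelihood.

## Spatial convolution model

The spatial model is the Besag–York–Mollié convolution on the log relative
risk:

    O_i ~ Poisson(E_i θ_i),  log θ_i = α + β1 UER_i + β2 MHI_i + u_i + δ_i

with u_i ~ N(0, σ²) exchangeable and δ intrinsic CAR over the neighbour
graph: δ_i | δ_−i ~ N(mean of neighbours, 1/(τ m_i)). One published
formulation writes the linear predictor for log θ_i with an additional
log E_i term; read literally that would count E_i twice, so the standard
reading log μ_i = log E_i + log θ_i is implemented.

Priors (second arguments are variances): α ~ N(0, 100), β_j ~ N(0, 1),
σ ~ half-Normal(0, 1000) (a scale must be positive, so the Normal prior on
σ is truncated at zero), τ ~ Gamma(0.5, 0.0005) — the long-standing
GeoBUGS default for an ICAR precision, configurable. A
`winbugs_precision` switch reads the same numbers as precisions instead,
since WinBUGS-style notation is ambiguous on this point; the variance
reading is the default because a statement like "σ ~ Normal(0, 1000)" is
only coherent with the second argument as a variance.

### Sampler

A Metropolis-within-Gibbs scheme, written so every sweep is a handful of
vectorized operations:

- α and each β_j: scalar Gaussian random walks.
- u: all n sites proposed at once and accepted element-wise. Valid because
  the u_i are conditionally independent given everything else (iid prior,
  likelihood factorizes by area).
- δ: the graph is greedily coloured once; sites within a colour class
  share no edge, so their ICAR full conditionals are mutually independent
  and each class is proposed and accepted element-wise (4–5 classes for
  the Iran graph).
- translation moves: the pairs (β_j, u) and (α, u) trade off along
  directions that leave the linear predictor — hence the likelihood —
  unchanged (add ε to β_j, subtract ε·x_j from every u_i). The conditional
  distribution along such a flat direction is Gaussian and is Gibbs-sampled
  exactly each sweep. Without these moves the weakly identified β mixes an
  order of magnitude slower (effective sample sizes of ~10 rather than
  ~200 per 5,000 sweeps on 30 areas), and short-chain credible intervals
  for β are unreliable.
- σ: Gaussian random walk on log σ with the Jacobian term.
- τ: conjugate Gibbs draw from Gamma(a0 + (n−k)/2, b0 + ½ Σ_{i~j}(δ_i−δ_j)²),
  k = number of graph components.

The ICAR prior is improper along the constant direction; after each sweep
δ is recentred to Σδ = 0 and the subtracted mean is added to α
(centring-on-the-fly). With the diffuse N(0,100) intercept prior this
targets the sum-to-zero-constrained model to well within Monte-Carlo
accuracy, which is verified directly: on a 3-area instance with fixed
(σ, τ), 100,000 draws agree with dense 4-dimensional grid integration over
(α, u+δ) to better than 0.005 on every posterior mean (the grid prior for
η = u + δ is the proper convolution N(0, σ²I + L⁺/τ)).

Step sizes adapt toward 0.44 acceptance in windows of 50 sweeps during
burn-in only and are frozen afterwards, so the retained chain is a fixed
Markov kernel with detailed balance. One seeded generator is consumed in a
fixed order (α, β's, u block, δ colour classes, σ, τ), making runs
bit-reproducible; the default seed is 20080101. Default chain length is
50,000 sweeps with 2,000 burn-in and no thinning, mirroring common practice
for this model class; tests and the acceptance script use shorter chains
(1,500–20,000 sweeps depending on the check), which these low-dimensional
posteriors mix through easily — at roughly 0.2 ms per sweep on 30 areas, a
full-length default run takes seconds.

Degenerate inputs: a disconnected adjacency graph is refused (per-component
centring is not implemented); zero observed counts are handled throughout
(0·log 0 = 0); expected counts must be strictly positive. Acceptance rates
outside (0.05, 0.95) after adaptation produce a warning, not a failure.

### Summaries and diagnostics

`summarize_posterior` reports per-area posterior mean/median RR, equal-tailed
95% credible intervals and exceedance probabilities P(θ_i > 1 | data), and a
parameter table with exp(β) intervals; a covariate is flagged not
significant when its exp(β) interval spans 1. Diagnostics: Geweke z-scores
(first 10% vs last 50%, autocorrelation-adjusted via Geyer initial-positive-
sequence effective sample sizes) and Gelman–Rubin R̂ when extra chains are
supplied.

## Model comparison

DIC = Dbar + pD with pD = Dbar − Dhat. Dhat is evaluated at the posterior
mean of each area's log relative risk, not at posterior means of individual
parameters — the u/δ split is not identified area by area, but their sum
is, and this choice makes DIC invariant to it. Both the raw-deviance
(−2 log L, including the log O_i! terms) and saturated-deviance conventions
are computed and labelled, because published tables rarely state which
convention they used and the two differ by a data-dependent constant
(pD is identical under both). Rankings flag DIC differences below 5 as not
decisive. The plug-in GLM report uses pD = p (exact for a flat-prior point
fit).

## Synthetic data

`simulate_dataset` draws from exactly the generative model the sampler
assumes: u iid Normal, δ an exact sum-to-zero ICAR draw (Gaussian in the
Laplacian eigenbasis with the null direction removed — exact and cheap at
n ≤ a few hundred), covariates either iid Normal or spatially autocorrelated
(ICAR draws), and Poisson counts. Expected-count profiles: constant,
lognormal, or copied from the packaged male/female fixture columns (the
realistic, strongly heterogeneous case — E ranges over two orders of
magnitude). Defaults emulate the study conditions: the 30-province Iran
graph, fixture expected counts, moderate heterogeneity σ_u = 0.2 and
τ_δ = 5 (marginal sd of δ about 0.2 on this graph). The truth record is
serialized beside the dataset so recovery studies are self-describing.

What the generator does not emulate: registry misclassification and
patient-mobility errors (a known feature of these data, listed as a future
extension), covariate measurement error, and within-province heterogeneity.
Passing recovery tests therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not robustness to those
real-data defects.

## Validation performed by the test suite

- Published per-sex SIR summaries reproduced from the packaged counts at
  printed precision (means 1.92/1.85, sds 3.25/3.37, maxima 10.85/11.41,
  minima 0.16, totals 12,155/9,388/21,543, male share 56.42%).
- Standardization conservation over 200 random stratum tables.
- GLM against closed forms and grid-search likelihood maximization (1e-4).
- Sampler against grid integration on 3 areas (0.02 tolerance).
- Parameter recovery: ≥ 80/100 coverage of α and β1 at reduced chain
  lengths; ≤ 10% false exclusion of exp(β) = 1 under a null β.
- Shrinkage contract on the male fixture: every posterior-mean RR lies
  weakly between that area's SIR and the pooled ratio, with East
  Azerbaijan and Ardabil in the top-3 risks and Sistan in the bottom-3.
  Betweenness is asserted up to a band of 3 Monte-Carlo standard errors
  plus a tenth of the area's posterior sd: the convolution model smooths
  toward a mix of the local neighbourhood mean and the global mean, so an
  area whose neighbours all lie on one side of it (Semnan, SIR 0.89 amid
  uniformly lower-risk neighbours) can land a statistically negligible
  distance past its own SIR. Deviations small relative to posterior
  uncertainty count as reaching the endpoint, not as anti-shrinkage.
- Spatial model beats the non-spatial GLM on DIC in ≥ 90/100 spatially
  structured replicates.

## Known limitations

- The published adjusted RR extremes (11.14, 0.22) and the covariate
  coefficient table cannot be reproduced: the per-province UER/MHI values
  were never published. The machinery is in place; the numbers are not
  desk-reproducible.
- Incidence rates per 10^5 person-years require external census
  denominators not shipped here.
- Single spatial prior family (ICAR convolution); no BYM2/Leroux
  reparameterizations, no WAIC/LOO.
- Disconnected maps are rejected rather than handled per component.
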