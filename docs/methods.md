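# Methods

This note documents the statistical model, the synthetic-data generator, the
inference machinery and the numerical/design choices behind `geostunt`, at
the level of detail a user would need to judge what the package's passing
tests do and do not demonstrate.

## Model

Outcomes are grouped binomial per survey cluster: $y_i \sim
\mathrm{Bin}(n_i, p_i)$ with $\operatorname{logit} p_i = x_i^\top\beta +
u(s_i)$. The latent field $u$ is zero-mean Gaussian with Matérn covariance
of smoothness $\nu = 1$,

$$\operatorname{Cov}(u(s), u(s')) = \sigma^2 \,(\kappa d)\,K_1(\kappa d),
\qquad d = \lVert s - s' \rVert,$$

with $\kappa$ a decay per km and $\sigma^2$ the marginal variance. All
coordinates live in a local equirectangular plane in kilometres (converted
once from lon/lat on input), so a single Euclidean metric serves
simulation, meshing, and reporting; ranges are in km.

Two range conventions are exposed: the *practical range* solving
$\rho(d) = 0.1$ (the reporting default; $d \approx 3.21/\kappa$ for
$\nu = 1$, found by bracketed root-finding to 1e-8 relative tolerance) and
the common $\sqrt{8\nu}/\kappa$ ($\rho \approx 0.14$). Posterior range
draws are obtained by applying the practical-range map to each $\kappa$
draw, so the reported range median is *not* the deterministic image of the
reported $\kappa$ median.

### SPDE/GMRF representation

The field is approximated by a GMRF on a Delaunay mesh via the SPDE link
($\alpha = \nu + d/2 = 2$ in two dimensions). With P1 finite elements,
lumped (diagonal) mass matrix $C$ and stiffness matrix $G$,

$$Q = \tau^2\left(\kappa^4 C + 2\kappa^2 G + G C^{-1} G\right),
\qquad \tau^2 = \frac{1}{4\pi\kappa^2\sigma^2},$$

so that the interior marginal variance targets $\sigma^2$. Mass lumping
keeps $Q$ sparse and is standard practice; the equivalence tests bound its
cost. A sparse barycentric projector $A$ (three non-zeros per row, rows
summing to 1) links observation/prediction points to mesh vertices.

Mesh construction: data locations deduplicated within `cutoff_km` share a
vertex (conditioning); filler vertices on a regular interior lattice and a
coarser extension ring; midpoint refinement until no in-boundary edge
exceeds `max_edge_km`. The mesh extends `extension_km` beyond the study
boundary — set it to roughly twice the expected range — because the SPDE's
Neumann boundary inflates variance near the mesh edge; the variance and
correlation tests exclude that buffer. Measured on a 400 km domain with an
80 km range, the maximum absolute error of the GMRF-implied correlation
against the closed form falls 0.092 → 0.076 → 0.036 as `max_edge` shrinks
60 → 30 → 15 km, and interior marginal variances are within 15% of
$\sigma^2$ at the fine resolution. Coarser meshes trade accuracy for speed;
the replicate studies use `max_edge` 45–50 km on a 300 km domain, which is
adequate for recovery but would not pass the ±0.05 correlation check.

### Priors

* intercept: normal, precision 1e-6 (effectively flat but proper, so
  marginal-likelihood bookkeeping stays defined);
* coefficients: normal(0, precision 0.001);
* field precision $1/\sigma^2$: gamma(shape 1, rate 0.00005) — an
  inverse-gamma prior on the variance;
* decay $\kappa$: by default log-normal, centred at the $\kappa$ whose
  conventional range is one fifth of the data bounding-box diagonal, with
  sd 1 on the log scale.

The decay prior deserves a note. A gamma(1, 0.00005) prior placed literally
on $\kappa$ is near-uniform out to $\kappa = 2\times 10^4$/km. In this
model the likelihood is flat in $\kappa$ once the field has degenerated
(huge $\kappa$, tiny $\sigma^2$ — effectively no field), so that prior's
enormous volume in the degenerate region dominates a likelihood preference
of several nats for a genuine field, and the sampler drifts into it. The
log-normal default is the mesh-scale-anchored prior conventional for SPDE
models and is weak across two orders of magnitude of range; the literal
gamma prior remains available via `PriorSpec(decay_prior="gamma")` for
users who want it.

## Inference

### Blocked Gibbs with Pólya-Gamma augmentation

Conditional on PG variables $\omega_i \sim \mathrm{PG}(n_i, \psi_i)$ the
binomial logit likelihood is Gaussian in the linear predictor, so
$(\beta, u)$ has a joint Gaussian full conditional sampled exactly by
Cholesky. PG draws use the truncated infinite-gamma-convolution series (200
terms) with the truncated tail replaced by its exact mean
$\tfrac{b}{2c}\tanh\tfrac{c}{2}$ minus the truncated-series mean; the
engine-vs-oracle test (total variation < 0.05 against brute-force 2-D grid
integration; measured ≈ 0.008) bounds the residual truncation error at the
posterior level.

Hyperparameters $(\log\kappa, \log\sigma^2)$ move by random-walk
Metropolis on the *collapsed* conditional: given $\omega$, the Gaussian
latent block is integrated analytically, so the acceptance ratio uses
$\tfrac12\log|Q| - \tfrac12\log|M| + \tfrac12 b^\top M^{-1} b$ with
$M = Z^\top\Omega Z + P(\theta)$. Conditioning on the sampled field instead
(the centred parameterization) mixes an order of magnitude worse here. The
step size adapts toward 30% acceptance during warm-up (Robbins-Monro,
frozen afterwards). Defaults are 4 chains × 2,500 draws after 1,000
warm-up; split-$\hat R$ and bulk ESS are computed for every coefficient and
hyperparameter, and a fit is flagged non-converged when any $\hat R >
1.05$.

### Laplace route

For replicate studies a fast approximation mirrors the
latent-Gaussian-model strategy the field typically uses: for each
$(\log\kappa, \log\sigma^2)$ the latent posterior is approximated by a
Gaussian at its Newton mode; the hyperparameter posterior is the Laplace
marginal (plus prior), maximised by Nelder-Mead and given a Gaussian
approximation from a finite-difference Hessian; posterior draws mix latent
conditionals over a 5×5 lattice of hyperparameter values (nearest-cell
assignment of continuous hyperparameter draws). On the desk-scale datasets
the two routes agree to ~0.02 in posterior medians of $\beta$ and well
within CrI widths on the hyperparameters (`test_gibbs_and_laplace_agree_on_spatial_fit`).

### Information criteria, interaction test, selection

WAIC $= -2(\mathrm{lppd} - p_\mathrm{WAIC})$ with $p_\mathrm{WAIC}$ the sum
of posterior variances of pointwise log-likelihoods; DIC $= \bar D + p_D$,
$p_D = \bar D - D(\text{posterior mean of }\psi)$. Both include the
binomial combinatorial constant so values are comparable across models on
the same data only.

Effect modification by age group (0–23 vs 24–59 months) is tested by a
Bayesian-Wald statistic: the joint null that all interaction coefficients
of a covariate vanish, evaluated with the posterior mean and covariance
from the non-spatial Laplace fit against a $\chi^2$ reference. Measured
operating characteristics at 5,000 children per group: type-I ≈ 0.05
(slightly conservative through the coefficient prior), power ≈ 1.0 for OR
1.2 vs 1.7.

Variable selection is greedy forward addition on non-spatial fits,
accepting a term when it improves the criterion by more than 2.0; ties
break by candidate order, and the full trace is returned.

## Survey estimation

The design-based prevalence is the ratio estimator
$\sum w_i y_i / \sum w_i$ with the with-replacement first-stage Taylor
linearization: scores $w_i(y_i - \hat p)/\sum w$ are totalled within
clusters and their between-cluster variance accumulated within strata with
the $n_h/(n_h-1)$ factor. Confidence intervals are normal-approximation,
truncated to [0, 1]; no logit transform. A stratum with a single cluster is
an error unless `single_cluster="center"` centres it at the grand mean.
Age groups are a generator-produced column; no date arithmetic.

## Synthetic-data generator

The generator emulates the design features that matter for the estimators:

* square study region partitioned into Voronoi zones (admin-2 analogue),
  one urban centre per zone;
* clusters: urban ones placed near centres selected
  probability-proportional-to-size (gamma-distributed size measure), rural
  ones uniform; stratum = zone × urban/rural; design weight = inverse
  selection probability (urban), 1 (rural);
* 28 households per cluster, children per household Poisson with rate
  defaulting to $9089/622/28$ so a cluster yields ≈ 14.6 measured children
  (the child-per-cluster distribution is an assumption — the design source
  does not state one);
* categorical covariates drawn at cluster or child level from stated
  frequencies (first level is the reference; child-level ones aggregate to
  per-cluster level proportions on the records);
* outcomes through the HAZ mechanism: per child, HAZ ~ Normal($\mu$,
  `haz_sd`) with $\mu = -2 - \mathrm{sd}\cdot\Phi^{-1}(p)$ so that
  $P(\mathrm{HAZ} < -2.0) = p$ under the logistic model; stunting is the
  strict inequality HAZ < −2.0. HAZ is generated directly on the z-score
  scale — no growth-standard lookup — because the analysis consumes only
  the dichotomised outcome;
* geo-masking: direction uniform, distance uniform on [0, max] with max
  2 km urban / 10 km rural, rejection-resampled until the displaced point
  stays inside the cluster's zone (preserving the distance distribution's
  support, unlike clamping);
* covariate rasters: exact Gaussian-field draws (dense Cholesky) on grids
  up to 3,000 cells, coarse-lattice simulation plus interpolation beyond.

Default scenario sizes: 622 clusters ("national scale") for demonstrations and
150 clusters ("desk scale") for the replicate studies.

What the generator does *not* emulate: household listing, response-rate
mechanics, questionnaire content, measurement error in height/age, real
admin geographies, non-stationarity or anisotropy of the field, and
spatially correlated covariate-outcome confounding. Passing recovery tests
therefore demonstrate internal statistical correctness of the pipeline
under a correctly specified model — not robustness to the misspecification
real surveys carry.

## Prediction, zonal aggregation, validation

Prediction surfaces evaluate $\operatorname{expit}(x^\top\beta + A u)$
draw-wise at pixel centres (5 km default lattice clipped to the boundary),
thinned to ≤ 500 draws for memory; summaries are pixelwise percentiles.
Categorical raster covariates pass through the climate band classifier
before one-hot coding. Zonal estimates aggregate pixels *within each draw*
(optionally population-weighted) and then take percentiles
(aggregate-then-summarize); the alternative order produces incoherent —
generally far wider — intervals, and a regression test pins the
implemented order on a two-pixel anticorrelated example.

Hold-out validation splits clusters 75/25 (train size round-half-up, so
622 → 467/155), fits on the training clusters and scores the test
clusters: RMSE and Pearson r compare observed proportions with
posterior-median prevalences (RMSE in percentage points); 95% coverage is
measured against the *posterior predictive* interval of the observed
proportion — a binomial draw of each test cluster's size per posterior
prevalence draw — because the prevalence CrI alone omits the binomial noise
of a ~30-child cluster and undercovers (~0.67 measured) even under a
correctly specified model. Constant predictions make r undefined; it is
reported as missing, not zero.

Moran's I uses row-standardized k-nearest weights (k = 5) by default —
inverse-distance and explicit matrices are accepted — with a label-
permutation p-value that counts the observed statistic among the
permutations. The implementation is cross-checked against an independent R
implementation on a fixture.

## Band classifications

Climate band edges follow the printed reporting labels, closed on the left:
daytime land-surface temperature <30 / [30, 35) / ≥35 °C; annual rainfall
<141 / [141, 1200) / ≥1200 mm (the printed labels leave 141–142 and
1199–1200 gaps; the half-open cover closes them); wet days per year by
terciles of the sample. Aridity labels Wet/Semi-arid/Arid have no printed
numeric edges; the UNEP aridity-index convention (arid < 0.2, semi-arid
[0.2, 0.5), wet ≥ 0.5) is used.

## Study designs and known limitations

The replicate studies (`geostunt.studies`) use sizes chosen for a
single-CPU battery: 50 replicates of 150 clusters for calibration/recovery,
50 non-spatial and 20 spatial replicates for model selection, 200/50
replicates for interaction error rates, one 300-cluster run for hold-out
validation, 10,000 displacements for the geo-masking bounds.

Known limitations:

* Fixed-truth frequentist coverage of the 95% CrIs pools at ≈ 0.92–0.94
  rather than 0.95 — expected behaviour of Bayesian intervals evaluated at
  a fixed truth with near-flat priors, not an approximation artefact (the
  exact sampler gives the same interval widths).
* With mesh vertices at cluster locations, a short-range, high-variance
  field can absorb spatially incoherent per-cluster overdispersion; after
  destroying spatial structure by permuting locations it is therefore the
  posterior *range* that collapses, not the field variance. Diagnostics
  should read the two jointly.
* The Laplace route's hyperparameter posterior is a Gaussian on the log
  scale; heavy tails (small data) are clipped at the ±2-cell lattice.
* Marginal likelihood is reported only from the Laplace route and is
  approximate; MCMC marginal likelihood is out of scope.
* Grouped binomial fits assume cluster-constant covariates; child-level
  covariates enter as cluster-level proportions (a linear-in-logit
  approximation). Child-level Bernoulli fits are the $n_i = 1$ special
  case of the same code path.
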