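# Methods

`roadcline` implements the statistical machinery for asking whether road
mortality acts as a selective agent on a discrete color polymorphism along
an urban–rural gradient, using eastern gray squirrels (*Sciurus
carolinensis*; gray vs. melanic morphs) as the model system.  The package
couples three largely independent analyses — a living-vs-road-killed cline
contrast, causally adjusted mortality-risk regressions, and range-wide
contingency statistics — and ships a synthetic-data generator with known
truth so every stage is testable without field data.

## 1. The living-squirrel cline model

Living-squirrel evidence comes from repeated 3-minute point counts and
daily camera-trap detection histories at fixed sites along the gradient.
For site *i*, survey occasion *j*, and morph *k*:

    N_total_i ~ Poisson(λ_i)             log λ_i  = β0_N + β1_N · z_i
    N_i,mel   ~ Binomial(N_total_i, p_mel_i)    logit p_mel_i = β0_M + β1_M · z_i
    C_ijk ~ Binomial(N_ik, p_ijk)                      (point counts)
    D_ijk ~ Bernoulli(p*_ijk),  p*_ijk = 1 − (1 − p_ijk)^N_ik   (camera days)
    logit p_ijk = a0_k + a1_k · t_ij + a2_k · t_ij²

where `z` is the standardized distance to the city center, `t` the
standardized mean daily temperature, `p` the per-individual detection
probability and `p*` the probability of photographing at least one of
`N_ik` individuals on a given day.  Distance and temperature are
standardized (mean 0, SD 1, n−1 denominator) before fitting; the constants
are stored with each fit so curves can be evaluated in kilometers.

**Marginalization.**  Rather than sampling the latent abundances, the
likelihood marginalizes them analytically via the Poisson thinning
identity: `N_mel ~ Poisson(λ·p_mel)` and `N_gray ~ Poisson(λ·(1−p_mel))`
are independent, so the site likelihood factorizes over morphs and each
factor is a single sum over its latent count.  The sum is truncated at the
smallest `N` whose Poisson upper tail falls below 1e−12, never below 50
(and never below the largest observed count); increasing the truncation
point changes the log-likelihood by less than 1e−10.  The equivalence of
the thinned and joint (Poisson total → Binomial split) formulations, and
agreement with brute-force latent enumeration, are tested properties, not
assumptions.

Two evaluation paths exist: a transparent per-site reference
(`site_marginal_loglik`, `living_model_loglik`) and a vectorized evaluator
(`LivingLikelihood`) used inside MCMC.  They agree to ~1e−9; the sampler's
instance runs the camera-history kernel (the dominant cost) in single
precision, introducing absolute likelihood error ~1e−4 — orders of
magnitude below Monte Carlo error.

## 2. The DOR cline and the selection contrast

Each road-killed (DOR) squirrel contributes one Bernoulli observation:
`M_i ~ Bernoulli(p_i)`, `logit p_i = α + β·z_i`.  The DOR model is fit
separately from the living model (independent data, no shared parameters);
its distances are standardized with its own sample constants, since the
two datasets need not share support.

The selection signal is the pointwise posterior difference

    Δ(d) = p_mel,living(d) − p_mel,DOR(d),   d ∈ [0.93, 11.3] km,

computed draw-by-draw (both curves are deterministic in their cline
parameters) and summarized by the mean and 2.5/97.5 percentiles at each of
100 grid points.  Because the two posteriors are independent, any pairing
of draws is valid; draws are pooled across chains, truncated to the
shorter posterior, and paired by index for reproducibility.  A positive
Δ with an interval excluding zero means melanics are underrepresented
among road-kill relative to the living population at that distance —
selection against the gray morph's crypsis advantage on pavement.

## 3. Posterior sampling

Sampling is a self-contained adaptive random-walk Metropolis:

- **Proposal**: multivariate normal, `scale² · Σ`.  For the living model
  `Σ` is initialized from a Laplace approximation (posterior mode by
  bounded L-BFGS started from moment estimates; covariance from a
  finite-difference Hessian, eigenvalue-clipped at 1e−4) and then refined
  from the chain's own history during adaptation; the scalar is tuned by
  Robbins–Monro toward 30% acceptance (within the 20–45% band).  Both are
  frozen when adaptation ends, preserving detailed balance for retained
  draws.
- **Initialization**: chains start from the Laplace approximation
  (overdispersed draws from it), from jittered moment estimates, or from
  prior draws (`init="laplace"|"moment"|"prior"`).  Prior-draw starts cap
  normal-prior SDs at 2.5 so nearly flat priors do not start chains in
  regions of absurd abundance.
- **Priors** (defaults, configurable): Normal(0, 10) on all regression
  coefficients; Uniform(0, 100) on mean site abundance `exp(β0_N)`;
  Uniform(0, 1) on mean proportion melanic `expit(β0_M)` and on each
  morph's mean detection probability `expit(a0_k)` — uniforms are imposed
  on the interpretable scale with the exact Jacobian on the sampled scale.
- **Protocol**: `MCMCConfig.reference_protocol()` mirrors the full field
  protocol (3 chains, 20,000 adaptation + 12,000 iterations, 1,000
  burn-in, thin 10 → 1,100 retained draws per chain, 3,300 total; the
  retained count follows directly from ceil((12,000−1,000)/10)).  Tests
  and the acceptance script use reduced protocols (3 chains, ~600
  adaptation + 2,400–4,200 iterations) sized for a single CPU; the
  reference protocol remains one configuration flag away.
- **Diagnostics**: split-chain Gelman–Rubin R-hat (each chain halved, so
  within-chain drift registers), convergence threshold 1.1.  Runs that
  fail the threshold are flagged in reports and test output, never
  silently accepted.  Posterior summaries are pooled means with 2.5/97.5
  percentile intervals, linear interpolation between order statistics.

The N-mixture posterior has a curved abundance–detection ridge (the data
constrain products like λ·p more tightly than either factor), which is why
plain identity-proposal RWM mixes poorly here and the Laplace
preconditioning matters.  Under the reduced protocols a minority of
replicates still land above R-hat 1.1; they are reported as such.
Gradient-based samplers and parallel tempering are out of scope.

## 4. Road-mortality risk with causal adjustment

Mortality risk per morph is analyzed as a DOR-vs-reference logistic
regression at the location level.  Exposures of interest: speed limit,
traffic volume (AADT), presence of above-ground crossing structures, and
habitat split (the difference in forest cover across the road).  To
isolate direct effects, each regression conditions on a backdoor
adjustment set read off a causal DAG linking distance to city center,
human population density, building density, forest cover, fragmentation,
morph abundance, the four exposures, and mortality.  The DAG ships as an
editable edge list (`src/roadcline/data/default_dag.csv`); it is a
reconstruction of the hypothesized structure for this study system, and
users can substitute their own.  With it, the exposures require exactly
{population density}, {population density}, {population density, forest
cover}, and {fragmentation} as observed adjustment sets — population
density, forest cover, and fragmentation in union.

- `d_separated` delegates to networkx's d-separation; `backdoor_sets`
  enumerates subsets of the exposure's non-descendants and keeps minimal
  sets that block the proper backdoor graph, sorted by size then
  lexicographically.  Both are verified against brute-force
  path-enumeration/subset-enumeration oracles on random DAGs.
- When several minimal sets exist, the smallest (lexicographic tie-break)
  fully observed one is used; all minimal sets are reported.  Unobserved
  nodes (building density, morph abundance) simply rule out sets that
  contain them.
- Population density, fragmentation and traffic are log-transformed before
  entering the regression (log-odds linearity).
- The fit is Firth's mean-bias-reduced logistic regression: Jeffreys
  penalty `½ log det I(β)`, modified-score iterations with hat-value
  adjusted responses, step-halving so the penalized log-likelihood is
  non-decreasing, convergence when the largest score component is below
  1e−8 (at most 100 iterations; non-convergence is flagged, not raised).
  Firth keeps estimates finite under complete separation — relevant at
  n = 282 with binary covariates.  Inference is Wald (estimate/SE);
  penalized-likelihood-ratio intervals are out of scope.

## 5. Range-wide contingency statistics

The citizen-science analysis reduces crowdsourced photo classifications to
a 2×2 morph × dead/alive table (the package also provides the upstream
consensus filter: ≥10 classifiers and ≥80% agreement per field).
Association is tested with Pearson's χ² with Yates' continuity correction,
with the correction clamped at `min(0.5, min|O−E|)` so an exactly
independent table scores 0 (the R convention; scipy's unclamped variant
differs only when |O−E| < 0.5).  Effect size is Cramér's V from the
uncorrected statistic — for the shipped table both variants round
identically at two decimals.  Per-morph DOR proportions get Agresti–Coull
intervals (adjusted count ñ = n + z², truncated to [0, 1]).

## 6. The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions:

- 41 sites, distances uniform on 0.93–11.3 km (site spacing is otherwise
  unknown; uniform covers the curve domain evenly), 24 randomly chosen
  camera sites (the split between camera and count-only sites is a free
  design choice).
- 5 point-count surveys per site and 263 camera days per camera site — the
  printed design medians — with `randomize=True` drawing effort over the
  printed ranges (2–7 surveys; 46–379 days with a Beta(2.2, 1.3) profile
  whose median sits near 263).
- Generating coefficients default to the published posterior means
  (abundance 2.58/−0.62; melanism −0.85/−0.80; melanic detection
  −2.16/−0.058/−0.34; gray detection −1.53/−0.019/−0.39; DOR −1.36/−0.22),
  so a default simulation is a replicate of the fitted system.
- Temperatures follow an annual sinusoid (coldest late January, amplitude
  13 °C) plus N(0, 3²) weather noise, standardized over the pooled
  point-count and camera occasions; only standardized temperature enters
  any model.
- 141 DOR records, distances uniform over the range.
- The risk generator draws covariates parent-first along the DAG with
  linear-Gaussian links on transformed scales (log for population density,
  building density, traffic, fragmentation; logit for forest cover and
  habitat split; Bernoulli for crossings), then the outcome from a
  logistic model whose coefficients act on the analysis scales.  Gray
  defaults plant a log-traffic effect of 0.32 and a crossings effect;
  melanic defaults plant a habitat-split effect of 1.89 (the magnitudes
  reported for the field system).  The matched design samples until 141
  cases and 141 references accumulate; `balanced=False` gives population
  sampling at the model's own prevalence.

What the generator does **not** emulate: spatial autocorrelation among
sites, road-network geometry and GIS-derived covariate error, kriging of
missing traffic counts, observer heterogeneity, carcass persistence and
detectability (treated as resolved upstream), multi-year dynamics, and the
citizen-science observation process itself (only its output tallies).
Passing tests therefore demonstrate correctness of the inference machinery
under the model's own assumptions — not robustness of the field study to
violations of them.

## 7. Numerical choices and problem sizes

- Detection probabilities are clipped to [1e−300, 1−1e−12] inside
  likelihoods for log-safety; abundance evaluations reject log-mean > 30
  outright.
- Quantiles everywhere: linear interpolation between order statistics.
- Standardization uses the n−1 SD; `standardize` returns its constants for
  exact back-transformation.
- Seeds: every public generator and fit takes explicit seeds; pipeline
  stages and chains derive theirs from one global seed via
  `numpy.random.SeedSequence`, so a manifest reproduces a run bit-for-bit.
- Test/acceptance problem sizes (chosen as the package's own single-CPU
  budget): 20 recovery replicates at full study scale with 3-chain reduced
  protocols; risk calibration with 400 matched replicates of n = 282;
  brute-force likelihood oracles on toy sites with latent sums to 250.

## 8. Known limitations

- The reduced MCMC protocols trade R-hat headroom for runtime; analyses
  that matter should use `MCMCConfig.reference_protocol()` and check the
  R-hat report.
- The default DAG is a reconstruction from the described structure of the
  study system; the original supplementary figure may contain additional
  landscape edges.  Conclusions about adjustment sets are conditional on
  the shipped edge list.
- Wald p-values from Firth fits can be conservative near separation;
  profile-penalized-likelihood intervals would be preferable there and are
  not implemented.
- The living model assumes closure (constant N during the season) and
  independence across sites and days, as in the standard N-mixture
  framework.
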