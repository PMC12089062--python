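# roadcline

Does road mortality act as an agent of natural selection on a color
polymorphism along an urban–rural gradient?  `roadcline` implements the
statistical machinery for answering that question in the eastern gray
squirrel (*Sciurus carolinensis*), whose melanic morph is more frequent
near city centers and more visible to drivers on pavement than the cryptic
gray morph.  The package is aimed at quantitative ecologists who want to
contrast morph clines between living and road-killed animals, estimate
causally adjusted road-mortality risk, or reanalyze large
citizen-science classification tallies — and at anyone who needs the
underlying components (marginalized N-mixture likelihoods, a
self-contained adaptive MCMC, backdoor adjustment-set identification,
Firth logistic regression) as tested building blocks.

## The models

**Living-squirrel cline** — an integrated hierarchical model of point
counts `C_ijk` and daily camera-trap detections `D_ijk` at sites `i` along
the gradient, for morph `k` ∈ {melanic, gray}:

```
N_total_i ~ Poisson(λ_i)                log λ_i       = β0_N + β1_N · z_i
N_i,mel   ~ Binomial(N_total_i, p_mel,i)  logit p_mel,i = β0_M + β1_M · z_i
C_ijk ~ Binomial(N_ik, p_ijk)
D_ijk ~ Bernoulli(1 − (1 − p_ijk)^N_ik)
logit p_ijk = a0_k + a1_k·t_ij + a2_k·t_ij²
```

with `z` the standardized distance to the city center and `t` the
standardized daily temperature.  The latent abundances are marginalized
analytically (Poisson thinning), so the likelihood is deterministic and
exactly testable against brute-force enumeration.

**DOR cline** — each dead-on-road squirrel is a Bernoulli draw,
`logit p_i = α + β·z_i`.  The selection signal is the posterior difference
`Δ(d) = p_mel,living(d) − p_mel,DOR(d)` along the gradient: a positive Δ
with a 95% credible interval excluding zero means melanics are
underrepresented among road-kill at that distance.

**Mortality risk** — DOR-vs-reference Firth logistic regressions of each
road/landscape exposure (speed, traffic, crossing structures, habitat
split), each adjusted for the minimal backdoor set identified from a
causal DAG of the urban landscape.

**Range-wide tallies** — Yates-corrected χ², Cramér's V, and
Agresti–Coull intervals on the 2×2 morph × dead/alive table from
crowdsourced photo classifications.

## Worked example

Simulate a field season at the study design's scale (41 sites, 24 with
cameras, 141 DOR records; generating coefficients at the published
posterior means), fit both clines, and contrast them:

```python
import roadcline as rc

truth = rc.TruthParams()                     # the study conditions
data, dor, _ = rc.simulate_study(truth, seed=20_250_925)

post_living = rc.fit_living_model(data, rc.MCMCConfig(
    n_chains=3, n_adapt=600, n_iter=2700, n_burnin=500, thin=3, seed=321))
post_dor = rc.fit_dor_model(dor, rc.MCMCConfig(
    n_chains=3, n_adapt=800, n_iter=4200, n_burnin=600, thin=3, seed=322))

living, dead, diff = rc.cline_difference_curves(post_living, post_dor)
print(living.mean[0], dead.mean[0], diff.mean[0], diff.lower95[0])
```

Running the equivalent analysis scripts prints:

```
$ python analysis/02_fit_clines.py
posterior means (95% CrI) vs generating truth:
  beta0_N  +2.61 (+2.29, +3.02)   truth +2.58   rhat 1.026
  beta1_N  -0.56 (-0.70, -0.44)   truth -0.62   rhat 1.014
  beta0_M  -0.94 (-1.57, -0.36)   truth -0.85   rhat 1.062
  beta1_M  -0.74 (-0.96, -0.54)   truth -0.80   rhat 1.008
  alpha_D  -1.44 (-1.88, -1.04)   truth -1.36   rhat 1.005
  beta_D   -0.27 (-0.69, +0.14)   truth -0.22   rhat 1.000
max R-hat 1.062 (converged)

$ python analysis/03_contrast_clines.py
proportion melanic at 0.93 km: living 0.601, DOR 0.294
difference at the urban end: +0.307 (95% CrI +0.069 to +0.516)
interval excludes 0 from 0.93 km out to 5.54 km
```

Read: every 95% credible interval brackets its generating value; the
abundance and melanism clines both decline away from the city
(`beta1_N`, `beta1_M` < 0 with intervals excluding zero) while the DOR
cline is flat (`beta_D` interval spans zero).  The contrast makes the
selection signal explicit — melanic squirrels make up ~60% of the living
population at the city center but only ~29% of road-kill, a ~30-point
underrepresentation whose credible interval excludes zero out to ~5.5 km.

The same season's risk and citizen-science stages:

```
$ python analysis/04_risk_effects.py
gray morph (n = 282, matched design):
  speed         beta -0.03 +/- 0.02 (p = 0.124)  adjusted for pop_density
  traffic       beta +0.55 +/- 0.18 (p = 0.002) *  adjusted for pop_density
  crossings     beta +0.69 +/- 0.26 (p = 0.007) *  adjusted for forest_cover, pop_density
  habitat_split beta -0.34 +/- 0.86 (p = 0.694)  adjusted for fragmentation
melanic morph (n = 282, matched design):
  ...
  habitat_split beta +1.73 +/- 0.87 (p = 0.048) *  adjusted for fragmentation

$ python analysis/05_citizen_stats.py
N = 108,730 squirrel photographs
melanic DOR: observed 174, expected 205.1 (underrepresented)
gray DOR:    observed 1581, expected 1549.9 (overrepresented)
chi2(1, Yates) = 5.24, p = 0.022, Cramer's V = 0.01
```

## Layout

- `src/roadcline/` — the library: `synthetic` (generators with known
  truth), `likelihood`/`curves` (cline models and contrasts),
  `mcmc`/`fit` (sampler, priors, diagnostics), `dag`/`firth`/`risk`
  (causal adjustment and penalized regression), `tables` (contingency
  statistics), `io`/`pipeline`/`cli` (files, orchestration, shell
  interface).
- `analysis/01…05_*.py` — numbered narrative drivers writing under
  `results/`.
- `docs/methods.md` — model assumptions, priors, numerical choices, and
  what the synthetic generator does and does not emulate.
- `roadcline run-all --outdir results/run --seed 1` runs the whole
  simulate → fit → contrast → risk → tables workflow from the shell; see
  `roadcline --help` for per-stage subcommands and CSV schemas
  (documented in `src/roadcline/io.py`).

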