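# dcrange

**Demography–climate relationships from abundance time series, by Bayesian
calibration of a spatially explicit individual-based model.**

Correlative species-distribution models describe *where* a species is;
they say little about *why* its abundance changes. `dcrange` targets the
mechanism: it links each demographic rate of a stage-structured population
model directly to seasonal climate, fits all process parameters jointly to
ordinary survey counts, and then asks the fitted model counterfactual
questions — how would the population have fared under a stationary climate?

It is aimed at quantitative ecologists with site×year count data (breeding
bird atlases and monitoring schemes are the archetype) who want
process-based range-dynamics inference without hand-measured demographic
rates.

## The model in brief

A female-only, two-stage (juvenile/adult) population lives on a grid of 1-km
cells with habitat suitability `h ∈ {0..100}`. Each year: reproduction →
natal dispersal → survival/maturation. Three demography–climate
relationships (DCRs) drive the rates from standardized seasonal predictors:

    ρ_max = exp(β₀ + β₁ T_br + β₂ T_br² + β₃ P_br + β₄ P_br²)        fecundity
    s_j   = logit⁻¹(γ₀ + γ₁ T_at + γ₂ T_at² + γ₃ P_wn + γ₄ P_wn²)    juvenile survival
    s_a   = logit⁻¹(δ₀ + δ₁ T_wn + δ₂ P_wn + δ₃ P_wn²)               adult survival

Fecundity is density dependent, `ρ(n) = ρ_max · exp(−n · b·100/h)`; dispersal
follows an exponential kernel (mean `d̄`) with emigration probability `p_e`
and neighbour-fallback settlement. The 18 parameters (14 DCR coefficients,
`b`, `p_e`, `d̄`, and a negative-binomial observation dispersion `σ`) are
estimated by DEzs MCMC against block-aggregated, replicate-averaged
simulated abundances. Fitted models are scored by RMSE, Harrell's c-index,
spatial AUC and a temporal c-index, and summarized by the low-density growth
rate `r = s_a/2 + √(s_a²/4 + s_j ρ)` — the dominant eigenvalue of the
two-stage transition matrix. See `docs/methods.md` for the full account.

Everything runs on synthetic data generated by `dcrange.synthetic` — no
external rasters or survey archives are required.

## Worked example

```python
import numpy as np
from dcrange import synthetic, calibration as cal, evaluation as ev, ibm

# a known-truth landscape: 15x15 km, 8 years, 25 survey sites
scen = synthetic.SyntheticScenario(nrows=15, ncols=15, first_year=2000,
                                   last_year=2007, n_sites=25,
                                   spinup_years=10, seed=42)
bundle = synthetic.generate(scen)

# calibrate (desk scale: 2 chains x 4000 evaluations, 3 replicates)
model = cal.PosteriorModel(priors=cal.default_priors(), survey=bundle.survey,
                           climate=bundle.climate, habitat=bundle.habitat,
                           initial=bundle.truth.initial, n_reps=3, block_size=8)
run = cal.dezs_sample(model, model.priors,
                      transform=cal.ParamTransform.for_model(),
                      n_chains=2, iterations=4000, seed=1)
print("max PSRF:", round(cal.gelman_rubin(run)["max_psrf"], 3))

# posterior-predictive fit
draws = cal.draws_as_parameter_vectors(cal.posterior_draws(run, n=5, seed=2))
sim = np.mean([ibm.simulate(pv, bundle.climate, bundle.habitat,
                            bundle.truth.initial, n_reps=3, seed=3 + i)
               for i, pv in enumerate(draws)], axis=0).mean(axis=1)[:, None]
pred, obs = ev.site_predictions(sim, bundle.survey, bundle.climate.years)
print("RMSE:", round(ev.rmse(pred, obs), 2),
      " c-index:", round(ev.c_index(pred, obs), 3))
```

Output:

```
max PSRF: 1.727
RMSE: 1.76  c-index: 0.848
```

The PSRF well above 1.1 says these two short desk-scale chains have not
converged (expected at 4000 evaluations — the full-scale studies use
3 × 20 000); the RMSE of 1.76 breeding pairs and c-index of 0.85 say that,
even so, the posterior predictions already rank site-year counts correctly
for about five of six discordant pairs.

The same pipeline is scriptable from the shell via the `dcrange` CLI
(`synth`, `calibrate`, `report` verbs driven by a YAML config; every run
freezes its config and seeds so artifacts regenerate bit-identically).

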