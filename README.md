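# survsync

Interpopulation differences and temporal synchrony in adult survival for
colonially breeding birds, estimated from annual mark-recapture data.

The package implements the full analysis chain for a two-colony
comparison: a hierarchical state-space Cormack-Jolly-Seber (CJS) model
with a synchronous year effect shared between colonies, colony-specific
asynchronous deviations and trap-dependent recapture; an intra-class
correlation (ICC) measure of survival synchrony; a variance
decomposition quantifying how much synchronous and asynchronous
variation a summer wind-speed covariate absorbs; a one-breakpoint
piecewise regression of survival on wind; and stochastic Leslie-matrix
projections translating survival differences into population-level
consequences.  Because the ringing data such analyses use are typically
access-restricted, a first-class synthetic-data generator reproduces
the whole generative model, so every stage is testable against ground
truth.

## Model

For colony *c* and year *t* (logit link throughout):

    logit φ_{c,t} = logit(α_c) + β_c W_t + γ_t + ε_{φ,c,t}
    logit p_{c,t} = logit(δ_{c,k}) + ε_{p,c,t}

with `γ_t ~ N(0, σ_γ²)` shared across colonies, `ε_{φ,c,t} ~ N(0, σ_{φ,ε}²)`
colony-specific, trap-dependent recapture intercepts `δ_{c,1}` /
`δ_{c,2}` (captured / not captured the year before), and `W_t` the
centred mean summer wind speed.  Synchrony is summarised per posterior
draw by

    ICC = σ_γ² / (σ_γ² + σ_{φ,ε}²),

and the wind-attributable share of each variance component by
`ω = 1 − σ²_residual / σ²_total` across paired fits without/with the
covariate.  The latent alive/dead state is marginalised analytically
and the likelihood reduced to sufficient statistics, so posterior
sampling (adaptive Metropolis-within-Gibbs, numba-compiled) takes
seconds rather than hours at realistic sizes.  See `docs/methods.md`
for the full model description and numerical choices.

## Worked example

```python
import numpy as np
from survsync import (SimulationConfig, simulate_dataset, filter_transients,
                      MCMCSettings, fit, posterior_icc)
from survsync.wind import WindCovariate

cfg = SimulationConfig(n_occasions=40, entry_totals=(1500, 900), seed=1)
data, truth = simulate_dataset(cfg)
data, report = filter_transients(data)
wind = WindCovariate(data.occasions[:-1], truth.wind_raw,
                     truth.wind_raw - truth.wind_raw.mean(), ("sim",), (5, 6, 7, 8))

res = fit(data, wind, MCMCSettings(chains=3, iterations=8000,
                                   burnin=2500, thin=5, seed=2))
icc = posterior_icc(res)
alpha = res.summary("alpha")
print(f"removed never-reseen: "
      f"{[round(r['fraction_removed'], 2) for r in report['colonies'].values()]}")
print(f"alpha medians: {np.round(alpha['median'], 3)} (truth {cfg.alpha})")
print(f"ICC median {icc['median']:.2f} (95% CrI {icc['lo']:.2f}-{icc['hi']:.2f})")
```

prints

    removed never-reseen: [0.53, 0.29]
    alpha medians: [0.984 0.957] (truth (0.96, 0.94))
    ICC median 0.79 (95% CrI 0.29-0.95)

Roughly half of the large colony's marked birds are never re-detected
and are filtered out, emulating the removal rates such monitoring
schemes report.  The survival intercepts come back near (slightly
above) their generating values — conditioning on re-detection removes
some true mortality, a small bias inherent to the transient filter —
and most between-year survival variance is inferred to be shared
between the colonies, as the generator's high-synchrony defaults
(σ_γ = 1.0 vs σ_{φ,ε} = 0.4) dictate.

## Analysis drivers

The numbered scripts under `analysis/` run the full study on synthetic
data at desk scale and narrate what they find; each writes small tables
to `results/` (bulky per-individual files and posterior dumps go to
`scratch/`, regenerable from fixed seeds):

1. `01_simulate_study.py` — generate the two-colony study and wind table,
   apply the transient filter.
2. `02_fit_cjs.py` — fit the CJS model without and with the wind
   covariate; parameter summaries, survival medians, diagnostics.
3. `03_synchrony_decomposition.py` — per-draw ICC, ω decomposition,
   wind-slope summaries.
4. `04_breakpoint.py` — piecewise regression of survival medians on raw
   wind speed.
5. `05_project_populations.py` — stochastic Leslie projections and the
   between-colony counterfactual ratio.

`python -m survsync all --seed 0 --outdir results/pipeline`
runs the same stages from one config with a reproducibility manifest.

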