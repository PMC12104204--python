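# secr1d

One-dimensional Bayesian spatially explicit capture-recapture (SECR) for
individual space use and stressor exposure.

`secr1d` is aimed at studies of individually identifiable coastal wildlife —
photo-identified whales being the motivating case — where repeat sightings
accumulate along an essentially linear (latitudinal) strip of habitat, and
where the management question is not only *where the population is* but
*which individuals overlap which human activities, and how much*.

## The model

The study area is tiled into latitude bins (0.01°, ≈1.1 km, by default).
Annual encounter histories `S[i,l,t]` — how often individual `i` was sighted
in bin `l` in year `t` — are modelled as

    S[i,l,t] ~ Poisson(λ[i,l,t])

    λ[i,l,t] = 0                                         if effort e[l,t] = 0
             = γ[i,l,t] · exp(−d²[i,l,t] / 2σ²[i,t])     otherwise

    γ[i,l,t] = A[i,t] · exp(R[i,t] + β_e · ẽ[l,t])

where the expected sighting rate decays half-normally with the distance `d`
from the bin centroid to the individual's latent annual activity center
`C[i,t]` (uniform prior over the study extent), `σ²[i,t]` is the activity
range with hierarchy `log σ² = μ + M[i,t]`, `M ~ N(0, ω²)`, `R[i,t] ~ N(0,1)`
is an individual-year residency intercept, `ẽ = 10·e/max(e)` is scaled survey
effort, and `A[i,t] ~ Bernoulli(0.5)` indicates presence in the study area
that year (absent individual-years are pinned to placeholder values and drop
out of the likelihood). Only individuals seen on ≥ 5 distinct survey days in
at least one year enter the model.

The posterior (adaptive Metropolis-within-Gibbs with exact presence updates;
3 chains, BGR < 1.1 and ESS > 400 checks built in) is propagated into:

- **space use** — per-draw normal occurrence per bin, weighted by residency
  rescaled to [0, 1], averaged over draws;
- **exposure** — per-draw overlap of occurrence with each stressor layer
  (scaled to [0, 1]; static per-bin or monthly dynamic, annualised), one
  exposure value in [0, 1] per draw, per individual-year and stressor;
- **post hoc** — activity range in km (`4·σ·110`) and probabilistic
  contrasts of group mean activity centers (e.g. juvenile vs. mature).

A seeded synthetic-data generator produces surveys, individuals, sightings
and stressor layers with exactly this generative structure, plus ground
truth for recovery experiments. See `docs/methods.md` for the full account.

## Worked example

```python
import secr1d as s

scen = s.SimScenario(n_bins=30, n_years=3, n_individuals=15, seed=42)
effort    = s.simulate_effort(scen)
truth     = s.simulate_individuals(scen)
sightings = s.simulate_sightings(truth, effort, scen)
grid = scen.grid

enc = s.build_encounter_array(s.assign_latitude_bins(sightings, grid),
                              effort, grid, min_days=5)
cfg = s.ModelConfig(n_chains=3, n_iter=20_000, burn_in=5_000, thin=10, seed=7)
post = s.mcmc_fit(enc, grid, cfg)

diag = s.convergence_table(post)
ranges = s.range_summaries(post)
layer = s.scale_layer(s.simulate_stressors(scen)[0])
exposure = s.exposure_summaries(
    s.exposure_distribution(post, layer, grid), post, layer.name)
```

With this seed the run prints, via the snippets in between:

```
12 individuals x 3 years, 805 encounters, 20 qualifying individual-years
max BGR = 1.029, min ESS = 146
mean activity range 26.3 km (min 11.43, max 51.7)
individual_id  year   stressor   median     mean     lo90     hi90
         W002  2016 port_north 0.648485 0.640164 0.531479 0.719483
         W002  2017 port_north 0.000000 0.000053 0.000000 0.000000
         W002  2018 port_north 0.000000 0.000026 0.000000 0.000000
```

Reading this: 12 of the 15 simulated animals cleared the five-day filter;
the chains mix across runs of this length (BGR near 1; the short demo chains
leave some parameters under the ESS 400 bar, which the full-length defaults
clear); the qualifying individual-years use activity ranges of ~11-52 km;
and individual W002 overlaps the northern-port stressor heavily in 2016
(median relative exposure 0.65 of the theoretical maximum) but is estimated
absent or far south in 2017-2018, where its exposure collapses to zero.

The same pipeline runs from a single YAML file on real tables
(`individual_id,date,latitude` sightings, `date,bin_index,area_km2` effort,
per-bin stressor layers):

```sh
secr1d run --config analysis.yaml --seed 1
```

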