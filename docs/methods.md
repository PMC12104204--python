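# Methods

## Model

`secr1d` implements a spatially explicit capture-recapture (SECR) model on a
one-dimensional latitudinal grid, designed for repeat photo-identification
sightings of individually recognisable animals along a narrow coastal strip
where longitudinal variation is negligible. The study area is tiled by
`n_bins` half-open latitude bins of width `bin_width_deg` (defaults 55 bins of
0.01°, about 1.1 km each).

The data are annual encounter histories: `S[i,l,t]`, the number of times
individual `i` was sighted in bin `l` in year `t`, together with the area
surveyed `e[l,t]` (km²). Only individuals seen on at least five distinct
survey days in at least one year are modelled; retained individuals contribute
all study years, with the latent presence indicator absorbing years in which
they were unobserved, and per-year inclusion flags are kept so summaries can
also be restricted to qualifying individual-years.

The observation model is

    S[i,l,t] ~ Poisson(λ[i,l,t])
    λ[i,l,t] = 0                                    if e[l,t] = 0
             = γ[i,l,t] · exp(−d²[i,l,t] / 2σ²[i,t]) otherwise
    γ[i,l,t] = A[i,t] · exp(R[i,t] + β_e · ẽ[l,t])

with `d` the distance in degrees from the bin centroid to the individual's
annual activity center `C[i,t]`, and `ẽ = 10·e/max(e)` the effort covariate
scaled by its global maximum across all bins and years (so years share a
common scale). The step function at zero effort encodes that nothing can be
sighted where nobody surveyed. The latent hierarchy is

    log σ²[i,t] = μ + M[i,t],   M ~ Normal(0, ω²)
    R[i,t] ~ Normal(0, 1)
    A[i,t] ~ Bernoulli(0.5)
    C[i,t] ~ Uniform(grid extent)

When `A[i,t] = 0` the reported activity center and range are pinned to
placeholder values (52° N, 0.001 deg²) and contribute nothing to the
likelihood; all space-use and exposure summaries treat those draws as zeros,
never as estimates. The continuous uniform prior on `C` over the grid extent
is equivalent to constraining the center to lie in one of the bins, without
artificially discretising a continuous quantity.

Because animals move in and out of the study area, the closed-population
assumption of classical SECR is deliberately relaxed; the model therefore
estimates *where individuals occur when present*, not density or abundance.

### Priors

The structural priors on `C`, `A` and `R` are part of the model. The
remaining hyperpriors are configuration (`PriorSpec`), with defaults
`μ ~ Normal(−5, 3²)` on the log deg² scale (diffuse, centred near the scale
of activity ranges of tens of kilometres), `ω ~ half-Normal(1)` and
`β_e ~ Normal(0, 10²)`. Prior-sensitivity reruns are a matter of editing the
configuration, not code.

## Sampler

Fitting is Metropolis-within-Gibbs. The likelihood factorises over
individual-years given the globals, so the per-individual-year blocks
(`C`, `M`, `R`) are updated with vectorised random-walk Metropolis proposals
accepted independently per element. The presence indicators are drawn
exactly from their two-point full conditionals (an individual-year with any
sighting is present with probability one; otherwise the conditional odds are
`exp(ℓ₁)` against 1, where `ℓ₁` is the Poisson log-likelihood under
presence). Globals `μ` and `β_e` use scalar random walks against the full
likelihood; `ω` touches only the `M` prior and is updated on the log scale
with the Jacobian term. When an individual-year is absent, its latent
`C`, `M`, `R` follow their priors, which keeps the two-point presence update
exact without trans-dimensional machinery.

Step sizes adapt toward a 0.44 acceptance rate with a decaying learning rate
during burn-in only; the post-burn-in kernel is fixed, so the retained draws
target the correct stationary distribution. Initialisation: `C` at the
sighting-weighted mean latitude (extent midpoint when unseen), `M = R = 0`,
`A = 1` wherever sightings exist (else a prior draw), globals at their prior
centres. Chains differ only by seed streams spawned from the configured
seed, and all draws retained are post-burn-in, thinned 1-in-`thin`
(defaults: 3 chains × 400,000 iterations, 50,000 burn-in, thin 100).

Convergence is assessed with the classic Brooks-Gelman-Rubin potential scale
reduction factor (between/within-chain variances, flagged at 1.1) and an
autocorrelation-based effective sample size with Geyer initial-positive-
sequence truncation (flagged at 400). Parameters with zero within-chain
variance — e.g. a presence indicator forced to 1 by data — are reported as
undefined rather than raising.

## Space use and exposure

Per retained draw, the relative occurrence of an individual in a bin is the
normal probability mass between the bin edges, using that draw's `C` and
`σ²`. Mass beyond the grid is truncated, not renormalised, so occurrence
vectors sum to at most 1. The residency intercept `R` (exponentially related
to encounter rate, hence used on its natural scale rather than logged) is
min-max rescaled to [0, 1] within each draw, jointly across all present
individual-years of the dataset so that years are comparable; absent
individual-years get 0, and if all present values coincide they map to 1 (a
lone observed individual counts as fully resident, not absent). Alternative
rescaling scopes are a deliberate configuration point of
`rescale_residency`, since the weighting is a definition, not an estimate.

Stressor layers are per-bin intensities scaled by their maximum so 1 means
highest relative intensity; dynamic layers (per bin, year, month) are scaled
by their single global maximum and annualised by averaging over months
within each (bin, year). Distance-based proxies are inverted before scaling
(`max_dist − d` by default; a reciprocal form is available) so that
proximity maps to high intensity. Zone-level data (e.g. per-fishing-zone
vessel counts) are mapped to bins by length-weighted overlap after dividing
each zone's value by its area.

Exposure for an individual-year, per draw, is
`E = (Σ_l occ_l · s_l) · R′ ∈ [0, 1]`; across draws this gives one exposure
distribution per individual-year-stressor, summarised by the median, mean
and central 90% interval, plus annual and overall means of the per-
individual-year medians as reference levels.

## Post hoc summaries

Activity range in kilometres is `4·σ·110` per draw: 4σ spans the central 95%
of the normal kernel, and 110 km/degree converts the 0.01°-per-1.1-km grid
scale. Draws with `A = 0` are excluded from range summaries. Group contrasts
(e.g. juvenile vs. mature) compute, per draw, the mean activity center over
each group's present members; the probability of direction is the fraction
of difference draws above zero, with exact ties counted half toward each
side and draws in which a group has no present member skipped and counted.
Labels are per individual-year, so animals that mature mid-study change
group between years.

## Synthetic data

The generator (`secr1d.synthetic`) is the package's test bed and emulates
the statistical structure the model assumes: ~30 survey days per June-
October season with uniform, north-heavy or patchy per-bin daily effort
(patchy guarantees some zero-effort bin-years); individuals present with
probability 0.5 per year, with uniform activity centers, log-normal activity
ranges (`mu_true = −5.5`, `omega_true = 0.8`, putting the median range near
28 km and the 95% spread at roughly 7-110 km) and standard-normal residency
intercepts; Poisson annual counts from exactly the model's rate, apportioned
to survey days in proportion to daily effort (the model is annual, but dated
records are needed for the five-day filter — the apportionment preserves the
annual rate exactly and any within-season law would do); and stressor layers
comprising three static proximity proxies plus two monthly dynamic fields
with year-to-year drift. All outputs are deterministic functions of the
scenario seed via independent spawned substreams.

What the generator does *not* emulate: measurement error in latitudes,
misidentification, behavioural responses to the survey platform, spatial
autocorrelation of effort with whale distribution, multi-modal space use,
and within-season movement. Passing recovery tests therefore demonstrate
correctness of the implementation under the model's own assumptions, not
robustness to their violation in field data.

## Numerical choices and problem sizes

- Bins are half-open with the lower edge inclusive; bin membership is
  computed against the exact edge array (searchsorted) so shared edges
  resolve deterministically in floating point.
- The log-likelihood includes the full Poisson normalising constants and
  returns −∞ exactly when a positive count sits on a zero rate.
- Effort scaling uses the global maximum over bins and years (flagged in the
  configuration; a per-year variant would change the meaning of `β_e`).
- Degenerate inputs fail loudly: all-zero effort, all-zero stressor layers,
  sightings in unsurveyed bin-years, and empty inclusion sets are errors,
  not silent zeros. An individual with all sightings in one bin is valid;
  its range posterior is then prior-dominated from below.
- Test and example runs use scaled-down chains (hundreds to tens of
  thousands of iterations on 15-30-bin grids), chosen as the smallest
  problems that exercise every code path and give stable Monte-Carlo
  checks; the configured defaults reproduce full-scale analyses.

## Known limitations

One-dimensional space use only; no density estimation (by design, as the
population is open); annual temporal resolution, so within-season exposure
dynamics are averaged away; exposure is relative overlap, not dose; and the
residency rescaling makes exposure comparable within a fitted dataset but
not across datasets fitted separately.
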