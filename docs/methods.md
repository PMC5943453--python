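# Methods

This package implements a Bayesian demographic trend analysis for
constant-effort bird-banding data of the kind produced by the MAPS
(Monitoring Avian Productivity and Survivorship) network: station-year
counts of adults, station-year juvenile/total captures, and individual
annual capture histories, with a human-footprint covariate per station.
Everything runs end-to-end on synthetic data whose generator encodes the
same generative assumptions as the fitted models, so recovery of known
truth is testable throughout.

## Models

**Breeding-density index (Poisson log-linear).** The adult count
C_{k,s,t} at station s in region k and year t is Poisson with

    log(lambda_{k,s,t}) = alpha_k + beta_trend_k * t + beta_hf * HF_s
                          + beta_effort * EF_{s,t} + omega_s + eps_{k,s,t}

where omega_s ~ N(0, sigma_station^2) is a station effect and
eps ~ N(0, sigma_noise^2) an observation-level deviate giving
lognormal-Poisson overdispersion. Effort enters as a standardized linear
covariate, not an offset, so the model can estimate rather than assume the
count-effort elasticity. Station-years with no operation are missing, never
zero.

**Relative productivity (binomial).** With N_{k,s,t} birds captured and
JUV_{k,s,t} of them juveniles,

    JUV ~ Binomial(N, p),   logit(p) = alpha_k + beta_trend_k * t
                                        + beta_hf * HF_s + omega_s.

The juvenile proportion is an index of reproductive output that folds in
nesting success and early post-fledging survival.

**Apparent survival (transient Cormack-Jolly-Seber with residency
mixture).** Capture histories condition on first capture. A new bird is a
local resident with probability pi and a transient otherwise; transients
are permanently unavailable after the first occasion. Residents survive an
interval with probability phi, are recaptured when alive with probability
pr, and are "pre-determined" residents (caught in more than one
within-season visit, hence known residents) with probability rho.
phi carries intercept, region offset, sex, footprint, a region-specific
year trend and a station effect; pi the same without the trend; pr and rho
carry intercept, sex and a station effect. The west region is the reference
level (offset fixed at zero) for every region-structured term — the model
would otherwise be overparameterized, having both a common intercept and a
full set of region terms.

Writing chi_t for the probability a live resident is never seen after
occasion t (the standard backward recursion), the likelihood of a history
with pre-determination flag d is

    d = 1:  pi * rho * P_CJS
    d = 0:  pi * (1 - rho) * P_CJS + (1 - pi) * I[no detection after first]

with P_CJS the usual product of phi/pr terms up to the last detection times
chi. The flag d is treated as observed data with its Bernoulli(rho) term; a
consequence worth noting is that even a one-occasion history is mildly
informative (P(d=0) = 1 - pi*rho). Summed over all detection vectors and
both flag outcomes the likelihood is exactly 1, which the test suite
verifies by enumeration; with pi = 1 and rho = 0 it reduces to the textbook
CJS likelihood. The trend covariate for the interval t -> t+1 is evaluated
at year t, and pr is indexed to the occasion of potential recapture.

**Derived recruitment.** The region index N_{k,t} is the station sum of
expected counts at mean effort with the observation-level noise set to
zero; regional survival phi_{k,t} is the unweighted male/female average at
the region's mean footprint and a typical station. Per posterior draw,

    rec_{k,t+1} = N_{k,t+1} - N_{k,t} * phi_{k,t}

is an identity, so abundance and survival uncertainty propagate exactly.
Recruitment draws may be negative (losses exceeding replacement); they are
kept in the series but excluded from the per-draw log-linear trend fit,
with exclusion counts reported. Recruitment trends are per-draw
least-squares slopes of log(rec) on year (an endpoint-ratio variant would
be a one-line change; regression uses all years and is the default).

## Covariates and standardization

Footprint is z-scored across stations, effort across station-years
(population-SD convention), and the year covariate is centered at the
study midpoint with unit = one year, so all trend coefficients are
per-year on the link scale and percent-per-year conversions are
100*(exp(beta)-1). Scaling constants are retained and
`destandardize_linear` reproduces raw-scale predictions to machine
precision. Station footprint values come from the two global raster years:
the mean of 1993 and 2009 when the station was active in both, otherwise
the value nearest the median active year, ties toward 2009.

Region is assigned from coordinates: west of 102°W is "west" (strict
inequality; a boundary station goes central); among the rest, stations
south of 47°N and east of a configurable meridian (default 90°W) are
"east", everything else "central". The eastern rule needs that meridian
because the region is described geographically rather than algorithmically;
real-data classifications should be audited against it.

Filters: the count model keeps stations with at least one capture;
productivity drops stations whose captures were all juveniles; survival
keeps stations with at least five marked individuals. Unknown-sex
individuals are excluded from survival data (exclusions would be logged);
station-years with zero recorded effort are treated as not operated.

## Inference

Sampling is adaptive random-walk Metropolis-within-Gibbs, written for this
package: scalar coefficients are single-site Metropolis blocks; each
station-random-effect vector is updated elementwise from a single
vectorized likelihood evaluation (valid because the likelihood factorizes
over stations); the observation-level noise vector is updated the same way
per observation. Proposal scales adapt toward 0.35 acceptance in windows
of 50 iterations during burn-in only, so retained draws come from a
fixed-kernel chain. Coefficients have diffuse normal(0, variance 10^3)
priors. Random-effect variances have inverse-gamma(0.001, 0.001) priors
and are drawn by exact conjugate Gibbs updates — a deliberate choice over
Metropolis on the log scale, since the conditional is available in closed
form and mixes better. Initial values: coefficients ~ N(0,1), random
effects ~ N(0, 0.5) (starting them at zero would put the first conjugate
variance draw in the degenerate sigma -> 0 corner), variances at 1, all
seed-controlled; runs are bit-reproducible given the configuration.

Abundance and survival are fitted jointly in a single model (independent
likelihoods sharing one iteration counter) so recruitment is derived from
aligned draws; productivity is fitted separately.

The full protocol is two chains of 100,000 iterations, 80,000 burn-in,
thinned by 2 — 20,000 pooled draws. Desk-scale runs and the test suite use
reduced presets of the same structure (e.g. 2 x 4,000/2,000 for the
survival model, 2 x 3,000/1,500 for the count models); these lengths were
chosen as the smallest at which R-hat for the slowest parameters settles
near 1.05 on study-scale data. Diagnostics are the classic Gelman-Rubin
R-hat (two identical chains degenerate to sqrt((n-1)/n), reported as-is),
narrowest-window HPD intervals, and the posterior mass below zero. No hard
R-hat gate is imposed; values are reported.

For the likelihood-heavy survival model the sampler collapses histories
with identical sufficient statistics — the per-history likelihood depends
only on (station, sex, first capture, last detection, number of
re-detections, flag) — and caches the phi/pi/pr/rho components of the
likelihood so an update of one family recomputes only its own terms.
Both optimizations are exact and are tested against the plain per-history
evaluation.

## Synthetic data

The generator draws stations (coordinates consistent with their region
label, footprint values from region-level means on the 0-50 index scale,
contiguous activity windows, net-hour effort around 500 per station-year),
then counts, juvenile/total captures and capture histories from exactly
the models above. Defaults are the study conditions: 23/3/33 stations per
region, 24 years, abundance trends of -1.48/+1.21/-4.64 percent per year,
juvenile proportions 0.35/0.43/0.32, female apparent survival
0.31/0.46/0.30 with a +0.58 logit sex effect, residency 0.58/0.28/0.23
with +0.42, recapture 0.27 (female) / 0.56 (male), footprint effects
-0.66 (density), +0.16 (productivity), +0.03 (survival), -0.46
(residency), and station-effect SDs of 0.3-0.4. The pre-determination
parameters are not published; rho = 0.40 for females with a +0.3 logit sex
effect is a realistic default for 6-9 within-season visits and is
configurable. New individuals enter as a Poisson stream (default 2.5 per
station-year) — entries are not coupled to the abundance model, which the
underlying analysis does not specify either.

What the generator does not emulate: spatial station placement beyond the
region boxes, within-season visit structure (collapsed to the single
pre-determination flag), climate or habitat covariates, sex-ratio
imbalance (default 0.5), and recapture availability limited to a station's
operating years — a resident can be re-detected in any year after first
capture, matching the constant-pr assumption of the fitted model. Passing
recovery tests therefore demonstrates correctness of the estimator under
the model's own assumptions, not robustness to the ways real monitoring
data violate them (trap response, emigration waves, effort-dependent
detection within seasons).

## Numerical choices and degenerate inputs

Probabilities are evaluated through `log_expit` so saturated logits stay
finite; 0 * log(0) guards cover degenerate pr; an impossible history
(e.g. a re-detection when pi = 0) yields likelihood 0, not an error.
Poisson log-means above the exp() overflow range raise in the public API
and are rejected as proposals inside the sampler. Zero-variance covariates
raise at standardization. HPD intervals require at least 100 draws; R-hat
at least 2 chains of 10 draws. The footprint-year tie (median active year
equidistant from 1993 and 2009) resolves to 2009.

## Known limitations

Group-level survival and residency estimates at study scale carry
posterior SDs of 0.03-0.08 on the probability scale (~1,500 marked
individuals), so single-dataset point recovery is noise-limited; the
recovery tests average over replicate datasets and check interval
coverage instead. The central region in the default design has 3 stations,
so its estimates are dominated by realized station effects, as in the
underlying study. The sampler is a random-walk scheme: adequate at these
data sizes, but chain lengths in the thousands are needed where a
gradient-based sampler would need hundreds; the reduced presets reflect
that trade-off. Annual indices with spatial autoregression are out of
scope — trends are modelled as linear on the link scale.
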