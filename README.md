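# mapsdemog

Bayesian demographic trend analysis for constant-effort bird-banding data,
built for the kind of dataset the MAPS (Monitoring Avian Productivity and
Survivorship) network produces for a declining migratory songbird: which
vital rate — breeding density, productivity, adult apparent survival or
recruitment — is driving a range-wide decline, and how does human footprint
around stations affect each?

The pipeline couples four pieces:

- **Breeding-density index** — station-year adult counts C_{k,s,t} as
  Poisson with
  `log λ = α_k + β_1k·t + β_2·HF_s + β_3·EF_st + ω_s + ε`,
  with station random effects and observation-level lognormal noise.
- **Relative productivity** — juvenile captures JUV ~ Binomial(N, p) with
  `logit p = α_k + β_1k·t + β_2·HF_s + ω_s`.
- **Apparent survival** — a transient Cormack-Jolly-Seber model with a
  residency mixture: each newly banded bird is a resident with probability
  π (or a passing transient, never seen again); residents survive with
  probability φ, are recaptured with probability pr, and are identified as
  residents by within-season repeat capture with probability ρ. All four
  are logit-linear in region, sex, footprint and (for φ) a per-region year
  trend, with station random effects.
- **Derived recruitment** — per posterior draw,
  `rec_{k,t+1} = N_{k,t+1} − N_{k,t}·φ_{k,t}`, so recruitment trends carry
  the joint uncertainty of the count and survival models.

Sampling is an adaptive Metropolis-within-Gibbs scheme written in numpy
(conjugate Gibbs draws for random-effect variances), with classic
Gelman-Rubin R-hat, narrowest-window 90% HPD intervals and
posterior-mass-below-zero reporting. Because the motivating banding data
are restricted-access, the package ships a synthetic-data generator whose
defaults reproduce the study conditions (59 stations in three breeding
regions, 24 years, region trends of −1.48/+1.21/−4.64 %/yr, sex- and
region-structured survival and residency), so every stage runs and is
tested against known truth.

## Worked example

The analysis is organised as numbered drivers over the library in
`src/mapsdemog/`:

```
python analysis/01_simulate.py        --seed 1   # write results/data/
python analysis/02_fit_joint.py       --seed 1   # abundance + survival
python analysis/03_fit_productivity.py --seed 1
python analysis/04_summarize.py
```

`01_simulate.py` reports the dataset dimensions:

```
wrote results/data/: 59 stations, 504 station-years of counts,
502 productivity records (2636 captures), 1275 capture histories
```

`02_fit_joint.py` applies the station filters (≥1 capture for counts, ≥5
marked individuals for survival), fits both models jointly at the reduced
preset (2 chains × 4,000 iterations, 2,000 burn-in) and reports the worst
R-hat. `04_summarize.py` then prints the per-region trend table (trend
coefficient is per year on the link scale; `percent_per_year` is
100·(e^β−1); `prob_decline` the posterior mass below zero):

```
             rate  region    mean  hpd_low  hpd_high  percent_per_year  prob_decline
 breeding_density    west  0.0008  -0.0188    0.0177            0.0826        0.4552
apparent_survival    west -0.0442  -0.0898   -0.0028           -4.3260        0.9530
     productivity    west -0.0106  -0.0363    0.0173           -1.0573        0.7367
      recruitment    west  0.0148  -0.0078    0.0376            1.4880        0.1355
 breeding_density central  0.0185  -0.0147    0.0526            1.8647        0.2028
apparent_survival central  0.1173  -0.0197    0.2537           12.4460        0.0747
     productivity central -0.0232  -0.1117    0.0675           -2.2955        0.6607
      recruitment central -0.0212  -0.0815    0.0403           -2.1005        0.7235
 breeding_density    east -0.0418  -0.0613   -0.0218           -4.0914        1.0000
apparent_survival    east -0.0282  -0.0833    0.0324           -2.7846        0.7957
     productivity    east  0.0017  -0.0260    0.0237            0.1678        0.4663
      recruitment    east -0.0335  -0.0597   -0.0060           -3.2937        0.9690
wrote results/report/
```

On this seed the fitted eastern breeding-density trend (−4.1 %/yr, HPD
excluding zero, Pr(decline) ≈ 1) recovers the −4.64 %/yr simulated truth,
the central region is positive and uncertain (3 stations), and eastern
recruitment declines (−3.3 %/yr, Pr ≈ 0.97) while productivity shows no
trend — the pattern that points at the non-breeding season rather than
breeding success. `results/report/` also contains the survival/residency
table by region and sex and the footprint-effect table with Pr(<0).

At the full protocol (`--preset full`: 2 × 100,000 iterations, 80,000
burn-in, thinned by 2 → 20,000 pooled draws) the joint fit takes a few
hours.

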