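# sealphen

Tools for analysing the phenology of the grey seal (*Halichoerus
grypus*) pupping season — when pups are born, how that timing responds
to sea-surface temperature (SST), and whether the response acts on
individual mothers or on the age structure of the breeding population.
The package is aimed at population ecologists working with colony
census data: repeated pup counts through a season, longitudinal
resightings of known mothers, and a gridded SST product.

## The analysis

**Season curves.** Cumulative pup counts through a season closely
follow a three-parameter logistic,

```
y(t) = A / (1 + exp((m − t) / s)),
```

with `A` the season total, `m` the midpoint (the day 50% of pups have
been counted; all dates are days since 1 July) and `s` a scale whose
central 95% span, `2 s ln 39`, is reported as season length. Curves are
fitted per year by bounded nonlinear least squares with an optional
AR(1) error process; goodness of fit is Lin's concordance correlation
coefficient.

**SST forcing.** Yearly totals, midpoints and lengths are regressed on
quarterly SST windows (previous autumn, winter = Dec–Feb preceding the
season, spring, summer, autumn) with penalized cubic regression splines
(gamma errors, log link, shrinkage smoothers, previous-year value as a
second smooth), and the windows are ranked by AICc. The engine is a
penalized-IRLS GAM/GAMM with GCV or REML smoothing selection and random
intercepts implemented as identity-penalized terms.

**Mechanism.** Two further models separate the candidate mechanisms:
pupping date of individual females against years-since-first-sighting
and winter SST with a female random intercept (is it the mother ageing,
or the sea?), and log yearly mean maternal age against winter SST (does
a warm winter recruit an older breeding cohort?).

**Demographic bound.** A seven-stage matrix population model (four
juvenile stages, three breeding stages with fertility = Pr(birth) ×
Pr(weaning)) yields the growth rate λ and the stable stage distribution
w. Because older mothers pup earlier, the population mean pupping date
is the pup-weighted average of stage dates with weights ∝ w_i ×
fertility_i. Discrete +10% perturbations of each matrix element, and a
sweep pushing old-adult survival to 0.999, bound how much phenological
advance a changed *stable* age structure could ever produce.

A fully parameterized synthetic-colony generator (`SimConfig`,
`simulate_all`) provides ground-truthed datasets for all of the above.

## Worked example

```python
import sealphen as sp

cfg = sp.SimConfig(rng_seed=1)          # 27-season synthetic colony
sst = sp.simulate_sst(cfg)
truth = sp.derive_true_season_params(sst, cfg)
surveys = sp.simulate_surveys(truth, cfg)

fit = sp.fit_season_curve(sp.build_cumulative(surveys, 1999))
print(f"1999: total={fit.A:.1f} pups, midpoint=day {fit.m:.1f}, "
      f"length(95%)={fit.length:.1f} d, ccc={fit.ccc:.4f}")
```

```
1999: total=224.6 pups, midpoint=day 87.9, length(95%)=79.6 d, ccc=0.9992
```

The fitted total, midpoint and scale sit on the generating values for
that season (222.9 pups, day 88.8, s = 10.16), and the concordance
above 0.995 says the logistic describes the cumulative counts almost
perfectly. The demographic bound from the command line:

```
$ sealphen mpm --out-dir out
lambda = 1.0700
mean pupping date = 86.34 days since 1 July
max achievable advance = -3.06 days
```

λ = 1.07 is the calibrated annual growth rate; the mean pupping date is
the pup-weighted stable-structure statistic; and even pushing old-adult
survival from 5% to 99.9% advances the season by at most ~3 days —
far less than the week-scale shifts seen at the population level, which
is the argument that *transient* age-structure change (e.g.
immigration), not the stable distribution, must carry the signal.

`sealphen all --seed 2 --out-dir out` runs the whole pipeline
(simulate → season curves → window comparison, individual and mean-age
models → matrix analyses) and writes every table plus a JSON report.

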