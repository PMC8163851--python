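# firegest

Self-comparison case–control analysis of gestational exposure to
fire-sourced PM2.5 and pregnancy loss.

Open-fire smoke (wildfires, crop burning, forest fires) episodically
drives fine-particle concentrations far above the urban background, and
pregnant women are among the most exposure-susceptible groups.
`firegest` implements, as a reusable and fully tested pipeline, the
epidemiological machinery needed to quantify that risk from
retrospective reproductive histories and chemical-transport-model (CTM)
output:

* **Exposure assessment** — paired CTM runs with and without fire
  emissions are turned into a monthly fire fraction
  `rho = (PM^wfire − PM^nofire) / PM^wfire` (clamped to [0, 1]), an
  annual calibration rate `eta = PM^satellite / mean_m(PM^wfire)`
  against a satellite-based reference, and calibrated exposure series
  `total = eta·PM^wfire`, `fire = eta·rho·PM^wfire`,
  `non-fire = eta·(1−rho)·PM^wfire`, downscaled to a 0.1° grid by
  inverse-distance weighting.
* **Matched cohort construction** — each mother's most recent pregnancy
  loss (the case) is compared against her own live births (controls),
  cancelling everything constant within a mother. Every event's
  covariates are averaged over a window of the *case's* gestation
  length starting at that event's own conception month.
* **Conditional logistic regression** — the exact conditional
  likelihood for 1:m matched sets, maximised by Newton–Raphson with
  step-halving; covariates follow the standard specification (maternal
  age bands, natural splines for temperature, humidity and conception
  month, calendar-year indicators, mutual adjustment of fire by
  non-fire PM2.5); likelihood-ratio tests, exposure-by-subgroup
  interactions, and spline/categorical exposure–response curves.
* **Impact accounting** — attributable fractions
  `AF = 1 − 1/exp[β·(PM2.5 − TMREL)]` with TMREL 0 µg/m³ for fire and
  10 µg/m³ for non-fire PM2.5, and the fire share of the PM2.5-linked
  burden.
* **A synthetic world** — a seeded generator of gridded fire/non-fire
  PM2.5, weather and burned-area fields plus mother-level reproductive
  histories whose loss risk follows a known mother-stratified logistic
  model, so that every stage of the pipeline (and its ability to
  recover known effect sizes) is testable without any external data.

The modelling interface follows the statsmodels idiom: a
`ConditionalLogit` model built from a long matched-set DataFrame, whose
`fit()` returns a results object with coefficients, covariance, odds
ratios per stated unit increment, and a `summary()` table.

## Worked example

Simulate a world of 40,000 mothers with a true fire effect of ln(1.051)
per µg/m³ and a non-fire effect of ln(1.014), build the matched cohort,
and fit the fully adjusted, mutually adjusted model:

```python
import firegest as fg
from firegest.study import build_cohort_from_world
from firegest.pipeline import default_terms

config = fg.WorldConfig(rng_seed=1, n_mothers=40000)
world = fg.simulate_world(config)
cohort = build_cohort_from_world(world)
result = fg.ConditionalLogit.from_dataframe(cohort.data, default_terms()).fit()
print(result.summary())
```

```
Conditional logistic regression (matched sets)
  sets: 9957   events: 31109   params: 31
  log-likelihood: -10593.2283   converged: True (4 iterations)

term                          coef        se       OR     2.5%    97.5%
fire                        0.0405    0.0160   1.0413   1.0092   1.0744
nonfire                     0.0087    0.0055   1.0087   0.9979   1.0196
age_band[20-24]            -0.2606    0.0660   0.7706   0.6771   0.8770
age_band[25-29]            -0.2176    0.0949   0.8045   0.6679   0.9690
age_band[30-34]            -0.1095    0.1260   0.8963   0.7001   1.1474
age_band[35-39]             0.1991    0.1641   1.2204   0.8847   1.6833
age_band[>=40]              0.5281    0.2452   1.6957   1.0487   2.7417
...
```

At ~10,000 matched sets the fitted fire odds ratio (1.041, CI
1.009–1.074) brackets the injected truth of 1.051; the non-fire OR
(1.009, CI 0.998–1.020) brackets 1.014. The age-band odds ratios show
the injected J-shape (relative to the `<20` reference). Converting the
coefficients into attributable fractions:

```python
from firegest import impact
ci = result.conf_int()
af_fire = impact.af_result("fire", result.params["fire"],
                           cohort.data["fire"].mean(), impact.TMREL_FIRE,
                           (ci.loc["fire", "lower"], ci.loc["fire", "upper"]))
af_non = impact.af_result("nonfire", result.params["nonfire"],
                          cohort.data["nonfire"].mean(), impact.TMREL_NONFIRE,
                          (ci.loc["nonfire", "lower"], ci.loc["nonfire", "upper"]))
comp = impact.compare_sources(af_fire.af, af_non.af,
                              result.params["fire"], result.params["nonfire"])
```

```
AF fire    : 0.0391 (0.0090, 0.0684)
AF non-fire: 0.2500 (-0.0737, 0.4760)
fire share of PM2.5-linked loss: 13.5%
```

Fire PM2.5 contributes only ~2 % of the simulated concentration, yet —
because its per-µg/m³ effect is several times that of non-fire PM2.5 —
around 14 % of the PM2.5-linked loss burden in this draw.

## Command line

The same pipeline runs from a shell, driven by a YAML configuration:

```sh
firegest run-all --config run.yml --seed 7 --out-dir out/
firegest fit --config run.yml --subgroups --nonlinear
```

Each run writes the event table, the matched cohort, per-model
coefficient CSVs, an impact summary, and a `manifest.json` (seed, input
hashes, per-stage row counts); a fixed configuration and seed reproduce
every output byte-for-byte apart from the manifest timestamp.

## Layout

| module | contents |
| --- | --- |
| `firegest.synthetic` | world configuration, field and cohort generators, reduced matched-set generator |
| `firegest.exposure` | fire fraction, calibration, decomposition, IDW downscaling, window means, NetCDF IO |
| `firegest.cohort` | case selection, window-matched controls, sensitivity-subset flags |
| `firegest.clogit` | `ConditionalLogit` model/results, LRT, interactions, exposure–response |
| `firegest.design` | term specifications, natural-spline and Fourier bases |
| `firegest.impact` | attributable fractions and source comparison |
| `firegest.pipeline` / `firegest.cli` | run configuration, orchestration, manifest, CLI |

See `docs/methods.md` for the statistical model, the synthetic-data
design and its limitations, and all numerical choices.
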