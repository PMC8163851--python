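# Methods

This note documents the statistical model, the exposure-assessment
conventions, the synthetic-data design, and every numerical or design
choice a maintainer might want to revisit. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The matched design and its estimand

The outcome is pregnancy loss (miscarriage: recalled gestation <5
months; stillbirth: ≥5 months) in retrospective reproductive
histories. Confounding across mothers is severe — genetics, wealth,
health care, residence — so the design compares each mother with
herself: her most recent loss inside the study period (the **case**)
against her own live births (the **controls**). Anything constant
within a mother cancels exactly.

Exposure windows are matched, not gestations: losses terminate early,
so a control averaged over its full nine-month pregnancy would see a
systematically longer window than its case. Every member of a set is
therefore averaged over a window of the *case's* gestation length `g`,
starting at the member's own conception month. Within a set the windows
are equally long and differ only in placement.

With exactly one case per set, the conditional likelihood of set *s*
with member covariates `x_j` is

    L_s(beta) = exp(x_case · beta) / sum_j exp(x_j · beta)

which is free of the set (mother) intercept. There are no ties, so no
Breslow/Efron variants are needed. The fitted `beta` is the log odds
ratio per unit of each covariate; fire and non-fire PM2.5 are reported
per 1 µg/m³.

**Covariate specification** (the fully adjusted, mutually adjusted
model): linear fire PM2.5; linear non-fire PM2.5 (mutual adjustment);
maternal age in six bands (<20, 20–24, 25–29, 30–34, 35–39, ≥40,
reference <20); natural splines with 3 df for window-mean temperature
and relative humidity; a natural spline with 4 df for conception month
(1–12); calendar-year-of-conception indicators (reference: earliest
year) absorbing the secular trend. Temperature and humidity enter as
means over each event's own matched window, so they vary within sets
and are identifiable; exposure odds ratios are invariant to the
reference-category choices.

**Maternal age** is recomputed per event at the end of its matched
exposure window (`conception + g − 1`). For the case this *is* its
termination month; controls are thereby age-rated at the same
gestational offset as their case instead of at delivery (a difference
of at most `9 − g` months). Classifying all members of a set at a
comparable pregnancy stage keeps the age covariate and any
age-dependent effect modification aligned with the period in which the
exposure acts; the alternative (age at each event's own termination)
shifts ~7 % of controls near a band boundary into the band above the
one in which their risk window lay, slightly attenuating age-specific
contrasts. One age definition is used everywhere — adjustment bands,
and the 3-level grouping (<30, 30–34, ≥35) used for effect
modification — because mixing two definitions leaves residual age main
effects that leak into exposure-by-age interaction terms.

## Exposure assessment

Monthly CTM-style fields come in pairs — with (`PM^wfire`) and without
(`PM^nofire`) fire emissions. Three conventions:

* **Fire fraction** `rho = (PM^wfire − PM^nofire)/PM^wfire`, defined as
  0 where `PM^wfire = 0`, and clamped into [0, 1]: CTM chemistry is
  nonlinear, so the without-fire run can exceed the with-fire run, and
  a negative fire concentration is physically uninterpretable.
  Clamping events are counted and reported in the run manifest.
* **Calibration** `eta_y = PM^satellite_y / (1/12 · Σ_m PM^wfire_m,y)`
  per cell and year, constant across that year's months, against an
  annual fine-resolution reference raster. Years must be complete
  (twelve months); an all-zero year leaves the rate undefined and is
  rejected.
* **Decomposition** `total = eta·PM^wfire`, `fire = eta·rho·PM^wfire`,
  `non-fire = total − fire`. Additivity is exact by construction, and
  the annual mean of the calibrated total reproduces the reference
  raster identically — both are asserted as invariants.

**Order of operations**: the coarse monthly fields *and* the fire
fraction are first downscaled to the fine grid, then calibrated there,
matching the resolution at which the satellite reference is defined.
`rho` is downscaled as its own field rather than recomputed from the
two downscaled runs.

**Downscaling** is inverse-distance weighting: k = 4 nearest coarse
cell centres, weights `1/d²` with great-circle distance `d`, an exact
hit returning the coarse value. IDW is a convex combination, so
downscaled fields stay within the coarse min/max. The fine grid is 0.1°
with centres at multiples of 0.1° plus 0.05°; points map to cells by
containment with the lower edge inclusive. Neither the neighbour
count, the power, nor the metric is canonical; these are recorded
choices.

**Window means** are arithmetic means over the inclusive window
`[conception, conception + g − 1]`, applied identically to every
environmental variable. An event whose window is not fully covered by
the field months is exposure-invalid: an invalid control is dropped
from its set, an invalid case drops the set (the count of unmatched
cases is reported).

## Sensitivity-analysis subsets

Each matched set carries boolean eligibility flags:

* case type — miscarriage (case gestation <5 months) or stillbirth;
* all controls singleton births;
* all controls survived >12 months with known status (unknown survival
  excludes under this flag only);
* parity-matched — case and controls all nulliparous with every control
  after the case, or all multiparous;
* bidirectional — at least one control terminating before and one after
  the case (limits secular-trend confounding);
* transported fire — zero satellite burned fraction in *every* window
  month at the mother's cell, the strictest reading; smoke may still be
  present by advection, which is the point of the subset. (Alternative
  readings — zero long-term mean, or a spatial neighbourhood — would be
  easy variants but are not implemented.)
* recall period — survey minus termination below n years (in whole
  months, n = 3, 4, 5, 6) for the case and every control.

Case ties within a month are broken by input record order (the later
record wins); the choice is deterministic and exercised by a fixture.
A control needs only valid exposure, not containment in the study
period; its in-period status is available as data.

## Estimation and inference

Newton–Raphson on the exact conditional log-likelihood: softmax
probabilities stabilised by the per-set maximum; score
`Σ_s (x_case − Σ_j p_j x_j)`; observed information
`Σ_s (Σ_j p_j x_j x_jᵀ − μ_s μ_sᵀ)`. Step-halving (up to 10 halvings)
guards ascent; convergence is a relative log-likelihood change below
1e-10 within 50 iterations, with a negligible-gradient criterion
(‖score‖ ≤ 1e-4·(1+|ll|)) as the operative stop when halving stalls on
float noise at the optimum. The covariance is the inverse observed
information; CIs are Wald. Columns constant within every set carry no
conditional information: they are flagged non-identifiable, excluded
from the optimisation, and reported as NaN — the remaining estimates
equal those of the model that omits them.

**Likelihood-ratio tests** compare nested fits on the same sets
(`2·(ll_full − ll_nested)` against chi-square). Nesting is checked by
column-name containment, with an explicit override for structural
nesting — the linear exposure term lies in the span of its
natural-spline basis, so the linearity test is nested with
`df_spline − 1` degrees of freedom.

**Effect modification** fits exposure × group-indicator products on top
of the full covariate set and reports per-group ORs (linear
combinations of the main and interaction coefficients) plus the
heterogeneity LRT against the common-effect model. The grouping column
may be mother-level (education, residence, insurance — set-constant, so
main effects cancel by design) or event-level (the age grouping, which
varies within sets); in both cases the shared model is a single fit, so
groups borrow strength for the nuisance covariates.

**Nonlinear exposure–response** replaces the linear fire term with a
natural spline (default 3 df; boundary knots at the observed exposure
range, internal knots at quantiles) and reports the log-OR curve
relative to zero exposure on 50 grid points from 0 to the 99th
exposure percentile, with pointwise Wald bands; evaluation at 0 uses
the spline's linear extrapolation, which is well defined for a natural
basis. A categorical-bins variant (ORs versus the lowest bin) is also
provided.

**Spline basis**: the truncated-power natural cubic basis — df columns,
boundary knots at min/max, df−1 internal knots at equally spaced
quantiles, zero second derivative beyond the boundaries (verified
numerically in tests). A periodic alternative for the conception-month
term is available behind a flag as a Fourier (sin/cos harmonic) basis;
the default is the non-cyclic spline.

## Impact accounting

`AF = 1 − 1/exp[β·(mean_exposure − TMREL)]` with TMREL 0 µg/m³ for fire
and 10 µg/m³ (the WHO guideline level) for non-fire PM2.5. The mean
exposure is taken over all analysed events (cases and controls).
Negative excess exposure is clamped to zero — no protective
attribution. The AF confidence interval substitutes the Wald bounds of
β into the same monotone formula. Source comparison reports the fire
share `AF_fire/(AF_fire + AF_nonfire)` and the per-unit excess-risk
ratio on the OR−1 scale, `(e^β_fire − 1)/(e^β_nonfire − 1) − 1`, as a
percentage. A stratified variant computes per-stratum AFs from stratum
mean exposures with shared coefficients.

## The synthetic world

The generator produces the statistical structure the analysis assumes,
not geographic realism.

**Fields** (monthly, on a 0.5° coarse grid over an 8°×8° domain,
2000–2014 by default): the fire component is a sum of Gaussian spatial
kernels around hotspot centres (σ = 1.2°) × a seasonal weight (1 in
the peak months March–May and October–November, 0.15 otherwise) × a
unit-mean lognormal monthly multiplier (sdlog 0.8) — right-skewed,
seasonally peaked, and spatially concentrated. The defaults give a
long-term peak-season mean of ~5 µg/m³ at a hotspot centre and a
domain-wide mean around 1 µg/m³, the regime of the study setting (mean
fire exposure ~1.2 µg/m³ against a total of ~50). The non-fire field
is a smooth low-order spatial surface (base 45 µg/m³, ±12 spatial
range) with a mild winter peak and weak noise — deliberately different
from the fire field in spatiotemporal pattern. With-fire = non-fire +
fire exactly. Burned fraction is nonzero only near hotspot centres in
peak months (kernel above 0.35), so advected smoke with zero local
burning exists and the transported-fire subset is non-trivial;
dry-matter emission is proportional to burned fraction. The annual
satellite reference is a noisy multiple (factor N(0.95, 0.05)) of the
annual-mean downscaled with-fire field. Weather fields are seasonal
sinusoids with latitude gradients and noise.

**Mothers**: each of `n_mothers` mothers has a cluster (village)
location, 1 + Poisson(2.3) pregnancies (max 8) spaced 10–40 months
apart, a normal mother intercept on the logit scale (mean logit(0.11),
SD 1 — a free nuisance parameter, cancelled by matching), mother-level
education/residence/insurance, and a survey month just after the study
period (enabling recall-period filters).

**Risk model**: each mother draws one latent risk-window length `g`
from the loss-gestation mixture (default over months 1–9 with ~68 %
mass below 5, spanning the miscarriage/stillbirth split; the mixture is
configuration, since no empirical distribution of recalled loss
gestations is canonical). Every one of her pregnancies' loss
probability is

    logit p = alpha_i + beta_fire·fire_w + beta_nonfire·(nonfire_w − 45)
              + age_band_offset + 0.010·(T_w − 26) + 0.004·(H_w − 65)
              + 0.15·sin(2π·month/12) − 0.010·(year − 2000)

where the `_w` quantities are means over `[conception, conception+g−1]`
of the *calibrated* series at the mother's cluster — the same
quantities the analysis computes. A loss realises gestation `g`; a live
birth runs 9 months. Because the case's gestation is `g` and controls
are analysed over windows of the case's length, the generative
covariate coincides exactly with the analysis covariate; drawing `g`
per pregnancy instead would make the analysed control exposure an
error-prone proxy for the generative one and attenuate recovery. The
per-mother window is interpretable as a mother-specific vulnerable
early-gestation period; its side effect (a mother's multiple losses
share a gestation length) is harmless since only the most recent loss
is analysed. Default effect sizes: beta_fire = ln(1.051),
beta_nonfire = ln(1.014); age offsets follow the J-shape (+0.20 at
<20, 0 at 20–24, rising to +0.60 at ≥40); an optional configuration
applies band-specific fire effects (<30/30–34/≥35) for effect-
modification studies.

**A reduced generator** (`simulate_matched_sets`) draws matched sets
straight from the stratified logistic without the spatial machinery —
covariates from a pluggable sampler, outcomes from
`logit p = alpha_i + x·beta`, mothers with ≥1 loss and ≥1 live birth
retained, most recent loss as case. It is used where thousands of
replicates are needed (CI coverage, test power, SE scaling), at a few
tens of milliseconds per replicate.

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real data: recall error in outcomes and
gestation lengths (gestations are exact here, so the
miscarriage/stillbirth split is clean); survey sampling design and
weights; migration (mothers never move, so exposure location is exact);
spatially correlated confounders co-varying with fire activity;
exposure measurement error beyond the satellite calibration noise; and
CTM nonlinearity (the with/without-fire difference is the fire
component by construction, so `rho` clamping never triggers in
synthetic runs — the clamp is exercised by unit tests instead).
Parameter-recovery results show the *estimator* is consistent and its
uncertainty honest under the design's assumptions, not that those
assumptions hold in any particular survey.

## Study sizing

The canonical recovery studies (`firegest.study`, also driven by
`scripts/acceptance.py`) size their cohorts by Monte-Carlo precision:

* main-effect study: ~20,000 matched sets (80,000 mothers), giving a
  fire-coefficient SE of ~0.010 — small against ln(1.051);
* age-heterogeneity study: ~300,000 sets (1.2 million mothers), since
  band-specific contrasts carry far less information per set; band SEs
  are then ~0.3–0.7 excess-risk points, small against the 4.1/7.6/11.1
  point targets. The heterogeneity LRT is decisive at this size.

Both respect a single root seed split per stage; identical
configuration and seed reproduce byte-identical outputs. CI coverage is
checked over 200 replicates of ~5,000 sets with the reduced generator
(empirical 95 % coverage asserted within [0.92, 0.98]).

## Known limitations

* Wald inference only: no robust/sandwich variance, no exact
  conditional (permutation) inference, no random-effects or GEE
  alternatives.
* The AF uses the odds ratio as a rate-ratio surrogate, appropriate for
  the rare-ish outcome regime (~10–15 % per pregnancy) but upward
  biased as the outcome becomes common.
* The AF confidence interval ignores uncertainty in the mean exposure.
* IDW downscaling is not mass-conservative; it is a smoother, not a
  regridder.
* Transported-fire flagging uses the mother's single fine cell; a
  neighbourhood criterion might classify edge cells differently.
* Mothers with all pregnancies outside the simulated period are
  retained in the mother table with a flag but contribute no events.
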