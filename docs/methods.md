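# Methods

`thcdosim` analyzes voluntary oral THC consumption experiments in mice:
how much drug an animal actually ingested, how strongly it responded on
the cannabimimetic triad (open-field hypolocomotion, tail-flick
analgesia, rectal hypothermia), and what intraperitoneal (i.p.) dose
would have produced the same response.  Because the underlying animal
data live in an external repository, the package ships a synthetic
cohort generator that reproduces the statistical structure of such a
study; every analysis stage is exercised and validated against it.

## Dose-response model

All triad dose-response curves use the Hill-slope-1 three-parameter Emax
form on a linear dose axis,

    y(d) = B + (T − B) · d / (d + ED50),

with Bottom `B` the vehicle response, Top `T` the asymptote and `ED50`
the half-maximal dose in mg/kg.  This form is defined at d = 0, so the
vehicle group anchors the fit directly.  Depressant responses
(hypolocomotion, hypothermia) are fitted on signed difference scores
with `T < B`; no magnitude transform is applied.  An equivalent
formulation fits the log-logistic model on log-dose with a vehicle
offset; the two agree wherever both are defined, and nothing downstream
depends on the choice because inversion round-trips through the same
fitted curve.

Fitting profiles the ED50 on a 60-point log grid spanning
[smallest positive dose / 10, largest dose × 10]; for each candidate
ED50 the model is linear in `(B, T)`, which are solved by ordinary least
squares.  The best grid candidate (ties to the smaller ED50) seeds a
Levenberg–Marquardt refinement over `(B, T, log ED50)`.  A fit is
flagged non-converged when the refinement fails or the span `|T − B|` is
indistinguishable from zero (constant responses); flagged fits are
refused by `ed50()` and `invert_emax()`.  When the largest tested dose
is below 2·ED50 the response never approached its plateau; the fit is
returned anyway with `plateau_reached=False`, and its Top is treated as
an extrapolated asymptote.

## Inverse dose prediction

The cross-route dose-equivalence model maps an oral-consumption group's
mean response onto the fitted i.p. reference curve:

    d* = ED50 · (y_obs − B) / (T − y_obs).

Per-behavior predicted doses are aggregated as their arithmetic mean
with an across-behavior SEM (sample SD / √k over the k = 3 behaviors);
this across-behavior spread is deliberately distinct from the
per-behavior bootstrap uncertainty available through
`bootstrap_predicted_dose` (resample animals, refit, re-invert).
Responses outside the open interval (B, T) have no finite dose and fail
loudly; silent clamping is never applied because non-plateauing curves
make extrapolated doses misleading.  By default the predicted dose may
not exceed the largest tested i.p. dose; `allow_extrapolation` relaxes
the cap to twice that dose.  The aggregate predicted dose is propagated
through the sex-specific 120 dB startle quadratic
`V_max(d) = a0 + a1·d + a2·d²` (fitted to per-dose group means, vehicle
included as dose 0) and compared to the measured oral startle group:
the verdict is `within_sem` iff |predicted − measured mean| ≤ measured
SEM.

## Consumption dosimetry

Grams eaten are cup mass before minus after access; apparent gains up to
0.05 g (drying-scale noise) clamp to zero and larger gains are data
errors.  With gelatin density fixed at 1 g/ml, a gel labelled X mg THC
per 15 ml delivers `grams · X/15` mg THC, normalized by body mass to
mg/kg.  Time-binned cumulative series are summarized by two mean rates
around a fixed 40-min changepoint (the observed plateau onset); the
changepoint is a configuration parameter, not estimated, and the
percent reduction is 100·(r1 − r2)/r1, undefined (flagged) when the
early rate is zero.  Animals with consumption at or below 0.00 g at
0.01 g scale resolution count as non-consumers.  Per-animal rates are
computed first and then averaged; whether published group rates are
per-animal means or pooled slopes is ambiguous, and this choice is
recorded here.

## Statistics core

SEM, one-way and two-way ANOVA, the Sidak adjustment
`1 − (1 − p)^m` (computed as `-expm1(m·log1p(−p))` for small p) and the
regression F test are implemented directly from sums of squares; scipy
supplies only the F-distribution tail probability.  Repeated-measures
designs are handled as a subject-blocked split-plot: subjects nested in
the between factor are the error stratum for that factor, while the
within factor and interaction are tested against the residual.  Only
balanced complete designs are supported; unbalanced Type-II/III
machinery is out of scope.  Zero effect sums of squares report F = 0,
p = 1; p-values below 1e-15 display as "<1e-15".

## Synthetic cohort generator

The generator's defaults are the study conditions the analyses assume:

- **Triad Emax parameters.** ED50s 1.3 (hypolocomotion), 3.9
  (analgesia), 14.4 mg/kg (hypothermia).  Published data give no
  asymptotes, so Tops are calibrated: −4000 cm (open-field distance over
  15 min), +6 s (tail-flick latency), and −8.64 °C, the last chosen so
  the hypothermia curve passes through −5.84 °C at 30 mg/kg i.p.
  Noise is additive Gaussian on the difference-score scale with
  per-assay SDs defaulting to ~20% of the span.
- **Consumption.** Two separately calibrated pathways mirror the two
  experimental cohorts: total-mass dosimetry draws each animal's
  consumed dose from a lognormal with group mean 29.2 mg/kg (10 mg/15 ml
  E-gel, 2 hr access; CV 0.30), while the 10-min time course uses
  piecewise-linear rates (13.0 → 4.2 mg/min for THC gel, 16.3 → 9.9 for
  vehicle, changepoint 40 min) scaled by a per-animal lognormal
  multiplier.  The printed rate profile integrates to ≈0.86 g whereas
  the printed total consumption is ≈1.0 g; the two figures come from
  different cohorts, so the generator honors each anchor on its own
  pathway rather than forcing a joint fit.
- **Oral-equivalent doses.** Each voluntary-access arm carries the i.p.
  dose producing the same mean triad response (3.7 mg/kg for 2 hr
  access, 8.8 mg/kg for 1 hr); oral triad responses are generated from
  the i.p. curves at that dose, which is exactly the assumption the
  inverse-prediction model tests.
- **Startle.** Sex-specific 120 dB quadratics pass through the anchor
  responses 1733/558 cm/min (males) and 688/310 cm/min (females) at 3.7
  and 8.8 mg/kg, plus a small positive response at 10 mg/kg so the mean
  stays physical across the tested range; the male curve is an inverted
  U (vertex ≈2.5 mg/kg), the female curve declines monotonically.  The
  vehicle intercepts are otherwise unconstrained calibration choices.
  Lower tones are scaled-down copies of the 120 dB mean (null 0.02
  through 110 dB 0.60); noise is additive and individual V_max values
  clip at 0.
- **Pharmacokinetics.** A one-compartment first-order oral absorption
  model with a sequential metabolite chain (gut → THC → 11-OH-THC →
  11-COOH-THC), solved exactly with the matrix exponential.  Rates
  (ka = 1.5/hr; THC loss 0.15/hr; metabolite turnover 0.7–0.95/hr) and
  level multipliers are calibrated — not fitted — so that at the 29.2
  mg/kg mean dose brain THC sits in 500–600 pmol/g across the 1–2.5 hr
  collection window and falls below 50 pmol/g by 26 hr, with metabolite
  peaks at or after the parent peak.  The chain is a range-reproducing
  device: no kinetic claims are made, and the PK and behavioral streams
  are generated independently (no pharmacodynamic linkage and no
  within-session tolerance).
- **Animals.** Body mass Normal(25 g, 2 g) truncated at 18 g, typical of
  adult C57BL/6J; sexes alternate within groups.  Sex enters the model
  only through the startle quadratics; triad and consumption parameters
  are shared across sexes.

All randomness flows from a single integer seed; identical
(config, seed) pairs produce byte-identical tables.

What the generator does *not* emulate: day-to-day aversive memory,
within-session response dynamics, PK-behavior coupling, per-animal
correlation between consumed dose and triad response in the oral arms,
and tail-flick cutoff censoring.  Passing tests therefore demonstrate
that the analysis pipeline recovers known structure under realistic
noise, not that real data satisfy these simplifications.

## Validation suites and problem sizes

- Noise-free round trips (Emax fit ↔ inversion, startle quadratic
  refit, piecewise rates) hold to 1e-9/1e-6 relative error.
- Stochastic recovery uses cohorts of 10 animals per dose over the
  8-level i.p. design with proportional noise at CV 20% (SD = 20% of
  the mean response at each dose); over 200 replicates the median
  absolute ED50 error stays within 25% and the median end-to-end
  predicted dose within 20% of truth.  These sizes keep the full suite
  in the tens of seconds while leaving the medians stable to well under
  the tolerance.
- Type-I error of the ANOVA and regression F tests is checked at 1000
  Gaussian-null replicates against a three-sigma binomial band around
  0.05.
- SEM/ANOVA/regression outputs match brute-force sums-of-squares
  oracles to 1e-10, and scipy/statsmodels serve as independent
  cross-checks in tests only.

## Known limitations

Degenerate designs (fewer than three distinct doses, singleton ANOVA
groups, constant predictors) are rejected rather than approximated.
The two-way ANOVA supports balanced complete designs only.  The
hypothermia design (largest dose ≈ 2×ED50) is weakly identifiable:
single noisy cohorts can misestimate its ED50 by 30–50%, which is why
recovery claims are stated as medians over replicates.  Inversion uses
group-mean oral responses; per-animal inversion exists only through the
bootstrap helper.
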