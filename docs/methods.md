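# Methods

## Model

The unit of analysis is the stratum: population × sex × education
(low/mid/high) × age group (30–44, 45–59, 60–69, 70–79). Registry
mortality (deaths `D`, person-years `PY`) is treated as fixed; survey
prevalences `P_i` over the categories of one risk factor are treated as
multinomial estimates with known sampling base `survey_n`; relative risks
`RR_i` (reference category 1) are external meta-analytic constants shared
across populations and education groups.

For a counterfactual distribution `P′` over the same categories,

    PAF = (Σ P_i RR_i − Σ P′_i RR_i) / Σ P_i RR_i .

This is exact — the avoided-death fraction, not an approximation — when
the stratum hazard factorises as `h × Σ P_i RR_i` (multiplicative risk,
no confounding within stratum, immediate and complete reversibility of
exposure effects). Those assumptions are inherited by everything
downstream and are the main caveat on causal readings of the output.

Aggregation over age is two-step: age-specific PAFs give age-specific
saved deaths `PAF_a · D_a` and counterfactual rates `rate_a (1 − PAF_a)`;
the overall PAF of an education group is `Σ_a PAF_a D_a / Σ_a D_a`.
Saved deaths stay real-valued throughout; rounding happens only in
reports.

Inequality metrics are computed from directly age-standardised rates
(per 100,000 person-years): `RD = rate_low − rate_high`,
`RR = rate_low / rate_high`. A scenario's impact is `ΔRD = RD_obs − RD_cf`
and the relative reduction `100 (RR_obs − RR_cf)/(RR_obs − 1)` — the
percentage of the excess rate ratio removed, which is the only relative
metric equal to 100% exactly when upward levelling removes all excess
risk. It is undefined (reported `na`) when `RR_obs = 1`, and
ill-conditioned near it.

**Standardisation weights.** Default: each population's own all-education
person-years distribution over the four age groups, per sex. No external
standard is imposed because none is canonical for this four-band 30–79
design; an explicit 4-vector can be passed instead (`weights=`). Reported
RD/RR values depend on this choice; the scenario *logic* does not.

## Scenarios and zero rules

**Upward levelling.** Low and mid strata receive the high-educated
distribution of the same population × sex × age. The high stratum is
never altered, so `ΔRD` equals the weighted low-educated rate drop
exactly. Zero rule: when the low educated are already the more favourable
group (the deaths-weighted overall PAF of levelling them up is negative),
the reported reductions (PAF_low, ΔRD, relative reduction) are set to
exactly 0 and the row is flagged `clamped`. The rule is applied per
population × sex (not per age group), and reported reductions are floored
at 0 component-wise, so levelling never widens reported inequality.
Clamping acts on *reported values only*; raw values are kept in
`*_unclamped` columns and the underlying distributions are never mutated.

**Best practice.** The target's low, mid and high strata receive the
donor's corresponding distributions (the defining groups are low and
high; giving mid the donor's mid keeps the counterfactual internally
consistent and does not affect the reported low-vs-high metrics). The
donor is selected per sex × risk factor as the population with the
smallest low-educated upward-levelling overall PAF among *eligible*
populations. Eligibility: the candidate's high-educated RR-weighted
exposure `Σ P_i RR_i` (unweighted mean over age groups) must not exceed
the cross-population median — a small inequality must come from low
exposure among the low educated, not high exposure among the high
educated. The median cutoff is a documented operationalisation (no
numeric criterion is canonical); explicit donor overrides per
factor × sex are accepted in the config. Ties break lexicographically on
population id, making selection deterministic. Zero rule: when the
donor's high-educated distribution is less favourable than the target's
(deaths-weighted PAF of the target's high group under the donor
distribution is negative), reported reductions are exactly 0. Otherwise
negative reductions — inequality widening because the target's gradient
is smaller than the donor's — are reported as negative.

Missingness is recorded at population × sex × risk-factor level
(matching how survey availability actually fails); partially present
strata are rejected at load. Missing cells propagate as `na`, never as 0.
Populations whose economic-inactivity definition differs (e.g. unemployed
counted as inactive) are handled by giving the variant its own
risk-factor id with its own RR rows, not by a flag.

## Bootstrap

Parametric, prevalence-only: mortality is registry data and RR
uncertainty is not propagated (no per-category CIs are available at the
granularity used). Each replicate redraws every involved stratum's
category counts as Multinomial(`survey_n`, `P`) per age group,
renormalises, rebuilds the counterfactual (under best practice the
donor's strata are redrawn too) and recomputes the low-educated overall
PAF. The scenario's zero rule is applied *within* each replicate
(default on), which is what produces interval lower bounds of exactly
0.0 for clamped or borderline cases. Intervals are percentile
(2.5/97.5 at the default 95% level), `B = 1000` by default — standard
choices, as no canonical values exist for this design. The interval is
widened to include the point estimate in the rare event a percentile
falls inside it; a warning is emitted when `B · (1 − level)/2 < 1`.

## Synthetic data generator

Emulates the study design the model targets: four age bands with
Gompertz-like increasing hazards (defaults 0.002/0.006/0.018/0.045 per
person-year for men, ×0.55 for women), education multipliers for residual
mortality (1.4/1.15/1.0), person-years decreasing with age
(400k/350k/250k/150k per stratum), six risk factors with field-typical
category schemes and RRs (current smoking 2.0, former 1.3; BMI 30+ 1.35;
sedentary 1.3; no participation 1.25; income quartiles up to 1.5;
economically inactive 1.6), and a survey base of ~2000 per stratum. The
education gradient moves probability mass from the reference to the
highest-RR category; it scales across populations (linspace 0.45–1.35),
shrinks with age (tilt 1.15/1.0/0.9/0.8), is damped for women (×0.75)
and can be sign-flipped per (population, sex, factor) to create
reverse-gradient fixtures. Because stratum rates are exactly
`h_a · m_e · Σ P_i RR_i`, every estimand (PAFs, ΔRD, relative reductions,
donor identity, clamp flags) has a closed form, computed independently of
the engine. With multiple factors, the mortality table is anchored to the
first configured factor; truths for the other factors use that same
mortality (one registry, many surveys — as in real data).

Noise modes: `none` (expectations everywhere; the pipeline must
reproduce truth to float accuracy — observed worst deviation ~5e-12,
dominated by the relative-reduction metric's `1/(RR_obs−1)`
amplification), `deaths` (Poisson death counts), `survey` (multinomial
prevalences), `poisson` (both). The generator does not emulate:
harmonisation error across surveys, confounded or education-dependent
RRs, exposure measurement error, lag between exposure and death, or
correlation between risk factors. Passing tests therefore demonstrate
correctness of the computation under the model's own assumptions, not
robustness of the substantive conclusions to their violation.

## Validation experiment sizes

Chosen as the smallest sizes at which the Monte-Carlo checks are stable:
100 randomised parameter draws for the noise-free identity; 200
replicates at 10^6 person-years per stratum for parameter recovery
(≥95% of estimates within 3 empirical SEs of truth); 200 survey-noise
replicates at `survey_n = 500` with `B = 500` for bootstrap coverage
(observed ~94–95% against a 90% floor); 5 seeds × B = 300–400 for the
interval-width monotonicity check.

## Numerical conventions

* Proportions must sum to 1 within 1e-6 on input (printed survey tables
  are rounded) and are renormalised to exactly 1 afterwards.
* Reference RR must equal 1 within 1e-9 and is snapped to exactly 1.
* Report rounding is decimal half-up (67.5 → 68), matching published
  table conventions; PAFs to 1 decimal in %, ΔRD to whole deaths per
  100,000. Medians are taken over non-`na`, non-`ref` populations; an
  even count averages the two central values.
* Impact bands are lower-inclusive: PAF <3 / [3,10) / ≥10 %; ΔRD
  <20 / [20,80) / ≥80 deaths per 100,000. Negative values fall in the
  lowest band.
* Degenerate inputs: zero total deaths make the overall PAF an error;
  zero-death single age groups simply carry no weight; `PAF ≥ 1` is
  rejected (non-positive counterfactual deaths); a missing high-educated
  stratum makes the whole population × sex cell `na`.

## Known limitations

Single-factor scenarios only: joint multi-factor counterfactuals require
an independence assumption that does not hold between nested factors
(e.g. smoking within low income) and are deliberately out of scope, as
are cause-specific mortality, time-lagged exposure scenarios and
estimation of the relative risks themselves (they are inputs). The
age-standardisation standard affects RD/RR levels; comparisons across
populations should fix one standard. Mid-vs-high contrasts are computed
but not tabulated in reports.
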