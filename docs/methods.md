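# Methods

## Model structure and assumptions

The package models a stationary, endothermic honeybee forager in
thermal steady state: metabolic heat production plus radiative gain
equals radiative, convective and evaporative loss. Conduction (only via
the leg tips) is neglected everywhere. Solving the balance for
metabolism gives

    M = r_l · R_loss − r_g · R_gain + E_cv + e_lev · E_ev   [W]

where `r_l`, `r_g`, `e_lev` and the convection coefficients inside
`E_cv` are fitted, not derived: they absorb everything the mechanistic
terms cannot capture (respiratory convection, posture- and
hair-dependent absorptivity, physiological regulation). Negative fitted
coefficients are accepted without warning — a negative abdomen
convection coefficient, for instance, means the abdomen on average
receives more heat (from the thorax via haemolymph and respiration,
and from the sun) than it loses to the air.

Temperatures are degC at every interface; the Kelvin shift (+273.15)
is internal and exact. Power is W internally and mW at user-facing
surfaces — the single most dangerous unit boundary in this model, which
is why file columns embed their units (`T_a_C`, `G_Wm2`, `M_mW`).

### Radiation

Loss is grey-body emission `ε_b σ T_b⁴ A_b` with `T_b` the unweighted
mean of the three part surface temperatures (no area weighting). Gain
splits into long-wave IR and solar parts, each acting on half the body
surface. How the original IR fluxes were computed is not documented, so
the package adopts an explicit closure: the surroundings are a
blackbody at an explicit surround temperature (default: ambient air),
giving `R_gIR = α_bIR σ T_surround⁴ A_b` with reflected IR zero (the
measurement-chamber paint is nearly black in the IR). The surround
temperature is a parameter, so other closures can be expressed. The
shipped coefficient presets are only guaranteed meaningful under a
closure consistent with the one used when they were fitted; this is an
irreducible caveat of undeposited data. Solar gain is
`α_bSOL G A_b/2` with an optional reflected term
`α_bSOL (1 − α_paint) G A_b/2` for sensitivity analysis (off by
default). `α_bSOL = 0.825` is used as given; the cosine-law edge
correction behind it is not re-derived.

### Geometry

Thorax: sphere (`A = π d²`). Head: oblate rotational ellipsoid,
`2πa²(1 + ((1−e²)/e) atanh e)`. Abdomen: prolate rotational ellipsoid,
`2πb²(1 + (a/(be)) asin e)`. Both formulas are continuous at the
sphere limit and verified against surface-of-revolution quadrature to
1e-9 relative error. Triaxial ellipsoids, wings and legs are out of
scope. The published part areas (30.80 / 47.78 / 85.91 mm²) ship as
the default preset; note the published total (163.7 mm²) differs from
the part sum (164.49 mm²) by 0.79 mm² — both values are carried,
selectable via `body_surface(total=...)`, and neither is silently
corrected. The full original dimension set is unpublished, so
`REFERENCE_DIMENSIONS` is a reconstruction: the thorax diameter is
exactly determined by its area; for head and abdomen one axis was fixed
at a plausible forager value (head width 3.5 mm, abdomen length
6.4 mm) and the other solved numerically.

## Fitting

Every variant is exactly linear in its coefficients, so the design
matrix has one column per coefficient: the radiative-loss flux (for
`r_l`), the negated radiative gain (for `r_g`), the constant `E_ev`
(for `e_lev`, effectively the model's intercept) and the convection
regressors. Two routes to the optimum are implemented deliberately:

* `fit_linear` — QR/SVD-based OLS, the exact closed form;
* `fit_iterative` — Levenberg–Marquardt with adaptive damping,
  converging when an accepted step changes reduced χ² (RSS/df) by less
  than 1e-9, followed by one undamped Gauss–Newton polish step (the
  damping goes to zero near the optimum). Initialization is all-ones;
  multiple starts are pointless for a convex problem. Iteration cap
  1000, reported via `converged`/`n_iterations`.

Their agreement (relative 1e-6) is asserted in the test suite; the
linearity also implies the per-part and three-compartment
parameterizations span the same column space (`T_th − T_hd` is a fixed
linear combination of the part-excess regressors), so those variant
pairs must produce identical residual vectors — another structural
check the suite enforces. Coefficients are always fitted jointly; they
are not interpretable in isolation.

Statistics follow the conventions of the published tables:
`SD_res = sqrt(RSS/df)` with `df = N − k` (the df denominator is
indistinguishable from the N denominator at N = 872 at the printed
precision), `SEM_res = SD_res/√N`, `adj R² = 1 − (RSS/df)/(TSS/(N−1))`
with TSS about the response mean, two-sided `P >|t|` from the t
distribution with df degrees of freedom, no multiple-testing
correction. The overall F statistic uses the uncentered no-intercept
ANOVA convention `F = ((Σy² − RSS)/k)/(RSS/df)`; statistics packages
disagree on F conventions for models without an intercept, so F values
are not comparable across software. Rank deficiency (e.g. a
constant-`T_a` dataset, which makes every intercept/slope column pair
proportional) is detected from the scaled singular values and reported
with the names of the involved columns. Shade and sun visits are
fitted pooled by default; per-condition fitting is available by
subsetting the input, not a separate mode.

## Synthetic data generator

The generator emulates the documented structure of the original
872-visit field campaign; the documented facts are the ranges and
summary statistics only, so every distributional choice is an invention
and a config knob:

* ambient temperature uniform on 14.8–37.5 °C;
* global radiation from a shade band (uniform 3.4–100 W m⁻²) or a sun
  band (uniform 100–921 W m⁻²), sun probability 0.5; the shade/sun
  label uses the strict 100 W m⁻² threshold everywhere;
* thorax temperature from a linear response surface
  `T_th = 31.0 + 0.26·T_a + 0.0028·G` plus Gaussian jitter
  (SD 2.6 °C), truncated to 33.3–45 °C by resampling;
* head and abdomen temperatures placed between ambient and thorax at
  uniform warming fractions (head 0.45–0.95, abdomen 0.05–0.45 of the
  thorax excess), enforcing the default ordering
  `T_a ≤ T_ab ≤ T_hd ≤ T_th` (the thorax is the heat source; the
  abdomen tracks ambient most closely);
* metabolism from the model itself (preset `table2a`) plus Gaussian
  residual noise (SD 5.78 mW), constrained to 4–85 mW by
  rejection-and-redraw of the whole row (body-temperature jitter
  included), which keeps the noise model honest near the range edges;
  the generator errors out if the first-pass rejection rate exceeds
  50%.

The response-surface slopes, jitter SD and warming fractions were
calibrated once, by a coarse grid search, so the generated energy
turnover reproduces the documented SD of ≈ 17.59 mW stably across
seeds (observed 17.67 ± 0.08 mW over five seeds, ≈ 9% rejections);
they are fixed defaults, not tuning targets. Per-condition sample
sizes of the original campaign are unknown, so the three feeding
regimes are mixed evenly and carry no distributional differences —
the condition column is a label, not a mechanism. Consequences for
interpretation: passing tests show that the pipeline recovers known
coefficients from data with the documented first and second moments;
they cannot show that the shipped presets are optimal for real bees,
nor reproduce the real data's condition-specific conductance
differences or sun-heated-abdomen exceptions (the ordering constraint
can be relaxed via the warming-fraction ranges).

## Numerical choices and degenerate inputs

* Ellipsoid formulas switch to the exact sphere expression at zero
  eccentricity; elsewhere the closed forms are numerically stable.
* Absolute zero: radiative fluxes accept −273.15 °C (zero flux) but
  reject anything below; Wien's law rejects −273.15 °C itself.
* Conductance `M/(T_b − T_a)` reports NaN at zero excess rather than
  raising — a zero-excess visit is data, not a programming error.
* Design-matrix rank tolerance: smallest scaled singular value below
  1e-10 of the largest.
* The default problem sizes used by the tests and the acceptance
  script (N = 872, 100 recovery replicates) match the original
  campaign size and keep the full suite in the low minutes on one
  core.

## Known limitations

Steady state only — no transient heating/cooling dynamics. Stationary
bees only — free flight changes the convection regime and needs its
own coefficient set. The presets were transcribed from flattened
published tables that contain apparent transposition ambiguities
(three different `e_lev` values appear across model variants that
should share them; one equals another table's `b_hhd`); the values are
entered exactly as printed and each preset carries a `caveat` field
flagging this. F values from other software will not match (see
above). The generator's evenly-mixed conditions and enforced
temperature ordering are simplifications of the real campaign.
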