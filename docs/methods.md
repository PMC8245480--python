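# Methods

This note documents the models, parameter choices, numerical conventions
and limitations behind each `seepflux` stage. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coupon dissolution rates

**Geometry.** A coupon's surface area is estimated from its mass, its
known diameter, and the aragonite density (2.93 g cm⁻³), treating the
coupon as a closed right cylinder: volume V = m/ρ, thickness t = V/(πr²),
area A = 2πr² + 2πrt. The cylinder is the natural model for a cored disk
cut to 1–3 mm; no closed-form alternative is plausible for this machining.
An implied thickness exceeding the diameter triggers a warning (the result
is still returned) since it indicates a unit error or a non-coupon mass.

**Which mass sets the area.** The before/after masses differ by the
dissolved mass, so the area is ambiguous up to that choice. The default is
the *mean* of initial and final mass — the symmetric choice — with
`initial` and `final` available via `mass_for_area`. For realistic losses
(≲10 mg on ~750 mg) the three differ by ≲0.3% in area.

**Rate regression.** Areal amounts (μmol CaCO₃ cm⁻², via the molar mass
100.0869 g mol⁻¹) are regressed against hours in the reactor by ordinary
least squares with a *free intercept*: a batch-phase attachment period can
offset the series without changing its slope. Forced-origin regression is
available (`force_origin=True`). The annual rate is slope × 8760 h yr⁻¹
exactly (never 8766 or 365.25 × 24), and the reported ± is the annualized
standard error of the slope. Other readings of a printed ± (dispersion of
time-point means, etc.) are possible; the slope s.e. is the one exposed
because it is the regression-native uncertainty and reproduces the
published relative uncertainty (~18%) under the published design.

**Negative mass loss** (a coupon gaining mass) is flagged and retained,
not excluded: no exclusion rule is defensible without knowing its cause,
and OLS handles the points symmetrically.

## Biofilm pH imaging

**Ratio image.** R = (I₄₈₈ − b₄₈₈)/(I₅₆₁ − b₅₆₁) per voxel, with scalar
per-channel backgrounds (supplied by the user or taken from a designated
background region). Voxels whose background-subtracted numerator or
denominator is ≤ 0 are masked (NaN) rather than clipped; masking is never
undone downstream.

**Calibration.** The titration curve is fit with the standard single-pKa
sigmoid for ratiometric fluorophores,
R(pH) = R_min + (R_max − R_min)/(1 + 10^(pKa − pH)),
by nonlinear least squares (trust-region, seeded from the data's span and
median pH). Its inverse is analytic — pH = pKa + log₁₀((R − R_min)/(R_max
− R)) — so the round-trip is exact to floating point; the test suite
asserts < 1e-10 across the calibrated range. A monotone piecewise-linear
interpolator is available (`form="linear"`) when the sigmoid is a poor
fit. Ratios outside (R_min, R_max) are errors by default; `clamp=True`
pulls them just inside the open interval, an explicit opt-in so pH values
are never silently invented. The default calibration design uses the
flow-cell titration set (pH 8.0, 7.8, 7.7, 7.55, 7.2, 7.0, 6.8), the set
acquired under the same optics as the experimental stacks.

**Kymographs.** A band (default width 13 μm) along a user-defined line is
averaged per z plane; averaging acts on the *ratio image* (matching the
practice of drawing kymographs on ratio images), with intensity-first
averaging as an option — the two agree exactly on noiseless data and
differ only at second order in the noise. z = 0 is the substratum (the
mineral surface), increasing toward the bulk; voxel centers are at 0-based
index × voxel size. A plane whose band is entirely masked yields a missing
value; the profile is still returned.

## Seafloor coverage

**Scale model.** With two 10 cm bars at rows x₁ (background) and x₂
(foreground), the cm/px scale at row x is y₁ + m(x − x₁) with
y_i = 10/(bar length in px) and m = (y₂ − y₁)/(x₂ − x₁). Models whose
scale is ≤ 0 anywhere inside the image are rejected.

**Area measurement.** A pixel's footprint is scale(row)² cm² — the square
of the linear per-row scale, the only dimensionally correct reading of a
per-row scale applied to areas. A polygon's area is the sum of footprints
over pixels whose *center* lies inside it (even-odd rule), with boundary
ties broken toward inclusion on top/left edges via an infinitesimal
down-right shift of the test point. Pixel (row r, col c) has its center at
continuous (x=c, y=r); an axis-aligned rectangle covering whole pixels
therefore spans half-integer coordinates. The pixel sum converges to the
analytic integral ∬ s(y)² dA as features grow; the suite verifies ≤ 1%
at ≥ 50 px features, and the analytic oracle (exact Gauss–Legendre
integration over vertex-row intervals, where the integrand is cubic) lives
in `seepflux.synthetic.polygon_weighted_area_exact`.

**Coverage.** Rock ROIs are unioned before measurement (overlaps are not
double-counted) and clipped to the total-visible ROI, so
mat ≤ rock ≤ total holds by construction. Each negative (mat-free) ROI
must be contained in the rock region; mat area = rock area − negative
area. Working resolution is whatever the model was fitted in; 1333 × 750
is the conventional survey-photo size and the default image extent.

## Flux upscaling

Site flux = rate (mol m⁻² yr⁻¹ = μmol cm⁻² yr⁻¹ × 10⁻²) × rock area × mat
fraction (default 0.9277, the mean mat coverage of exposed carbonates in
ground-truth imagery). Since the flux is linear in the rate,
flux ± = flux × (rate s.e./rate).

**Global uncertainty rule.** The global estimate is mean(site fluxes) ×
n_seeps (default 10,000). Its ± is the *mean of the per-site ±* scaled by
n_seeps — the rule that reproduces the published ±1×10¹⁰ mol C yr⁻¹ and
the 1.38–11.92% lability range exactly; quadrature combination is
available via `se_rule="quadrature"` (it is ~2.2× smaller and treats the
per-site errors as independent, which they are not, since they share one
rate). The lability range pairs (flux − se) with the high precipitation
bound (3.6 Tmol yr⁻¹) and (flux + se) with the low bound (0.6), the
extreme-ratio construction. Carbon mass uses 12.011 g mol⁻¹ (1 mol CaCO₃ ≡
1 mol C).

**A documented inconsistency.** For Santa Monica Basin the published
per-site flux (6.84×10⁶ mol yr⁻¹) does not equal rate × rock area × mat
fraction (≈ 6.48×10⁶), while its published ± (1.19×10⁶) *does* equal the
recomputed flux × the rate's relative s.e. — consistent with a
transcription error confined to the flux column. The packaged table ships
the published values verbatim; the package recomputes 6.48×10⁶ and the
test suite asserts the discrepancy rather than silently "correcting"
either number. The global chain uses the published fluxes as inputs, which
is what the published global value is built from.

## Synthetic data

The generators are pure functions of (spec, seed) — byte-identical reruns
— and always return ground truth alongside the data (in sidecar files when
written to disk, never embedded in the data files).

**Coupon experiments** follow the real design: 6 harvests at 96 h
intervals over 21 days, 2 weighed coupons per harvest, initial masses
uniform on 400–1100 mg (the mass range of 12.7 mm aragonite disks cut to
1–3 mm). The forward model converts the target areal loss back to a mass
loss through the coupon's pre-dissolution surface area (the analysis
default uses the mean-mass area; the resulting bias is ≈0.1% of the rate,
negligible against the estimator's spread). Final-mass noise is Gaussian
with sd 7 mg, the value that closed-form OLS error propagation
(sd_areal/(slope·√Sxx), Sxx = 322,560 h² for this schedule) maps to the
~18% relative standard error of the measured thiosulfate rate.

**pH stacks** prescribe a laterally uniform depth profile through control
points (0 μm, 7.65), (30 μm, 7.33), (80 μm, 7.76) — mineral-surface,
mid-biofilm minimum, bulk-ward recovery — interpolated by a
shape-preserving (PCHIP) cubic, constant beyond 80 μm. The 561 nm channel
is a flat reference intensity (1000 AU), the 488 nm channel is the
reference times the calibration ratio; both get multiplicative Gaussian
noise (default CV 2%, switchable to scaled-Poisson) plus scalar
backgrounds (100 AU). Default stack 40×64×128 voxels at (4, 4, 2.5) μm
gives a 500 μm kymograph line and a 100 μm depth range at modest memory.
What this does *not* emulate: real optics (PSF blur, depth attenuation,
bleaching), lateral biofilm structure, or dye-binding heterogeneity —
recovery tests therefore validate the estimator chain, not the microscope.

**Seafloor scenes** emit scale bars whose pixel lengths are exactly
true_length/scale(bar row) under a chosen linear model, plus rectangular
ROIs aligned to whole pixels so their weighted areas have a closed form
(row sum of s(r)²). Irregular-polygon accuracy is tested against the
continuous analytic integral instead.

## Problem sizes and tolerances

The default test run uses 100 coupon-experiment replicates, 20 pH stacks
at 2% noise (40×64×128 voxels), and 20 randomized coverage scenes — sizes
chosen so the whole suite completes in well under a minute while the
recovery statistics are stable to the asserted tolerances (rate bias
within 2 s.e. of the replicate mean; profile RMS ≤ 0.05 pH; area error
≤ 1% at ≥ 50 px). Printed-table comparisons round both sides to 3
significant figures, the precision of the published tables.

## Known limitations

- The coupon area model ignores edge scoring and surface roughness; rates
  are therefore referenced to geometric, not true, surface area.
- Scalar per-channel backgrounds; no per-plane background estimation.
- The perspective model is linear in the row only — no lens distortion,
  no horizontal foreshortening; ROIs partially occluded by fauna/shadows
  are the user's responsibility.
- The global extrapolation inherits every caveat of its inputs: six mapped
  sites, one mat-coverage figure applied to all, an order-of-magnitude
  seep count, and a single laboratory dissolution rate.
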