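# Methods

This note documents the statistical and physical models implemented in
cytodose, the defaults and why they were chosen, the numerical details,
and what the synthetic-data validation does and does not demonstrate.

## Aberration-distribution statistics

A dose point is a dense vector `counts[k]` = cells with exactly *k*
aberrations (k = 0..k_max, trailing zeros allowed). Summaries use exact
closed forms over the count vector; they are identical (to 1e-12, and
tested so) to brute-force computation on the expanded per-cell list.

* Yield ȳ = x/n (x = Σ k·counts[k], n = Σ counts[k]).
* Sample variance with denominator (n − 1). This choice is required to
  reproduce published dispersion indices and is the standard estimator.
* Dispersion index d = σ²/ȳ; undefined (NaN, flagged) when x = 0 —
  never fabricated.
* Papworth u = (d − 1)·sqrt((n − 1)/(2(1 − 1/x))), computed from the
  unrounded d. Asymptotically standard normal under Poisson; the 1.96
  two-sided 5% critical value flags overdispersion. u is undefined for
  x ≤ 1 (the 1 − 1/x factor degenerates) and n < 2.
* The "± SD" quoted on the aberration total is the Poisson value
  sqrt(x), rounded once to an integer for display. Published tables of
  this kind occasionally carry a double-rounded integer (x.45–x.47
  rounded up); the unrounded sqrt(x) is the defined quantity here.

Pooling across donors sums count vectors component-wise and is refused
across different doses or assays, since the multiplicity distribution is
only homogeneous within one exposure condition.

## Dose-response fitting

Counts x_i at dose D_i over n_i cells are modelled x_i ~
Poisson(n_i·A(D_i)) with A(D) = c + αD (+ βD²), D in Gy. mGy is the
unit at every I/O boundary; conversion happens once, entering the fit.

The maximizer is iteratively reweighted least squares on yields with
weights n_i/Â_i — the Fisher-scoring iteration of the identity-link
Poisson GLM with cell-number exposure, i.e. the fitting scheme of the
standard cytogenetic-dosimetry software. Numerical details:

* Start: ordinary least squares on the yields. If the OLS plane is
  infeasible (a non-positive fitted yield at a data point — common when
  the unirradiated point has zero aberrations), restart from
  non-negative least squares with the intercept floored at 1e-8.
* Fitted means are floored at 1e-9 inside the weights; steps that would
  drive a fitted data-point mean non-positive are halved (≤ 30 times).
* Convergence: per-coefficient step below max(1e-8·|coef|, 1e-12).
  The absolute floor matters when c converges to the zero boundary —
  a pure relative criterion never terminates there. Cap 100 iterations,
  then an explicit failure carrying the last iterate.
* Covariance = inverse observed (= expected, for this model) information
  at the optimum; intercept c is freely fitted, not clamped.

Diagnostics: Pearson χ² = Σ n_i(ȳ_i − Â_i)²/Â_i with dof = points −
parameters and upper-tail p (flagged non-computable when dof ≤ 0);
Pearson R² between observed and fitted yields; two-sided normal z-tests
for the coefficients. Coefficient comparisons between radiation
qualities use z = |a₁ − a₂|/sqrt(se₁² + se₂²), two-sided, reported as a
magnitude.

Curve inversion (the enabling step for iso-effect RBE) uses the closed
forms D = (A − c)/α and the positive quadratic root; the round trip
invert(evaluate(D)) = D is exact to 1e-10 and property-tested.

Note on reported SEs: they are model-based (Poisson). When the data are
overdispersed the true sampling variance of α̂ is inflated by roughly
the dispersion index; see the validation section for the measured
consequence. No quasi-Poisson scale factor is applied, matching the
convention of the reference software (whose published SEs this
reproduces).

## RBE

All ratios use first-order (delta-method) error propagation with
independent numerator/denominator estimates:

* RBE_M = α_n/α_ref, SE = value·sqrt((se_n/α_n)² + (se_ref/α_ref)²).
* Dose-specific RBE = D_ref(A_n)/D_n with D_ref by curve inversion. The
  SE propagates the reference-curve coefficient covariance through the
  inversion by implicit differentiation: dD/dθ = −(1, D, D²)/(α + 2βD).
  Uncertainty in the measured neutron yield is excluded by default
  (opt-in flag), since quoted dose-specific RBEs are conventionally
  printed without it.
* (n,p)-only RBE_M: α_np = (α_n − (1 − f_np)·α_ref)/f_np under the
  assumption that the (n,γ) dose fraction acts with the reference α;
  f_np comes from the per-channel dose-per-fluence components. With
  f_np = 1 this reduces identically to RBE_M.

Reference photon curves are injected as data (coefficients + SEs), never
refit: their raw scoring data are not available here.

## Capture-reaction physics

Dose additivity over capture channels: k_total = k_np + k_γ
(pGy cm² n⁻¹), f_np = k_np/k_total. Fluence-rate × k_total × 3600 ×
10⁻⁹ gives mGy h⁻¹; all unit constants live in one module.

Macroscopic cross-sections: Σ(E) = Σ_elements w_e·ρ·N_A/A_e · σ_e(E)
over the designated reaction list. Bundled σ are 2200 m/s (0.0253 eV)
thermal values — H(n,γ) 0.3326 b, ¹⁴N(n,p) 1.83 b, ¹²C(n,γ) 0.00353 b,
¹⁶O(n,γ) 0.00019 b, ²⁸Si(n,γ) 0.177 b — scaled 1/v across the thermal
range; user-supplied grids are interpolated log-log with no
extrapolation. For a 1/v law the log-log interpolation is exact (it is
a power law), which is why the default grid density is uncritical.

Slab removal is single-exponential, 1 − exp(−Σt): pure absorption, no
scattering buildup. This matches the mutual consistency of the
published 2/10/100 cm removal triplet, which a calibration helper
(Σ from one anchor) reproduces within 0.1 percentage points from any
anchor. The hand value of Σ for ICRU four-component tissue from the
bundled 2200 m/s data is ≈ 0.0222 cm⁻¹ at 25 meV, slightly below the
≈ 0.0230 implied by the published percentages (different evaluations /
spectrum averaging); the acceptance check therefore tests internal
consistency of the triplet rather than an absolute Σ.

Tissue compositions: blood uses the study's modelled mass fractions
(10.19% H, 2.96% N, 75.94% O, 10.00% C) with the ~0.9% trace remainder
folded into oxygen so fractions sum to 1; the other bundled materials
(ICRU four-component tissue, ICRP soft tissue at 2.49% N, eye lens at
5.70% N) are nominal four-component reductions for the capture-curve
ordering analyses, not certified compositions.

## Microdosimetry

Spectra are counts per source particle on strictly increasing
(log-spaced) lineal-energy bin edges; the representative lineal energy
of a bin is the geometric midpoint. Combination of neutron and gamma
spectra is fluence-weighted: w_p = Φ_p/(Φ_n + Φ_γ) per bin, no
resampling (mismatched binning is an error). Moments are the discrete
forms ȳ_F = ΣC_iy_i/ΣC_i and ȳ_D = ΣC_iy_i²/ΣC_iy_i; the dose
distribution is y·d(y) normalised to the log₁₀ bin width.

The quality-factor relation is pluggable; the default is the ICRP 60
piecewise Q(L) applied with y as the LET surrogate (Q = 1 below
10 keV μm⁻¹; 0.32y − 2.2 to 100; 300/√y above). Published Q̄ values from
full transport simulations are treated as reference inputs, not
reproduction targets, because the underlying spectra are not published
and the authors' exact Q(y) convention is unstated.

Specific energy: for a sphere of diameter d the Cauchy mean chord is
2d/3, so z̄_F = ȳ_F·(2d/3)/(ρ·π/6·d³), keV → J and g → kg conversions
via CODATA constants, reported in mGy (z̄_F ∝ ȳ_F/ρd²). Hit statistics
are Poisson with N = D/z̄_F. The neutron-only hit tables pair the (n,p)
dose component with the *uncollided*-field z̄_F and the total dose with
the *collided*-field z̄_F — the physically consistent pairing (the
uncollided primaries drive the capture reactions) and the one that
reproduces the published hit tables.

## Synthetic data and what the validation shows

Cohort generator: per cell at dose D, T ~ Poisson(λ) tracks, each
contributing 1 + Poisson(m) aberrations (compound Poisson / Neyman
type A), with λ = (c + αD + βD²)/(1 + m) so the expected yield sits
exactly on the curve. The dispersion index is (1 + m) + m/(1 + m),
independent of dose; m = 0 is exactly Poisson. Defaults mirror the
pooled DCA design (six points 0–408 mGy, 12 643 cells, α = 0.467 Gy⁻¹,
c = 0.001) with m = 0.105, i.e. dispersion ≈ 1.20 — the middle of the
1.1–1.5 range of the study tables. A single seed drives per-dose-point
substreams (SeedSequence spawning), so cohorts are bit-reproducible and
stable under added dose points.

The generator emulates: curve-shaped mean yields, clustering-driven
overdispersion, realistic cell numbers. It does not emulate: donor
heterogeneity, dose-dependent dispersion, scoring errors, or
cell-cycle/culture effects. Passing recovery tests therefore show the
estimator chain is correct under the assumed sampling model — not that
real scoring data meet those assumptions.

Measured consequence of overdispersion: over 200 replicates at the
default design, the empirical SD of α̂ exceeds the mean reported
Poisson SE by the expected factor √1.2 ≈ 1.09, so nominal 95% (2-SE)
Wald intervals cover the truth ≈ 93.5% of the time. That satisfies a
≥ 90% coverage requirement but falls short of nominal; analysts wanting
calibrated intervals on overdispersed data should scale SEs by the
root dispersion index externally.

Spectrum generator: log-normal event distributions clipped to the gamma
band (0.1–10 keV μm⁻¹) and the neutron band (10–100 keV μm⁻¹, mode near
35 keV μm⁻¹, the proton-edge region of the 584 keV capture proton);
fluences are solved so a requested gamma dose share is realised exactly
in the fluence-weighted combination.

## Known limitations

* The printed 31 meV (n,p)-only RBE_M (7.6 ± 1.0) is not reproduced by
  the same closed-form decomposition that reproduces the 64 meV value
  (15.5 ± 2.2) exactly; the closed form gives ≈ 9.0 for the 31 meV
  inputs. The package reports the closed form and does not tune
  constants toward the printed value; the discrepancy is unresolved
  without the original intermediate arithmetic.
* The published linear-fit χ² significance (0.668) is not recoverable
  from the pooled six-point table (Pearson and deviance both give
  ≈ 0.33); the linear-quadratic χ² and all coefficient/SE values are.
  Donor-level data would be needed to settle the difference.
* Dose-specific RBE columns of the study tables require the reference
  curves' unpublished β and c; they are carried as fixture data only,
  with inversion round-trip and low-dose-convergence properties tested
  in their place.
* No partial-body/contaminated-Poisson dose estimation, no Bayesian
  inverse dosimetry, no particle transport: per-beam dose coefficients
  and TEPC metrics are consumed as inputs.
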