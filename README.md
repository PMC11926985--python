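# cytodose

Cytogenetic biodosimetry of thermal-neutron exposures in human blood
lymphocytes: aberration-distribution statistics, Poisson-weighted
dose-response fitting, relative biological effectiveness (RBE) with
delta-method uncertainties, thermal-neutron capture dosimetry, and
microdosimetric hit statistics — with a synthetic-cohort generator for
end-to-end validation.

## Who this is for

Radiobiologists and health physicists analysing dicentric chromosome
assay (DCA) or cytokinesis-block micronucleus (MN) scoring data after
thermal-neutron irradiation, where the dose arrives through two capture
channels: the high-LET ¹⁴N(n,p)¹⁴C reaction (a 584 keV proton plus a
¹⁴C recoil, both with micrometre-scale ranges) and low-LET (n,γ)
radiative capture acting through secondary-photon electrons.

## The model

At each dose point the raw observable is the number of cells carrying
exactly *k* aberrations. The per-cell yield is modelled as

    A(D) = c + αD            (linear)
    A(D) = c + αD + βD²      (linear-quadratic)

with *D* the absorbed dose in Gy. Aberration counts are Poisson with
mean *n*·A(D) for *n* scored cells; coefficients are maximum-likelihood
estimates from iteratively reweighted least squares (weights
*n*/fitted-yield — the identity-link Poisson GLM with cell-number
exposure standard in cytogenetic dosimetry), with standard errors from
the inverse Fisher information.

Densely ionising tracks cluster damage, so per-cell counts are
overdispersed relative to Poisson. The dispersion index σ²/ȳ and
Papworth's u-statistic,

    u = (σ²/ȳ − 1) · sqrt((n − 1) / (2(1 − 1/x))),

quantify this (x = total aberrations; u > 1.96 flags significant
overdispersion).

RBE estimators: RBE_M = α_n/α_ref (low-dose limit); iso-effect
(dose-specific) RBE by reference-curve inversion; and a Schmid-style
decomposition isolating the (n,p) channel, assuming the (n,γ) fraction
acts with the reference α:

    α_np = (α_n − (1 − f_np)·α_ref) / f_np,   RBE_M(n,p) = α_np / α_ref.

The physics layer books doses per unit fluence additively over capture
channels (k_total = k_np + k_γ, in pGy cm² n⁻¹), converts fluence rates
to dose rates, computes macroscopic capture cross-sections of tissue
mixtures (1/v-scaled thermal cross-sections, log-log interpolation), and
single-exponential slab removal. The microdosimetry layer combines TEPC
pulse-height spectra fluence-weighted, computes ȳ_F, ȳ_D, the log-binned
dose distribution y·d(y), a pluggable dose-mean quality factor
(ICRP 60 Q(y) by default), the frequency-mean specific energy
z̄_F = ȳ_F·(2d/3)/(ρπd³/6) of a spherical site, and Poisson hit
statistics p(ν) = Nᵛe⁻ᴺ/ν! with N = D/z̄_F.

## Worked example

The pooled study tables are bundled, so the whole analysis runs without
input files:

```bash
cytodose run --model both
```

prints (abridged):

```
dose(mGy)  assay  cells  total  yield   disp    u
        0  DCA     2326      2  0.001   1.00  -0.02
       41  DCA      988     20  0.020   1.48  10.97
      ...
      408  DCA     2387    488  0.204   1.19   6.41
        0  MN      5634     82  0.015   1.08   4.44
      ...
DCA linear: c=0.0008±0.0006 alpha=0.467±0.014 /Gy
DCA linear_quadratic: c=0.0009±0.0006 alpha=0.387±0.042 beta=0.260±0.131 /Gy
DCA RBE_M = 6.7 ± 0.9 vs Cs-137 reference
MN RBE_M = 4.4 ± 0.4 vs Co-60 reference
```

Reading: every irradiated DCA dose point is significantly overdispersed
(u > 1.96 — clustered damage from single high-LET tracks); the linear
slope 0.467 Gy⁻¹ against the ¹³⁷Cs reference slope 0.070 Gy⁻¹ gives a
maximum RBE of 6.7 ± 0.9, i.e. at low doses these thermal neutrons are
roughly seven-fold more effective per gray than reference photons at
producing dicentrics plus rings.

The same pieces are available as a library:

```python
from cytodose import fixtures, summarize_distribution, rbe_max

s = summarize_distribution(fixtures("table2", dose=408))
print(s.yield_per_cell, s.dispersion_index, s.u_statistic)
# 0.2044 1.185 6.410

print(rbe_max(0.467, 0.015, 0.070, 0.0088).value)  # 6.671...
```

Synthetic cohorts with a known truth (compound-Poisson overdispersion)
support recovery experiments:

```bash
cytodose simulate --out-dir /tmp/demo --seed 11
cytodose run --input /tmp/demo/distributions.csv
```

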