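# Methods

This note documents the models implemented in `y90dose`, the numerical
choices behind them, what the synthetic data emulate, and known limits.

## Region-based dosimetry

All compartmental formulas derive from the MIRD schema specialised to ⁹⁰Y
microspheres: no biological clearance (permanent trapping), pure β emission
with negligible bremsstrahlung, and full local absorption at the organ scale
(absorbed fraction φ = 1). The cumulated activity is `Ã = A(0)/λ` and the
energy released per becquerel of initial activity is
Δβ/λ = 933 keV / 3.00×10⁻⁶ s⁻¹ = 3.11×10⁸ keV·s ≈ 49.8 nJ/Bq. Every dose
equation uses the conventional rounded constant **50 Gy·kg/GBq**; both the
rounded and exact values are exposed on `Y90Constants`. The voxel
concentration formula `D = c₀·50×10⁻⁶/ρ` evaluates to 48.08×10⁻⁶ Gy per
Bq/cm³ at soft-tissue density 1.04 g/cm³ (sometimes quoted rounded as 48).

Partition model conventions:

* LSF is computed from *total* counts (lung vs lung+liver), the T/N ratio
  from *mean* (per-volume) counts — the ratio is defined on concentrations.
* The lung mass in the lung dose defaults to 1.0 kg. The classical partition
  model does not specify one; override `lung_mass_kg` whenever a
  patient-specific estimate exists.
* Activity conservation `A_T + A_N + A_L = A` holds to machine precision and
  is enforced by tests.
* A multi-compartment set whose FIAs do not sum to 1 warns instead of
  failing: partial compartment sets (e.g. tumours only) are legitimate.

## The dose-point kernel

The packaged radial kernel (`data/y90_dpk_water.csv`, 240 bins of 0.05 mm to
12 mm, water) is produced by a small deterministic condensed-history
electron simulation (`y90dose.kernels.generate_water_dpk`,
`scripts/make_kernel.py`):

* **Spectrum.** Fermi theory with the relativistic point-Coulomb Fermi
  function for the Z = 40 daughter and the unique first-forbidden shape
  factor (p² + q²), endpoint 2.2801 MeV. Implemented mean energy:
  0.9475 MeV, 1.6% above the nominal 933 keV.
* **Energy loss.** Berger–Seltzer collision stopping power for liquid water
  (I = 75 eV) with the Sternheimer density-effect correction; radiative
  losses are neglected (<1% below the endpoint), consistent with treating
  bremsstrahlung as locally re-absorbed.
* **Transport.** Histories step 0.02 mm along the CSDA range; each step
  deposits its CSDA energy loss at the midpoint and Gaussian-scatters the
  direction with the Rossi–Greisen rms angle `Es/(pβc)·√(ds/X₀)`,
  Es = 15 MeV, X₀ = 36.08 cm. Energy is scored in spherical shells.

Validation anchors are independent of any downstream result: the spectrum
mean (933 keV within 2%, which is also the kernel energy-normalisation
invariant `4π∫k(r)ρr²dr = Δβ`), the CSDA range of the mean-energy electron
(3.85 mm in soft tissue), and the radius containing 90% of the emitted
energy (X90 ≈ 5.3 mm in water, reproduced to 0.25 mm). A pure straight-line
CSDA quadrature (no scattering) was evaluated first and rejected: it
overestimates X90 by ~25%, which visibly distorts sphere absorbed
fractions. The Gaussian small-angle treatment underrepresents rare
large-angle single scatters; this residual shape error is well below the
tolerances quoted for the phantom study.

Density scaling to a uniform medium of density ρ uses `r → r·ρ_w/ρ` with
amplitude `·(ρ/ρ_w)²`, the scaling that preserves the energy integral of a
*dose* kernel. Heterogeneous media (radiological-distance scaling) are not
supported; lung-density constants are exposed but no lung kernel is shipped.

## Voxel dosimetry

The dose-voxel kernel is built from the radial table by midpoint
supersampling (5³ per voxel) of the energy density ρ·k(r); the central voxel
receives the residual so the kernel sums *exactly* to the tabulated energy
per decay — global energy conservation of convolution dosimetry is then
structural, and tests confirm it to <2% against emitted energy on padded
grids. Convolution uses zero-padded FFTs (`scipy.signal.fftconvolve`, no
wrap-around); isotropic voxels are required. Local energy deposition applies
the concentration formula per voxel and is preferable when the image
resolution exceeds the β range (FWHM ≳ 4.5 mm).

Sphere phantoms are binary indicators rasterised by centre-of-voxel
inclusion on grids padded by max(12 mm kernel range, 3×FWHM); default
resolution 0.5 mm for diameters ≤ 50 mm and 1.0 mm above (grid-refinement
changes φ by <0.005 at 20 mm). The PSF study blurs with isotropic Gaussians
(σ = FWHM/2.355, truncation 6σ keeps counts to 10⁻⁶). RC and φ are both
computed as in-sphere sums of the degraded images, and their ratio measures
the residual partial-volume mismatch of the local-deposition hypothesis. An
analytic continuum oracle — the kernel's radial energy distribution against
the sphere chord-overlap probability `P(r) = 1 − 3r/4R + r³/16R³` — backs
the voxelised pipeline in tests.

DVHs bin voxel doses (default 1 Gy) and store per-bin volumes and
dose-weighted mean doses, so the differential first moment reproduces the
map's mean dose to 10⁻⁶. D_X and V_Y are read from the exact empirical
survival function with ties resolved toward the higher dose ("least dose
irradiating X% of the volume"): a uniform 100 Gy region yields D₅₀ = 100 Gy
exactly, which interpolation on binned curves would miss.

## Simulated dose-response cohorts

The generator *is* the study design, not a tunable: 100 lesions at fixed
doses 1, 3, …, 199 Gy, one Bernoulli response per lesion with

    p(D) = exp(−8·e^(−0.03·D)) · (1 − 3.3×10⁻⁵·D).

Over the grid the mean response probability is 0.558; per-dose response
rates over many seeds pass a χ² goodness-of-fit against p(D). What this
emulates is the *statistical* structure of a retrospective lesion series
(binary response vs dose); what it does not emulate is anything clinical —
dose uncertainty, correlated lesions within patients, censoring — so
passing distributional tests validates the statistical machinery, not a
clinical claim.

Analysis conventions:

* Rank-sum: two-sample Mann–Whitney with normal approximation, tie and
  continuity corrections (responders vs non-responders).
* ROC: empirical curve over all distinct thresholds; trapezoidal AUC, which
  equals U/(n₁n₀) identically; DeLong (not bootstrap) 95% CI for
  determinism; Youden cutoff with ties resolved to the lowest threshold.
* Logistic model: increasing parameterisation `logit P = β₀ + β₁·D`
  (the decreasing-exponent convention `a = −β₁, b = β₀` is exposed for
  compatibility with the form sometimes printed). MLE via GLM-binomial;
  fractional responses with weights are accepted, so the model can be fitted
  to exact probabilities. ED_p = (logit p − β₀)/β₁ with delta-method CIs on
  the dose scale by default; a profile-likelihood CI is available
  (`ci_method="profile"`). Complete separation is flagged, never silently
  estimated.
* The KL projection of the generator onto the logistic family (weighted MLE
  on exact probabilities) gives ED50 = 88.0 Gy and ED80 = 121.3 Gy; these
  deterministic references are pinned as regression tests. The sampling
  distribution of single-cohort ED50 estimates is centred there with an IQR
  of roughly ±4 Gy, i.e. noticeably above the ~81 Gy crossing of the
  generating sigmoid itself, because the symmetric logistic cannot follow
  the Gompertz-like asymmetry. Single-draw values 1.5–2 SD from the centre
  are unremarkable.

## Radiobiology

* **TCP.** `P(D) = exp(−N₀·e^(−αD − GβD²))` with β tied through α/β
  (default 10 Gy), μ = 0.46 h⁻¹, λ = 0.0108 h⁻¹, hence G = 0.0229 for a
  permanent ⁹⁰Y implant. The binned fit (default 25 Gy bins, per-bin mean
  dose and response fraction, count-weighted Levenberg–Marquardt) frees
  N₀ and α only — the minimal identifiable set; N₀ is fitted on a log scale
  for positivity. ED50/ED80 are solved numerically from the fitted curve.
* **EUD.** `−(1/α)·ln(mean e^(−αD))` over voxels or differential-DVH bins
  (log-sum-exp for stability). α > 0 is required; the α→0 limit is exposed
  separately as `mean_dose`. Literature liver α is ~0.0065 Gy⁻¹; tumour
  values reported for HCC span 0.001–0.038 Gy⁻¹ and must be chosen by the
  user.
* **NTCP.** Lyman probit via the standard-normal CDF with
  `TD50(v) = TD50/v`; the slope `m` has no defensible default and is a
  required input.
* **Microscale TD50.** `[25.2 + 22.1(1 − e^(−2.74·msA))]/(v − 0.4)^0.584`
  with msA in kBq per sphere — the only bracketing of the published
  expression that reproduces all four printed values (38/64/57/96 Gy). For
  v ≤ 0.4 the model diverges and the TD50 is reported as infinite with a
  warning rather than raising: divergence is the model's statement that
  selective treatments are safe, not an input error. The model ignores
  pre-existing liver dysfunction and prior therapies.
* **TI and P\*.** TI takes TD50 and ED50 as explicit inputs (published
  worked examples mix TD50 sources, so nothing is derived implicitly). The
  P\* activity scan maps administered activity through compartment dose
  coefficients to TCP·(1−NTCP) and locates the maximum by grid argmax.

## Problem sizes and determinism

Test-suite and acceptance computations use the full 10×5 sphere/PSF grid at
the default resolutions (largest grid ≈ 242³ voxels at 1 mm), 200-seed
cohort ensembles for distributional statistics, 10⁴-lesion synthetic
cohorts for parameter-recovery checks, and 3×10⁵ histories for the shipped
kernel (1:10⁶ available via the regeneration script). All stochastic
components take explicit integer seeds; hypothesis-based property tests run
derandomised.

## Known limitations

* No Monte Carlo transport at runtime and no collapsed-cone option; the
  kernel route assumes a uniform medium.
* Planar-scintigraphy processing (geometric means, scatter/attenuation
  correction) is upstream of this package: count inputs are taken as given.
* The Gaussian PSF is an idealisation of SPECT/PET resolution; no
  distance-dependent or asymmetric PSF.
* Radiobiological parameters (α, N₀, m, TD50) are user inputs; the package
  deliberately ships no clinical defaults beyond the conventional α/β and
  repair constants, and none of its outputs constitute treatment
  recommendations.
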