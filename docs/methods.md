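# Methods

`prosailgpr` implements a hybrid retrieval of rice leaf area index
(LAI): a physical canopy reflectance model generates a training
database, and a Gaussian process regression (GPR) learns the inverse
mapping from Sentinel-2 band reflectance to LAI. This note documents
the models, the defaults and their rationale, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Leaf model

The leaf module is a four-parameter plate model (the PROSPECT-4
formulation): a leaf is N stacked "plates" — absorbing slabs bounded by
rough dielectric interfaces — with N real-valued. Inputs are the
structure index N (1.2–2.5 in the sampling scheme), chlorophyll a+b
content Cab (µg/cm²), equivalent water thickness Cw (cm) and dry
matter Cm (g/cm²). Per wavelength, the slab absorption is
k(λ) = (Cab·k_cab + Cw·k_cw + Cm·k_cm)/N; the slab transmissivity
integrates Beer's law over the incidence hemisphere, which has the
closed form (1−k)e⁻ᵏ + k²E₁(k) with E₁ the exponential integral.
Interface transmissivities average the Fresnel coefficients over an
incidence cone (the Stern/Allen formula); the top surface uses a 40°
half-angle (the conventional value for a rough epidermis, exposed as
`incidence_deg`), interior interfaces are hemispherical. The stack of
N−1 interior plates is composed with Stokes' pile-of-plates solution,
which extends to non-integer counts.

Numerical choices: E₁ is evaluated by its power series for x ≤ 1 and a
modified-Lentz continued fraction above (≈1e-14 relative accuracy,
verified against quadrature); the Stokes expressions have guarded
limits for conservative (r+t→1), non-scattering (r→0) and opaque
(t→0) plates.

**Optical constants.** The published PROSPECT-4 calibration table is
not redistributed here. The package default
(`leaf.synthetic_absorption_table`) is a deterministic synthetic table
with the structure of real leaf optical constants — refractive index
falling from ~1.52 to ~1.36, chlorophyll absorption peaking at 430 and
670 nm and vanishing past the red edge, water bands at 970/1190/1450/
1940/2400 nm, dry matter rising into the SWIR — with magnitudes chosen
once so that a mid-range leaf (N = 1.85, Cab = 32.5, Cw = 0.025,
Cm = 0.015) produces realistic spectra (red reflectance ≈ 0.04, NIR
plateau ≈ 0.54 with T ≈ 0.45, deep SWIR water troughs). Users holding
the published calibration can supply it as a text table via
`load_absorption_table`; every API accepts a table argument.

## Canopy model

The canopy module is the 4SAIL four-stream turbid-medium model: the
canopy is a horizontally homogeneous layer of randomly positioned
leaves with an inclination distribution, over a Lambertian soil.
Four fluxes are tracked (direct solar, downward and upward diffuse,
flux-equivalent radiance toward the observer); extinction and
scattering coefficients come from the leaf inclination distribution
and the sun/view geometry (the classic 13-class discretization:
eight 10° classes plus five 2° classes near vertical).

Leaf inclination is parameterized solely by its mean angle ALA
(degrees from horizontal), expanded into the ellipsoidal (Campbell)
distribution; the ellipsoid axis ratio is solved numerically so the
continuous mean equals ALA (cached interpolation, mean accurate to
well under the 2° contract).

The diffuse two-stream operators use the standard analytic
exponential solution. The multiple-scattering contribution to the
bidirectional term is computed directly from the closed-form solution
of the two-stream boundary-value problem driven by the attenuated
direct beam (particular solution ∝ e^(−ks·x) plus two homogeneous
exponentials e^(∓m·x), coefficients fixed by the boundary conditions),
integrated along the view path. This form is verified against an
independent finite-difference solution of the same four-stream system
to ≤1e-3 absolute (typically ~1e-6). The single-scattering term uses
the Kuusk hot-spot correction with the standard 20-step integral of
the joint sun–view gap probability; `hotspot = 0` disables the
correction (uncorrelated gaps).

Degenerate inputs: perfectly conservative scattering (leaf ρ+τ = 1)
makes the analytic solution singular; the backscatter coefficient is
nudged down by 1e-6 (equivalent to adding ~1e-6 absorption), keeping
the coefficient set internally consistent and the output accurate to
<1e-4 there. LAI = 0 returns the soil spectrum exactly.

Defaults, all config-exposed: sun zenith 30°, nadir view (Sentinel-2
views within ~12° of nadir), relative azimuth sampled in the LUT;
diffuse fraction skyl = 0.1 (clear-sky mid-visible value; it is a
listed model input with no prescribed value); hot-spot parameter 0.01
(small but non-zero — zero would disable the correction entirely,
while typical leaf-width/canopy-height ratios are of this order).

## Training database (LUT)

2000 parameter vectors are drawn per the study's sampling scheme:
LAI ~ truncated Gaussian(5.5, 4) on [0.2, 9] and Cab ~ TG(35, 20) on
[10, 55] — the two parameters with stated moments — and N, Cm, Cw,
ALA, soil scaling and relative azimuth uniform on their ranges.
Truncated Gaussians are sampled by inverse-CDF so draws are
deterministic given the seed. The LUT size is configurable; 2000 is
the study size (larger databases gave indistinguishable accuracy
there).

Each row draws one wet/dry endmember pair from the soil library and
mixes it with the row's scaling factor s: soil = s·dry + (1−s)·wet —
the library supplies between-sample variability, the factor the
moisture/brightness continuum; both mechanisms are present because the
source describes both without stating their combination.

Spectra are resampled to the ten retained Sentinel-2 bands (B2–B8A,
B11, B12) with Gaussian response functions whose FWHM equals each
band's nominal bandwidth, truncated at ±2 FWHM (tails clipped at the
400–2500 nm grid edge, which only affects B2). Tabulated official
spectral response functions can be supplied per band. Band values are
response-weighted means, exactly linear in the spectrum.

Noise (training only; the clean LUT is preserved separately):
R* = R(1 + md + mi) + ad + ai with md ~ N(0, (2 %)²) per band,
mi ~ N(0, (2 %)²) per sample, ad ~ N(0, 0.01²) per band,
ai ~ N(0, 0.01²) per sample. "Wavelength dependent" means an
independent draw per band; "independent" means one draw shared across
a sample's bands.

## Gaussian process regression

Standard zero-mean GP regression after centring the targets on their
mean (this realizes the bias term of the predictive expansion without
a free parameter), with the ARD squared-exponential kernel
K(x,x′) = ν·exp(−Σ_b (x_b−x′_b)²/(2σ_b²)) and observation noise σ_n²
on the Gram diagonal. Inputs are standardized per band from training
statistics, so the fitted length-scales are comparable across bands;
σ_b is reported in standardized units for the relevance ranking
(smaller length-scale = more relevant band).

Hyperparameters (ν, σ_n, σ_1..σ_B) maximize the log marginal
likelihood by L-BFGS in log-parameter space with analytic gradients;
5 restarts by default (the first from ν = var(y), σ_n = 0.1·sd(y),
unit-scale σ_b; later ones log-normal perturbations). For training
sets beyond `max_opt_points` (default 600) the likelihood is optimized
on a seeded subset of that size and the weights are then solved on the
full set — the standard cost control for the cubic Cholesky; on this
problem the subset choice moves the cross-validated R² by well under a
point. A jitter of 1e-10·ν stabilizes the factorization; predictive
variances are clamped at zero (warning if beyond round-off).

Cross-validation: seeded shuffle into k near-equal folds (remainder
spread one per fold), each sample predicted exactly once out-of-fold.
The reported R² is the squared Pearson correlation of the least-squares
fit of predicted on observed (matching the study's scatter-plot
convention); a 1:1-line (Nash–Sutcliffe) R² is reported alongside as
`r2_identity` to remove ambiguity. RMSE is against the 1:1 line.

## Retrieval products

Raster inversion applies the posterior mean and standard deviation
per pixel; nodata and implausible pixels (any band outside [0, 1.2])
are propagated; georeferencing is copied to the outputs. Phenology
profiles average valid pixels inside each plot polygon per date and
label phases from days after sowing: vegetative ≤ 57, reproductive
58–72, ripening > 72 (thresholds and sowing date are inputs; the
default calendar uses the campaign's printed DAS values verbatim,
including the 92-DAS milk-stage row even though it is inconsistent
with simple date arithmetic on the earlier rows).

## Synthetic data generator

The generator stands in for an undeposited field campaign; it defines
the test conditions rather than adapting to them.

*Soil library* (default 69 samples): a smooth dry-soil template scaled
by per-sample brightness in [0.5, 1.5] with ±10 % spectral slope
variation; wet counterparts are darkened (×0.62 with deepened water
bands). Labels split half/half. Real soil libraries vary in shape,
roughness and moisture far more richly; this matters for how well the
regression can explain away the background (see Limitations).

*Phenology truth*: double-logistic LAI trajectories in DAS — rise
midpoint ≈ 50 DAS, decline midpoint ≈ 88 DAS — with peak amplitude set
by nitrogen rate (4.6/6.0/7.4 for 55/110/165 kg ha⁻¹ before random
effects), block and plot effects smaller than the between-rate gaps
(so the nitrogen ordering of peaks is preserved in every replicate),
and a transient dip centred at 56 DAS for the alternate-wetting
regimes (12 % moderate, 22 % severe). These shapes satisfy the
qualitative constraints reported for the emulated experiment
(continuously flooded plots rise monotonically through the vegetative
phase; peaks fall in the reproductive/ripening window; all values in
[0.2, 9]); amplitudes are otherwise a design choice.

*Campaign rendering*: per plot–date, nuisance parameters (leaf
properties, ALA, soil, azimuth) are drawn from the LUT sampling
scheme, reflectance is rendered at the true LAI, band noise applied,
and observed LAI = truth + N(0, 0.3²) — 0.3 LAI units being plausible
plant-canopy-analyzer plus within-plot variability; config-exposed.

## Problem sizes

The test suite and the acceptance script run the full study pipeline —
2000-sample LUT, 10-fold cross-validation, five seeds — exactly at
study scale. Supporting experiments are sized for speed without
changing conclusions: the end-to-end closure test trains on a
600-sample noiseless LUT (accuracy there is insensitive to database
size well below 2000), the canopy oracle uses a 1500-node finite
difference grid, and GP hyperparameters are optimized on 600-point
subsets as described above.

## Limitations

- The optical constants are synthetic. Band-level information content
  is qualitatively right (red edge, NIR plateau, SWIR water), but
  absolute reflectance and retrieval accuracy cannot be expected to
  match runs that use the published calibration data.
- The synthetic soil library is smoother and lower-dimensional than a
  field-measured one, which makes the soil background easier for the
  regression to separate from the canopy signal; cross-validated
  accuracies on this database are therefore optimistic relative to a
  database built on field soil spectra.
- The canopy is a turbid medium: no row structure, clumping or 3-D
  effects, and the generator does not emulate mixed pixels or spatial
  autocorrelation at the 20 m grid.
- Passing tests demonstrate internal consistency of the pipeline and
  its statistics on simulated data, not field retrieval accuracy.
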