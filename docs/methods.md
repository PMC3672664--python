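# Methods

This note documents the models implemented in `dosidensity`, the default
parameters and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter.

## Optical forward model

Light transport is modeled with the diffusion approximation for a
semi-infinite homogeneous medium with an extrapolated boundary. For
absorption μa, reduced scattering μs′ (both mm⁻¹), source–detector
separation ρ and angular modulation frequency ω, the complex
photon-density-wave reflectance is

    R(ρ, ω) ∝ exp(−k r₁)/r₁ − exp(−k r₂)/r₂,
    k = sqrt((μa + iω/c_n)/D),   D = 1/(3(μa + μs′)),

with an isotropic source one transport mean free path z₀ = 1/(μa + μs′)
below the surface, its negative image mirrored about the extrapolated
boundary z_b = 2AD, A = (1 + R_eff)/(1 − R_eff), and the internal
reflection parameter R_eff from the Groenhuis polynomial in the tissue
refractive index (n = 1.4 by default, the conventional soft-tissue value).
Amplitude is |R| and phase the (positive) lag −arg R; the steady-state
model is the ω = 0 limit and is treated everywhere as known only up to a
global positive gain. The boundary condition, refractive index and
extinction sources are conventional choices — standard frequency-domain
photon-migration practice — because closed-form testability was the
priority.

Tissue absorption follows Beer–Lambert superposition:

    μa(λ) = ε_HHb(λ)·ctHHb + ε_O2Hb(λ)·ctO2Hb
            + (water/100)·μa_water(λ) + (lipid/100)·μa_lipid(λ),

with hemoglobins in µM and water/lipid as percent of the pure substance's
absorption (volume-fraction convention). Reduced scattering uses the
standard spectral power law μs′(λ) = A(λ/λ₀)^(−b) with λ₀ = 650 nm, the
short edge of the broadband window.

The bundled extinction table (`data/extinction_synthetic.csv`, 1-nm grid,
650–1000 nm) is a **synthetic** literature-style compilation: smooth
shape-preserving interpolation through representative anchor values, with
the hemoglobin isosbestic point near 800 nm, the water absorption peak near
975 nm and the lipid peak near 930 nm. It is internally consistent — every
forward/inverse round trip in the package uses the same table — but it is
not a verbatim published tabulation, so absolute concentrations recovered
from *real* instrument data with this table would carry the table's
approximation error. Users can substitute their own table in the same CSV
format.

## Recovery chain

1. **Per-wavelength frequency-domain fit.** Nonlinear least squares of the
   forward model jointly to log-amplitude and phase across the modulation
   sweep, with a free per-wavelength log-gain profiled out analytically
   (the instrument's amplitude scale is arbitrary). Optimization is in
   log(μa), log(μs′) starting from the best point of a 10×10 log-spaced
   grid over μa ∈ [5·10⁻⁴, 0.1], μs′ ∈ [0.2, 3] mm⁻¹ (the physiological
   breast range); Levenberg–Marquardt refinement with tight (1e-14)
   tolerances. Equal weights on log-amplitude and phase in radians — their
   noise scales are comparable at the default noise model (1 % amplitude,
   0.1° phase).
2. **Scatter power law.** Ordinary least squares of log μs′ on log λ
   across the laser wavelengths.
3. **Broadband absorption.** The unknown broadband gain is the geometric
   mean of measured/model reflectance ratios at the frequency-domain
   anchor wavelengths (least squares in log space); each wavelength's μa
   then comes from Brent root finding on the steady-state model (bracket
   10⁻⁷–2 mm⁻¹, xtol 10⁻¹³), with μs′(λ) from the power law. The chain is
   invariant to any global rescaling of amplitudes or reflectance.
4. **Unmixing.** Non-negative least squares onto the four basis spectra.
   Non-negativity is imposed because negative concentrations are
   unphysical; the residual norm is returned so poor fits are visible.
5. **Derived indices.** ctTHb = ctHHb + ctO₂Hb (exact by construction),
   stO₂ = 100·ctO₂Hb/ctTHb, TOI = ctHHb·water/lipid.

Subject averages are unweighted means over non-areolar grid positions. The
areola is a concentrated fibroglandular region unrepresentative of the
breast, so it is excluded by an explicit mask (automatic areola detection
is out of scope). Whether subject-level stO₂/TOI should be the index of the
averaged concentrations or the average of per-position indices is
genuinely ambiguous in field practice; both are computed and labeled
(`indices_of_means`, `mean_of_indices`).

Measurement days are binned at edges 15/45/75/105/135 days into
baseline/30/60/90/120-day intervals — the midpoints between the published
follow-up interval ranges (21–43, 55–69, 78–104, 106–127 days), so each
printed range falls inside its bin.

## MRI segmentation

Axial T1-weighted volumes without fat suppression, indexed
(slice, row anterior→posterior, column); the operator supplies the slice
range and the sternum row. Stages:

1. **Thorax crop** at the posterior margin of the sternum (config input).
2. **Breast boundary.** A volume-level two-class FCM splits air from
   tissue; the binarization threshold sits at
   c_air + 0.25·(c_tissue − c_air) rather than the midpoint because the
   darkest tissue class (fibroglandular) lies far below the tissue
   centroid on non-fat-suppressed T1 — a midpoint rule sends it to the air
   class. Residual dark interior voxels are recovered by per-slice hole
   filling; the largest connected component is kept and the chest-wall
   boundary is smoothed with a least-squares spline across columns.
3. **Bias-field correction.** The multiplicative field is exp of a
   2nd-order 3-D polynomial in normalized coordinates fitted to log
   intensity, with two-class FCM log-means subtracted each round (3
   rounds) so anatomy does not leak into the field, and the fit restricted
   to the mask eroded by 3 voxels so the skin rim (intermediate intensity
   hugging the anterior surface) cannot masquerade as a trend. The field
   is normalized to mean 1 over the mask. This is a pluggable smooth-field
   estimator in the spirit of nonparametric nonuniformity normalization
   (N3); reproducing the published N3 algorithm exactly is a non-goal.
4. **Skin exclusion.** Binary erosion of the breast mask with the array
   border treated as tissue, so only the free anterior surface is peeled
   (default 2 voxels); the chest-wall face survives.
5. **Classification.** Six-cluster FCM on the corrected interior
   intensities (fuzzifier m = 2, relative objective tolerance 10⁻⁵, max
   300 iterations, deterministic range-spread centroid initialization).
   Clusters are ranked by centroid; fat is bright on T1 without fat
   suppression, so high centroids are fat and low ones fibroglandular. The
   default split point is the **largest gap between adjacent ranked
   centroids**: when each tissue attracts three of the six clusters this
   reproduces the classic 3 + 3 assignment, but FCM places centroids in
   proportion to voxel mass, so a low-density breast (≈5 % fibroglandular)
   may devote only one or two clusters to the dark tissue — a fixed 3 + 3
   split would then relabel a fat cluster as fibroglandular and inflate
   density by tens of percentage points. A fixed count is available via
   `n_fibro=3`.
6. **Density.** Volumes are voxel counts × voxel volume (cm³);
   percent density = 100 × fibroglandular / breast volume.

## Synthetic data: what it emulates, what it does not

**Baseline compositions** are drawn per menopausal group from independent
truncated normals with the published group means and SD = SE·√n
(premenopausal n = 17, postmenopausal n = 11; only standard errors are
published). Truncation is marginal (concentrations ≥ 0, water/lipid in
[0, 100]). A strict joint cap water + lipid ≤ 100 is available
(`sum_cap=100`) but off by default: the published means put the sum near
91 % with ~10 pp joint spread, so joint rejection trims the upper tail and
biases both means by a quarter SD — with independent draws one can have
faithful group means or a strict sum bound, not both, and the consumers of
the generator calibrate against the means. Real chromophores are
correlated (water up, lipid down); a correlation hook exists but the
default is independence because no covariance is published.

**NAC trajectories** scale each chromophore by 1 + pct(day)/100 with
pct interpolated linearly from 0 at day 0 to the published day-90 GEE
anchor (water −11.9 %/+4.4 %, ctO₂Hb −20.0 %/−20.1 %, ctHHb −2.5 %/+0.5 %,
lipid +3.8 %/−0.4 % for pre/post), constant afterwards. The published
stO₂ changes (−6.9 %/−7.4 %) are carried as data, but generated stO₂ is
derived from the sampled hemoglobins — scaling it independently would
contradict the hemoglobin trajectories (the published per-parameter
estimates need not be mutually consistent, ours must).

**Cohorts** place visits by per-interval attendance probabilities matching
the published per-interval sample sizes, with visit days uniform inside
the published ranges. Within-subject measurement noise is 3 % multiplicative
per parameter, motivated by the reported sub-5 % test/retest variation
(whose exact definition is unpublished). Note one estimand subtlety: the
day-90 interval spans days 78–104 while the trajectory ramp tops out at
day 90, so the interval's true cell mean is
pct₉₀ · E[min(day, 90)]/90 ≈ 0.969 · pct₉₀ — recovery tests compare
against this implied value, and confidence-interval coverage is assessed
against the configured anchor.

**MRI phantoms** are a half-ellipsoid breast resting on a thorax band,
with a nested fibroglandular region grown to hit the target volume
fraction exactly (stored ground truth is exact by construction), a 2-voxel
skin rim on the anterior surface, Gaussian noise (SD 5 % of the fat mean)
and a ±20 % smooth multiplicative bias field (linear ramp by default).
Default grid 24×72×72 at 2×1×1 mm — a scaled-down matrix chosen to keep
the full five-fraction recovery suite fast while leaving every stage
(boundary, bias, skin, classification) nontrivial. The phantoms are
piecewise-constant two-tissue objects: they do not emulate partial-volume
voxels, anatomical texture, Rician noise statistics, nipple anatomy, or
inter-slice profile variation. Passing the phantom suite therefore shows
the pipeline's stages are individually and jointly correct under the
stated intensity model, not that clinical segmentation accuracy would
reach the same ±2 pp.

## Statistics

* **Mann–Whitney U**: exact two-sided p by complete enumeration of group
  assignments with mid-rank ties for combined n ≤ 16 (extremeness measured
  by |U − n₁n₂/2|); otherwise the normal approximation with tie and
  continuity correction.
* **ANOVA / Kruskal–Wallis**: classical F and tie-corrected H with
  chi-square p; identical-constant groups raise (F undefined).
* **Holm**: step-down adjustment, adjusted p monotone, order-invariant.
* **Pearson + diagnostics**: r with t-based p; simple regression; DFFITS
  from the leave-one-out closed form, flagged at |DFFITS| > 2√(2/n); a
  perfect fit reports zero DFFITS by convention.
* **GEE**: identity link, normal variance, exchangeable working
  correlation. Iterate GLS updates of β with moment re-estimation of the
  dispersion φ (Pearson residual sum of squares over N − p) and of α
  (cross-products over pairs, Liang–Zeger denominators) until
  max|Δβ| < 10⁻⁸; the exchangeable inverse is applied in closed form. The
  outcome is subject-level percent change from baseline (baseline excluded
  from the response; modeling absolute change is the documented
  alternative), and the mean structure is the saturated group × interval
  cell-means parameterization — equivalent to the
  intercept/group/interval/interaction coding when every cell is filled,
  and still identifiable on unbalanced panels with empty cells. Reported
  contrasts are per-cell percent changes with 95 % normal-quantile CIs on
  robust SEs. The sandwich covariance defaults to the Mancl–DeRouen
  bias-corrected form ((I − H_ii)⁻¹-inflated cluster residuals): with only
  tens of subjects the plain sandwich is biased low and its nominal-95 %
  intervals undercover; the correction is the standard small-sample
  remedy (plain sandwich via `bias_corrected=False`). α is clipped to its
  positive-definiteness range; α forced to 0 reproduces pooled OLS
  exactly.

Two-sided tests and α = 0.05 throughout. Shapiro–Wilk normality screening
is deliberately not implemented (standard test, no bespoke content).

## Known limitations

* Homogeneous semi-infinite optics only: no layered/heterogeneous media,
  no time-domain, no probe-pressure or instrument-drift correction, no
  tumor contrast.
* The bundled extinction table is a synthetic compilation (see above).
* Segmentation assumes non-fat-suppressed T1 contrast (fat bright); no
  inter-timepoint registration; nipple exclusion must come through the
  areola/config inputs.
* BI-RADS categories are input labels only; no category assignment.
* Published patient-level results are not reproducible by construction
  (the cohort data are unavailable); published group statistics enter only
  as generator parameters and arithmetic-identity checks.
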