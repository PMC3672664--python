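# dosidensity

Quantitative breast-tissue composition from diffuse optical spectroscopic
imaging (DOSI), MRI fibroglandular percent density from T1-weighted volumes,
and the longitudinal statistics that link the two during neoadjuvant
chemotherapy (NAC).

Breast density — the volume fraction of fibroglandular (epithelial +
connective) tissue — is a strong breast-cancer risk factor and a candidate
biomarker of response to endocrine therapy. DOSI measures it functionally at
the bedside: frequency-domain photon migration (six laser diodes, 660–850 nm,
modulated 50–500 MHz) separates tissue absorption μa from reduced scattering
μs′, broadband continuous-wave reflectance (650–1000 nm) extends the
absorption spectrum, and Beer–Lambert unmixing turns μa(λ) into tissue
concentrations of deoxy- and oxyhemoglobin (ctHHb, ctO₂Hb, µM), water and
bulk lipid (% of pure-substance absorption). Derived indices are total
hemoglobin ctTHb = ctHHb + ctO₂Hb, oxygen saturation
stO₂ = 100·ctO₂Hb/ctTHb, and the tissue optical index
TOI = ctHHb · water / lipid. MRI percent density is the fibroglandular
volume divided by breast volume × 100, segmented by the classic
fuzzy-c-means (FCM) pipeline. Percent change from baseline during NAC is
modeled with generalized estimating equations (GEE; identity link,
exchangeable working correlation, robust sandwich covariance).

The package is written for researchers in tissue optics and quantitative
breast imaging who want a tested, self-contained reference implementation of
this pipeline. Patient data behind such studies are not publicly deposited,
so a first-class synthetic-cohort module generates optical grid scans, MRI
phantoms with known ground truth, and longitudinal cohorts with the
published group statistics — every downstream stage is exercised end to end
without patient data.

## Modules

| module | contents |
| --- | --- |
| `dosidensity.tissue_optics` | extinction spectra, Beer–Lambert forward model, μs′ power law, frequency-domain and steady-state diffuse reflectance (semi-infinite medium, extrapolated boundary) |
| `dosidensity.synthetic_cohort` | baseline composition sampling, NAC trajectories, 10-mm measurement grids with areola, MRI phantoms, cohort assembly, plain-text IO |
| `dosidensity.dosi_recovery` | per-wavelength (μa, μs′) fitting, scatter-power fit, broadband μa recovery, non-negative unmixing, derived indices, 2-D maps, areola-excluded averaging, interval binning |
| `dosidensity.mri_density` | FCM, thorax crop, breast boundary, bias-field correction, skin exclusion, tissue classification, percent density |
| `dosidensity.stats_analysis` | Mann–Whitney (exact + asymptotic), ANOVA/Kruskal–Wallis, Holm adjustment, Pearson + DFFITS diagnostics, GEE percent-change models |

## Worked example

Forward-model a 3×4 optical grid scan of a premenopausal-like breast
(ctHHb 5.3 µM, ctO₂Hb 18.9 µM, water 24.4 %, lipid 67.0 %) with an areolar
position and instrument-level noise, then invert it and fit the longitudinal
model on a simulated 28-subject cohort:

```python
from dosidensity import synthetic_cohort as sc, dosi_recovery as dr, stats_analysis as sa
from dosidensity.tissue_optics import TissueComposition

comp = TissueComposition(ct_hhb=5.3, ct_o2hb=18.9, water=24.4, lipid=67.0)
spec = sc.GridSpec(rows=3, cols=4, areola=frozenset({(1, 1)}))
scan = sc.generate_grid_scan(comp, sc.DEFAULT_AREOLA, spec, seed=0)
results, avg = dr.recover_scan(scan)

cohort = sc.generate_cohort(seed=0)
fit = sa.gee_fit(sa.prepare_change_table(cohort, "water"))
est = sa.estimate_group_day_change(fit, sc.PRE, 90)
```

This prints (via the accompanying formatting calls):

```
average over 11 non-areolar positions (1 areolar excluded):
  ctHHb  =  5.31 uM
  ctO2Hb = 18.92 uM
  water  = 24.42 %
  lipid  = 66.88 %
  ctTHb  = 24.23 uM   stO2 = 78.10 %   TOI = 1.94
 premenopausal day-90 water change:  -10.6% (95% CI -12.0 to -9.2)
postmenopausal day-90 water change:   +4.3% (95% CI +2.2 to +6.4)
```

The recovered average reproduces the generating composition to within the
1 % amplitude / 0.1° phase measurement noise, and the GEE percent-change
estimates recover the generator's configured day-90 anchors (−11.9 % water
premenopausal, +4.4 % postmenopausal; the day-90 interval spans days 78–104,
so its cell mean sits slightly above the anchor by construction).

The same operations are scriptable from the shell:

```sh
dosidensity simulate-cohort --seed 0 --out cohort.csv
dosidensity analyze --cohort cohort.csv --out report/
dosidensity simulate-phantom --seed 0 --fraction 0.2 --out phantom/
dosidensity segment --volume phantom/t1_phantom.nii.gz --config seg.yaml --out seg/
dosidensity recover --scan scan.tsv --broadband bb.csv --out subject.json
```

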