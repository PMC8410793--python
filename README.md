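# wgwr — wavelet geographically weighted regression for vis–NIR spectroscopy

Soil properties such as organic carbon content, clay content and pH can be
estimated cheaply from visible–near-infrared (350–2500 nm) diffuse
reflectance spectra. Standard chemometric calibrations (e.g. partial least
squares regression) treat every sample identically and every wavelength on
a single scale, ignoring two structures that field surveys actually have:

* **multiresolution structure** — absorption features live at particular
  spectral scales (broad water bands, narrow mineral bands) that a wavelet
  multiresolution analysis (MRA) separates cleanly, and
* **spatial non-stationarity** — the relationship between spectra and a
  soil property drifts across a region as parent material, climate and
  land use change.

`wgwr` implements a modelling chain that uses both: spectra are decomposed
with a maximal-overlap discrete wavelet transform (Daubechies wavelet with
4 vanishing moments, reflection boundary) into detail components D₁…D₆ at
dyadic scales λᵢ = 2ⁱ plus a smooth S; an optimal subset of wavelet
coefficients is selected in three stages (ranking by absolute Pearson
correlation |R|, sequential variance-inflation-factor filtering at
VIF < 10, ten-fold cross-validated subset sizing); and a geographically
weighted regression (GWR)

  s = β₀(**u**) + Σᵢ βᵢ(**u**) wᵢ + ε

is fitted, where the coefficients β(**u**) vary with location **u** through
locally weighted least squares with an adaptive Gaussian kernel
w = exp(−½ (d/b)²), b the distance to the q-th nearest neighbour, and q
chosen by minimising the corrected Akaike criterion (AICc) computed from
the hat-matrix trace. Global comparators (PLSR on the full absorbance
spectra, and WLR — ordinary least squares on the same selected wavelets)
and the external-validation protocol (seeded 70/30 split; R², MAE, RMSE on
the back-transformed scale; relative likelihoods
η_j = exp((AICc_min − AICc_j)/2)) are included, along with a Monte-Carlo
randomisation test for spatial non-stationarity of the local coefficients.

A fully seeded synthetic-data generator (`wgwr.synthgen`) produces spectral
libraries with scale-localised absorption bands, realistic
wavelength-correlated scatter noise, and properties built from known
coefficient surfaces, so every stage is testable against ground truth.

## Worked example

```python
from wgwr import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(preset="drift"), seed=0)
for name, m in report.models.items():
    t = m["testing"]
    print(f"{name:5s} test R2 = {t['r2']:.3f}  MAE = {t['mae']:.3f}  RMSE = {t['rmse']:.3f}")
pc = report.percent_changes
print("WLR -> WGWR: R2 +{}%, RMSE -{}%".format(
    pc["WLR_to_WGWR"]["test_r2_increase"], pc["WLR_to_WGWR"]["test_rmse_reduction"]))
print("q_opt =", report.gwr_summary["q"],
      " selected =", [(s["scale"], int(s["wavelength"]))
                      for s in report.selection["selected"]][:4])
```

prints

```
PLSR  test R2 = 0.211  MAE = 1.684  RMSE = 2.102
WLR   test R2 = 0.607  MAE = 1.137  RMSE = 1.485
WGWR  test R2 = 0.680  MAE = 1.045  RMSE = 1.339
WLR -> WGWR: R2 +12.1%, RMSE -9.8%
q_opt = 33  selected = [('D5', 1395), ('D4', 2207), ('D4', 2197), ('D5', 1416)]
```

The `drift` preset plants three absorption bands (700, 1415, 2205 nm) whose
wavelet features drive the property through coefficient surfaces that vary
linearly across a 300 × 300 km domain. The report shows the full chain at
work: the wavelet selection stage recovers coefficients at and around the
planted scales and wavelengths; moving from full-spectrum PLSR to the
selected wavelets (WLR) captures the multiresolution information; and
adding spatial weighting (WGWR, here with an adaptive bandwidth of 33
neighbours) improves the held-out R² and RMSE again. The report object
also carries per-model AICc and relative likelihoods, the cross-validation
trace of the selection stage, and the split bookkeeping.

The same chain is available from the shell:

```
wgwr simulate --preset drift --seed 7 --out data/
wgwr select --spectra data/spectra.csv --properties data/properties.csv --out sel.json
wgwr fit --spectra data/spectra.csv --properties data/properties.csv \
         --selection sel.json --out-prefix model
wgwr run --preset drift --seed 7 --out report.json
```

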