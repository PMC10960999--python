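# ricelwc

Estimation of rice **leaf water content (LWC)** from canopy hyperspectral
reflectance, coupled with physiological and micro-ecological covariates —
the crop water stress index (CWSI), chlorophyll-fluorescence efficiency
(Fv/Fm) and SPAD chlorophyll readings.

The package is aimed at crop-phenotyping researchers who want a tested,
reusable implementation of this workflow: exhaustive two-band spectral
index screening, the Idso-style CWSI chain, spectral–physiological coupled
regression, and a tree-ensemble benchmark — plus a synthetic campaign
generator with planted ground truth, so every stage has a recovery test
without any field data.

## The method

**LWC** is gravimetric: `LWC = (FW − DW)/FW` for fresh mass FW and oven-dry
mass DW. The spectral predictor is the two-band normalised difference

```
ND(λ1, λ2) = (R_λ1 − R_λ2) / (R_λ1 + R_λ2)
```

screened exhaustively over all pairs of the 1-nm grid 350–2500 nm: for each
pair, LWC is regressed on ND by ordinary least squares and the R²/RMSE
surfaces over all pairs select the optimal pair (near 1287/1673 nm for
water-sensitive canopies). Five classical indices (NDVI, NDII, NDWI, WI,
MSI) serve as fixed-band references.

**CWSI** locates the midday canopy–air temperature difference between a
non-stressed baseline and a fully stressed upper limit:

```
CWSI = ((Tc − Ta) − Tmin) / (Tmax − Tmin)
Tmin = A + B·VPD,   Tmax = A + B·VPG
VPD  = 0.61·exp(17.27·Ta/(Ta + 237.3))·(1 − RH/100)
VPG  = es(Ta) − es(Ta + A)
```

with A, B fit by OLS of `Tc − Ta` on VPD over well-watered (CK) plots in
the 10:00–14:00 window.

**Coupling:** per growth stage, the single-index line `LWC = a·ND + b` is
extended to `LWC = b0 + b1·ND + b2·cov` for one covariate (CWSI, Fv/Fm or
SPAD), fit on one study year and validated on the other; slope and
intercept of the single-index line are additionally related quadratically
to stage-mean covariates. Collinearity (VIF/tolerance) and Durbin–Watson
diagnostics accompany every model. Finally decision-tree, random-forest,
k-NN and gradient-boosted regressors are benchmarked against the linear
model on a seeded 70/30 split, scored by `R² = 1 − SSres/SStot` and RMSE.

## Worked example

```python
import ricelwc as rl

cfg = rl.RunConfig(out_dir="demo_run", seed=1, band_step=3)
report = rl.run_all(cfg)          # simulate -> ... -> benchmark

print(report["band_search"]["flowering"]["best_pair"])   # [1286, 1679]
print(report["cwsi_baseline"])    # {'A': 1.892, 'B': -1.958, 'n_fit': 800, ...}
print(report["pcc_lwc_cwsi"]["flowering"])               # -0.758
```

The run simulates a 120-plot campaign with a planted sensitive pair at
(1287, 1673) nm and a planted baseline A = 2.0 °C, B = −2.0 °C kPa⁻¹. The
scan recovers the pair to within a few nm — `(1286, 1679)` here — the
baseline fit returns `A = 1.892, B = −1.958` from 800 well-watered hours,
and CWSI correlates with LWC at −0.76 at flowering. The coupled ND + CWSI
model at flowering reaches model R² 0.80 versus 0.68 for ND alone (an 18.7%
relative improvement), and on the nonlinear benchmark GBDT attains
validation R² 0.90 versus 0.77 for the linear model (ratio 1.17).

The same workflow is available from the shell:

```bash
lwc simulate --seed 1 --out demo_campaign
lwc run --simulate --seed 1 --out demo_run
lwc bandscan --spectra demo_run/spectra.csv --lwc demo_run/observations.csv \
    --stage flowering --step 3 --out demo_scan
```

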