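# Methods

This note documents the models the package implements, the synthetic data
the tests run on, and the numerical and design choices a maintainer would
want to know about. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Physiological quantities

All plot-level traits are simple ratios or linear forms computed on plot
means (the models are fit on plot means; plant-level retention is out of
scope):

- `Fv/Fm = (Fm − Fo)/Fm` — maximum photochemical efficiency of PSII from
  dark-adapted fluorescence; a fraction, typically 0.75–0.85 in unstressed
  leaves.
- `Y(II) = (Fm′ − Fs)/Fm′` — actual photochemical efficiency under light.
- `LWC = (FW − DW)/FW` — gravimetric leaf water content, fraction.
- `LAI = D·ρ/10000` — leaf area per hill D (cm²) times planting density ρ
  (hills m⁻²), converted to m² m⁻².
- SPAD is aggregated as the arithmetic mean of the individual readings.

Zero denominators raise typed errors rather than propagating NaN: these
are data errors, and the pipeline is meant to fail fast on them.

## CWSI chain

Saturation vapour pressure uses the Tetens-form constants
`es(Ta) = 0.61·exp(17.27·Ta/(Ta + 237.3))` kPa; `VPD = es·(1 − RH/100)`.
The non-stressed baseline `Tc − Ta = A + B·VPD` is fit by OLS on
well-watered (CK) hourly records inside the 10:00–14:00 window — the same
window as the spectral measurements, so the stress state is consistent
across co-measured variables — per site-year, pooled over stages (a single
A, B pair per experiment context). The upper limit uses
`VPG = es(Ta) − es(Ta + A)` (the Idso construction; negative for A > 0,
which with B < 0 puts Tmax above Tmin). The textbook prose for VPG is
ambiguous about the sign; the opposite convention is available via a
`convention="reversed"` switch without being endorsed.

CWSI is **not clamped** to [0, 1]: values outside the envelope are flagged
(`out_of_envelope`) because they usually indicate baseline misfit, and
clamping would hide that from the downstream regressions, which accept raw
values. Per plot and stage, CWSI is the mean of the in-window hourly
values.

## Spectral indices and the band search

Indices read the 1-nm grid directly — no interpolation, smoothing or
continuum removal — so every index is invariant under multiplying the
spectrum by a positive constant. The classical set is NDVI(895,675),
NDII(819,1600), NDWI(860,1240), WI(970/900), MSI(1600/820); extra two-band
indices can be registered by name.

The exhaustive scan fits `LWC = a·ND(λ1,λ2) + b` for every unordered pair.
Because simple-regression R² equals the squared Pearson correlation and
the fitted RMSE is `sd(LWC)·sqrt(1 − R²)`, the scan vectorises to one
matrix product per anchor band; only the upper triangle is computed and
mirrored (the fit is exactly swap-symmetric, since swapping the pair
negates ND). A full 2151-band scan on ~120 samples takes a few seconds on
one CPU; `step=k` decimates the grid for quick looks. Cells with constant
ND (including the diagonal) are masked NaN. The best pair maximises R²,
with ties broken by smaller RMSE and then the lexicographically smaller
pair — a deterministic rule, stated because the underlying optimum can be
flat. Whether a single stage's map or a cross-stage view should pick the
operational pair is genuinely open; the pipeline reports per-stage optima
and, as its own aggregation, the per-stage optimum whose mean R² across
stages is highest.

R² is `1 − SSres/SStot` everywhere. (One published rendering of this
metric omits the "1 −", which would make it an unexplained-variance
fraction and contradict "larger is better"; the standard goodness-of-fit
form is used throughout.)

## Screening and diagnostics

Pearson correlations are pairwise-complete with two-sided t-test stars at
5%/1%, uncorrected for multiplicity (flagged as such in reports).
Covariates are ranked by |r| with LWC averaged over stages; signs are
preserved (CWSI is negatively correlated with LWC). Descriptive statistics
use the n−1 SD and CV = SD/mean. Outliers default to the mean ± 3 SD rule
per variable (a 1.5·IQR alternative is available); flagged rows are only
excluded when the config says so. Normality is checked by Shapiro–Wilk and
reported, never enforced. Collinearity uses the defining auxiliary
regressions: tolerance_j = 1 − R²_j, VIF_j = 1/tolerance_j. Durbin–Watson
is `Σ(Δe)²/Σe²` on residuals ordered by (year, site, plot_id) — the
observation order of field campaigns is rarely recorded, so the ordering
rule is explicit and logged.

## Coupling

Stage lines `LWC = a·ND + b` are validated on the held-out year against
the 1:1 line. The quadratic analysis regresses a and b on stage-mean
covariates (means over all plots of a stage). With four stages the
quadratic has one residual degree of freedom, and with three it is
saturated (R² = 1 by construction), so the relation is reported as
descriptive, without significance claims. Coupled models
`LWC = b0 + b1·ND + b2·cov` are fit by OLS (statsmodels) on the training
year — the campaign's 2022 by default, validated on 2021 — with 95%
coefficient confidence intervals, and at most one covariate joins ND (the
two-predictor form is the model family of interest; more predictors are a
non-goal).

## ML benchmark

DT (max depth 10), RF (100 trees, depth 10), KNN (k = 3, features
standardised with training-set statistics — distance-based methods need a
common scale, and only KNN gets it), GBDT (100 trees, depth 3, learning
rate 0.1) and OLS, all via scikit-learn, on a seeded random 70/30 split
(⌈0.7n⌉ training rows). All hyperparameters and the seed are recorded in
each result, making every run exactly reproducible. Ratio tables relative
to the linear model are computed from this package's own runs; published
ratios from any particular field dataset depend on that dataset and are
not comparison targets.

## Synthetic campaigns

The generator's defaults define the study conditions the tests assume:

- **Design:** 2 years × 4 cultivars × 3 irrigation treatments (CK flooded
  control, mild and severe alternate wetting–drying) × 5 replicate plots =
  120 plots, 4 growth stages, 5 midday microclimate hours per plot-stage.
- **LWC populations:** stage means 0.78/0.76/0.73/0.70 (CK) with
  treatment offsets 0/−0.04/−0.08 and within-cell σ = 0.02, giving
  CK > MADW > SADW and an overall range ≈ 0.60–0.80.
- **Reflectance:** a smooth dry-canopy base curve (green peak, red edge,
  SWIR decline) times multiplicative Gaussian absorption troughs. The
  major water bands at 1450/1940 nm deepen with LWC but carry extra
  plot-level variability (emulating saturation and canopy-structure
  effects at canopy scale), while the trough at the planted 1673 nm band
  is tightly LWC-coupled and the planted 1287 nm reference brightens
  slightly with LWC — so ND(1287, 1673) is the most LWC-correlated pair on
  the grid by construction. Band noise σ = 0.008 (post scan-averaging)
  puts single-stage ND–LWC R² near 0.6, a realistic canopy-scale value.
  The trough gain and offset vary across stages as quadratic functions of
  the stage-mean stress level, so the ND–LWC slope and intercept are
  stage-dependent.
- **Microclimate:** `Tc − Ta = A + B·VPD + s·(1 − LWC_norm) + noise` with
  planted A = 2.0 °C, B = −2.0 °C kPa⁻¹ (plausible for lower-baseline
  regressions; chosen as known truth for recovery testing), stress gain
  s = 2.5 °C, hourly noise 0.3 °C. LWC_norm is normalised to the CK stage
  mean so well-watered plots sit on the planted baseline on average.
- **Covariates:** linear-in-LWC Gaussians whose noise variances are solved
  in closed form from target within-stage correlations (CWSI −0.75,
  Fv/Fm 0.65, SPAD 0.60, Fo −0.50, Y(II) 0.55, LAI 0.50, biomass 0.45,
  yield 0.50 — inside commonly reported ranges). For CWSI the closed form
  additionally subtracts the variance contributed by averaged hourly
  noise. Rejection sampling is avoided for determinism and speed;
  `covariate_noise_scale=0` gives exactly deterministic covariates.
  Unreachable targets raise an error naming the covariate.

**What the generator does not emulate:** radiative-transfer leaf optics
(PROSPECT-class coupling of water content to the full spectrum), weather
dynamics, spatial field structure, cultivar-specific spectral signatures,
or non-Gaussian trait distributions. Passing recovery tests therefore show
that the *algorithms* are correct and coherent end-to-end under the
assumed statistical structure — not that any particular field dataset
satisfies that structure.

Two auxiliary generators serve focused checks: one draws data directly
from a known coupled equation (defaults 1.49·ND − 0.08·CWSI + 0.57,
σ = 0.01, 55 training / 36 validation rows labelled by year) for
coefficient recovery, and one plants an ND × CWSI interaction that a
linear model cannot express, for the ensemble-vs-linear benchmark.

## Numerical choices and degenerate inputs

- Replicate-scan averaging computes `first + mean(deviations)` so that
  averaging identical scans is exactly idempotent in floating point.
- The wavelength grid is fixed at 1-nm steps 350–2500 nm; other grids are
  rejected rather than resampled (resampling policy is out of scope).
  Percent-scaled reflectance (max > 1.5) is auto-converted with a logged
  warning.
- Scan cells are clipped to R² ∈ [0, 1] before the RMSE identity to guard
  against tiny negative round-off under the square root.
- One global seed drives everything; stage-level seeds are derived by
  CRC-hashing the stage name, so adding a stage never shifts another
  stage's draws. Same seed ⇒ bit-identical simulated tables and reports.
- Default problem sizes (120-plot campaigns, grid step 3 in the pipeline
  demos, 20–100 seed Monte-Carlo suites) keep a full run in seconds while
  leaving sampling error well inside the asserted tolerances; step 1 over
  the full grid remains the library default for the scan itself.

## Known limitations

- The year-based split assumes two study years; single-year data need the
  random split (the error message says so).
- The quadratic slope/intercept analysis is descriptive by construction at
  3–4 stages; it cannot support significance statements.
- Joint coverage of several marginal confidence intervals is below the
  per-interval level — simultaneous recovery checks across all
  coefficients of a model should expect roughly 0.95^k joint coverage, and
  the test suite's per-coefficient checks are the calibrated ones.
- CWSI assumes the air temperature recorded alongside canopy temperature;
  whether Ta is in-canopy or station-based is left to the user (both are
  carried).
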